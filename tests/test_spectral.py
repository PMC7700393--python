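"""Spectral core: tiling, power spectra vs a brute-force DFT oracle, peak
detection, movement classification and the full-map pipeline."""

import numpy as np
import pytest

from ciliaquant import (
    BlockSpectrum,
    FrameStack,
    SpectralParams,
    block_spectrum,
    classify_block,
    compute_cbf_map,
    dominant_frequency,
    tile,
)
from ciliaquant.spectral import _power_spectra

from conftest import make_sinusoid_stack, naive_power_spectrum


@pytest.mark.parametrize(
    "height,width,block_size,n_rows,n_cols,residual",
    [
        (128, 128, 4, 32, 32, 0),
        (10, 10, 4, 2, 2, 36),
        (4, 4, 4, 1, 1, 0),
        (130, 127, 8, 16, 15, 130 * 127 - 16 * 15 * 64),
    ],
)
def test_tile_geometry(height, width, block_size, n_rows, n_cols, residual):
    """Non-overlapping floor-division tiling with residual pixel accounting."""
    grid = tile(height, width, SpectralParams(block_size=block_size))
    assert (grid.n_rows, grid.n_cols) == (n_rows, n_cols)
    assert grid.residual_pixels == residual
    assert grid.n_blocks == n_rows * n_cols


def test_tile_rejects_subblock_frames():
    with pytest.raises(ValueError, match="smaller than one"):
        tile(3, 100, SpectralParams())


def test_block_size_minimum_enforced():
    with pytest.raises(ValueError, match="at least 4"):
        SpectralParams(block_size=2)


@pytest.mark.parametrize("window,detrend", [("none", True), ("none", False), ("hann", True)])
def test_power_spectrum_matches_naive_dft_oracle(window, detrend):
    """Implementation equals an explicit O(T²) DFT on random blocks to 1e-9.

    The oracle receives the same detrended/tapered series, so the check
    isolates the transform + power normalisation itself.
    """
    rng = np.random.default_rng(42)
    params = SpectralParams(window=window, detrend=detrend)
    worst = 0.0
    for _ in range(25):
        t = int(rng.integers(16, 65))
        frames = rng.uniform(0, 200, size=(t, 4, 4))
        stack = FrameStack(frames=frames, fps=500.0)
        spec = block_spectrum(stack, (0, 0), params)
        # oracle: same preprocessing, explicit DFT per pixel, then average
        pixels = frames.reshape(t, -1).astype(float)
        if detrend:
            pixels = pixels - pixels.mean(axis=0)
        if window == "hann":
            pixels = pixels * np.hanning(t)[:, None]
        expected = np.mean(
            [naive_power_spectrum(pixels[:, j], 500.0)[1] for j in range(pixels.shape[1])],
            axis=0,
        )
        scale = max(expected.max(), 1e-30)
        worst = max(worst, np.max(np.abs(spec.power - expected)) / scale)
    assert worst <= 1e-9


def test_parseval_energy_conservation(params_rect):
    """window=none + detrend: Σ power equals the mean per-pixel Σ(x−x̄)²."""
    rng = np.random.default_rng(7)
    frames = rng.uniform(0, 4095, size=(64, 4, 4))
    stack = FrameStack(frames=frames, fps=500.0)
    spec = block_spectrum(stack, (0, 0), params_rect)
    pixels = frames.reshape(64, -1)
    energy = ((pixels - pixels.mean(axis=0)) ** 2).sum(axis=0).mean()
    assert spec.power.sum() == pytest.approx(energy, rel=1e-9)


def test_constant_block_gives_zero_spectrum(params_rect):
    """Zero-variance input is valid and spectrally silent."""
    stack = FrameStack(frames=np.full((32, 4, 4), 100.0), fps=500.0)
    spec = block_spectrum(stack, (0, 0), params_rect)
    assert np.all(spec.power[1:] == 0.0)
    assert dominant_frequency(spec, params_rect) is None
    assert not classify_block(spec, params_rect).is_moving


def test_too_few_frames_rejected(params_rect):
    stack = FrameStack(frames=np.random.default_rng(0).uniform(size=(8, 4, 4)), fps=500.0)
    with pytest.raises(ValueError, match="insufficient frames"):
        block_spectrum(stack, (0, 0), params_rect)


def test_pure_sinusoid_concentrates_in_its_bin(params_rect):
    """14 Hz at fps 500, T 250: all non-DC power lands in bin 7 (2 Hz grid)."""
    stack = make_sinusoid_stack(14.0)
    spec = block_spectrum(stack, (0, 0), params_rect)
    assert spec.frequencies[7] == 14.0
    assert spec.power[7] == pytest.approx(spec.power[1:].sum(), rel=1e-9)
    freq, peak = dominant_frequency(spec, params_rect)
    assert freq == 14.0 and peak > 0


def test_power_averaging_survives_antiphase_halves(params_rect):
    """Two half-blocks beating in antiphase: pixel-averaged *power* keeps the
    14 Hz peak, whereas the spectrum of the block-mean signal cancels to ~0.

    This is the metachronal-wave rationale for averaging power, not
    amplitude, across a block.
    """
    t = np.arange(250) / 500.0
    s0 = 30 * np.sin(2 * np.pi * 14 * t)
    frames = np.empty((250, 4, 4))
    frames[:, :, :2] = (100 + s0)[:, None, None]
    frames[:, :, 2:] = (100 - s0)[:, None, None]  # phase π
    stack = FrameStack(frames=frames, fps=500.0)
    spec = block_spectrum(stack, (0, 0), params_rect)
    freq, peak = dominant_frequency(spec, params_rect)
    assert freq == 14.0
    # amplitude-averaging oracle: the mean signal is constant
    mean_signal = frames.reshape(250, -1).mean(axis=1)
    _, cancelled = naive_power_spectrum(mean_signal - mean_signal.mean(), 500.0)
    assert cancelled.max() < 1e-18 * peak


@pytest.mark.parametrize("freq,expected_moving", [(2.0, True), (50.0, True), (1.0, False), (60.0, False)])
def test_detection_band_edges_inclusive(freq, expected_moving, params_rect):
    """2 and 50 Hz are inside the band; 1 and 60 Hz are rejected.

    T=500 at fps 500 puts every one of these frequencies on the 1 Hz
    grid, so the calls probe the band logic, not spectral leakage.
    """
    stack = make_sinusoid_stack(freq, n_frames=500)
    result = classify_block(block_spectrum(stack, (0, 0), params_rect), params_rect)
    assert result.is_moving is expected_moving
    if expected_moving:
        assert result.dominant_freq_hz == freq


def test_tie_breaks_to_lower_frequency(params_rect):
    """Two exactly equal in-band peaks: the lower frequency wins."""
    freqs = np.arange(0, 126) * 2.0
    power = np.zeros_like(freqs)
    power[5] = power[20] = 7.0  # 10 Hz and 40 Hz
    spec = BlockSpectrum(row=0, col=0, frequencies=freqs, power=power, noise_floor=0.0)
    freq, _ = dominant_frequency(spec, params_rect)
    assert freq == 10.0


def test_nonaligned_frequency_within_one_bin():
    """A 14.7 Hz beat lands within one grid step (fps/T = 2 Hz) of truth."""
    params = SpectralParams()  # hann suppresses the leakage skirt
    stack = make_sinusoid_stack(14.7)
    freq, _ = dominant_frequency(block_spectrum(stack, (0, 0), params), params)
    assert abs(freq - 14.7) <= 500.0 / 250


def test_noiseless_signal_classifies_moving(params_rect):
    result = classify_block(block_spectrum(make_sinusoid_stack(14.0), (0, 0), params_rect), params_rect)
    assert result.is_moving and result.dominant_freq_hz == 14.0
    assert result.peak_power > 8 * result.noise_floor


def test_white_noise_false_positive_rate_below_one_percent(params_default):
    """Monte-Carlo bound: of 1024 pure-noise blocks, <1% classify moving."""
    rng = np.random.default_rng(2024)
    frames = 100 + 10 * rng.standard_normal((250, 128, 128))
    cbf_map = compute_cbf_map(FrameStack(frames=frames, fps=500.0), params_default)
    assert cbf_map.grid.n_blocks == 1024
    assert cbf_map.n_blocks_moving / cbf_map.grid.n_blocks < 0.01


def test_fmax_above_nyquist_rejected():
    stack = make_sinusoid_stack(10.0, fps=80.0, n_frames=80)
    with pytest.raises(ValueError, match="Nyquist"):
        compute_cbf_map(stack, SpectralParams(f_max=50.0))


def test_full_map_matches_per_block_path(params_default):
    """The vectorised map equals block-by-block spectrum + classification."""
    rng = np.random.default_rng(5)
    t = np.arange(64) / 500.0
    frames = 100 + 5 * rng.standard_normal((64, 12, 12))
    frames[:, :8, :4] += 40 * np.sin(2 * np.pi * 14 * t)[:, None, None]
    stack = FrameStack(frames=frames, fps=500.0)
    cbf_map = compute_cbf_map(stack, params_default)
    for result in cbf_map:
        single = classify_block(
            block_spectrum(stack, (result.row, result.col), params_default), params_default
        )
        assert single.is_moving == result.is_moving
        assert single.dominant_freq_hz == result.dominant_freq_hz
        assert single.peak_power == pytest.approx(result.peak_power, rel=1e-12, abs=1e-300)
        assert single.noise_floor == pytest.approx(result.noise_floor, rel=1e-12, abs=1e-300)


def test_map_is_deterministic(params_default):
    rng = np.random.default_rng(11)
    frames = rng.uniform(0, 255, size=(64, 16, 16))
    stack = FrameStack(frames=frames, fps=500.0)
    a = compute_cbf_map(stack, params_default)
    b = compute_cbf_map(stack, params_default)
    assert np.array_equal(a.is_moving, b.is_moving)
    assert np.array_equal(a.dominant_freq_hz, b.dominant_freq_hz, equal_nan=True)
    assert np.array_equal(a.peak_power, b.peak_power)


def test_more_noise_never_means_more_moving_blocks():
    """In expectation over seeds, raising noise variance cannot raise the
    number of moving blocks for a fixed signal."""
    from ciliaquant import SimScene, simulate_stack
    import dataclasses

    counts = []
    for noise_sd in (5.0, 15.0, 45.0):
        total = 0
        for seed in range(3):
            scene = SimScene(
                width=64, height=64, n_frames=125, coverage_fraction=0.3,
                noise_sd=noise_sd, patch_shape="rect", align=4, seed=seed,
            )
            stack, _ = simulate_stack(scene)
            total += compute_cbf_map(stack).n_blocks_moving
        counts.append(total / 3)
    assert counts[0] >= counts[1] >= counts[2]


def test_map_table_round_trip(tmp_path, params_default):
    from ciliaquant.spectral import read_cbf_map_csv

    rng = np.random.default_rng(3)
    stack = FrameStack(frames=rng.uniform(0, 255, (32, 8, 8)), fps=500.0)
    cbf_map = compute_cbf_map(stack, params_default, fov_id="fov7")
    path = tmp_path / "map.csv"
    cbf_map.to_csv(path)
    df = read_cbf_map_csv(path)
    assert df.attrs["fov_id"] == "fov7"
    assert len(df) == cbf_map.grid.n_blocks
    assert df["is_moving"].sum() == cbf_map.n_blocks_moving
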