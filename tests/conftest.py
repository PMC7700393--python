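"""Shared fixtures: sinusoid stacks and parameter sets used across the suite."""

import numpy as np
import pytest

from ciliaquant import FrameStack, SpectralParams


@pytest.fixture
def params_rect() -> SpectralParams:
    """Rectangular window, no leakage: the exact-recovery configuration."""
    return SpectralParams(window="none")


@pytest.fixture
def params_default() -> SpectralParams:
    return SpectralParams()


def make_sinusoid_stack(
    freq_hz: float,
    fps: float = 500.0,
    n_frames: int = 250,
    height: int = 8,
    width: int = 8,
    amplitude: float = 30.0,
    baseline: float = 100.0,
    phase: float = 0.0,
) -> FrameStack:
    """Every pixel beats in phase at ``freq_hz``; no noise."""
    t = np.arange(n_frames) / fps
    trace = baseline + amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
    frames = np.broadcast_to(trace[:, None, None], (n_frames, height, width)).copy()
    return FrameStack(frames=frames, fps=fps, source_id=f"sin{freq_hz}")


def naive_power_spectrum(x: np.ndarray, fps: float):
    """O(T²) one-sided DFT power oracle, variance-energy normalisation.

    Independent of numpy.fft: the transform is an explicit correlation
    against complex exponentials.
    """
    x = np.asarray(x, dtype=np.float64)
    t = len(x)
    n = np.arange(t)
    ks = np.arange(t // 2 + 1)
    power = np.empty(len(ks))
    for i, k in enumerate(ks):
        coeff = np.sum(x * np.exp(-2j * np.pi * k * n / t))
        p = abs(coeff) ** 2 / t
        if k != 0 and not (t % 2 == 0 and k == t // 2):
            p *= 2.0
        power[i] = p
    freqs = ks * fps / t
    return freqs, power
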