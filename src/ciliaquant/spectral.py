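"""Block-wise temporal power spectra and dominant beat-frequency detection.

The field of view is tiled into square pixel blocks (minimum 4×4, the
analysis unit of the motion map).  For each block, every pixel's
intensity time series is mean-detrended, optionally Hann-tapered, and
Fourier transformed; the one-sided power spectra are then *averaged
across the block's pixels*.  Averaging power rather than complex
amplitude is essential: neighbouring cilia beat with a spatial phase lag
(the metachronal wave), and amplitude-averaging phase-shifted sinusoids
cancels exactly where power-averaging reinforces.

A block is classified as "moving" when the dominant in-band spectral
peak (detection band 2–50 Hz by default, band edges inclusive, DC never
a candidate) rises above ``power_ratio_k`` times the in-band median
power — a robust noise floor.  The dominant frequency is reported at bin
resolution ``fps / n_frames``; no sub-bin interpolation is performed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .video_io import FrameStack

__all__ = [
    "SpectralParams",
    "BlockGrid",
    "BlockSpectrum",
    "BlockResult",
    "CBFMap",
    "tile",
    "block_spectrum",
    "trace_spectrum",
    "dominant_frequency",
    "classify_block",
    "compute_cbf_map",
]

#: Shortest stack that yields a usable frequency grid.
MIN_FRAMES = 16

#: In-band power below this fraction of the total non-DC power is treated as
#: numerically zero.  An out-of-band oscillation leaves O(machine-eps²)
#: rounding dust inside the band; without this floor the peak/median ratio
#: test can fire on that dust.
REL_POWER_FLOOR = 1e-12


@dataclass(frozen=True)
class SpectralParams:
    """Tunable parameters of the block-FFT motion analysis.

    Attributes
    ----------
    block_size
        Pixels per side of a square analysis block; minimum 4.
    f_min, f_max
        Detection band in Hz (inclusive).  Peaks outside the band are
        treated as non-movement: slow drift and debris live below 2 Hz,
        and ciliary beating above 50 Hz is not physiological.
    power_ratio_k
        Movement-significance multiplier: a block moves only if its peak
        power exceeds ``power_ratio_k`` × the in-band median power.
    detrend
        Subtract each pixel's temporal mean before the transform.
    window
        Taper applied along time: ``"hann"`` (default, suppresses
        leakage of non-bin-aligned beats) or ``"none"``.
    """

    block_size: int = 4
    f_min: float = 2.0
    f_max: float = 50.0
    power_ratio_k: float = 8.0
    detrend: bool = True
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.block_size < 4:
            raise ValueError(
                f"block_size must be at least 4 pixels, got {self.block_size}"
            )
        if not (0 < self.f_min < self.f_max):
            raise ValueError(
                f"need 0 < f_min < f_max, got f_min={self.f_min}, f_max={self.f_max}"
            )
        if self.power_ratio_k <= 0:
            raise ValueError("power_ratio_k must be positive")
        if self.window not in ("none", "hann"):
            raise ValueError(f"window must be 'none' or 'hann', got {self.window!r}")

    def validate_against(self, fps: float) -> None:
        """Check band edges against the Nyquist limit of an acquisition."""
        if self.f_max > fps / 2:
            raise ValueError(
                f"f_max={self.f_max} Hz exceeds the Nyquist frequency {fps / 2} Hz"
            )


@dataclass(frozen=True)
class BlockGrid:
    """Non-overlapping tiling of an H×W frame into square blocks.

    Edge residuals smaller than one block are excluded from analysis;
    their pixel count is reported so area accounting stays explicit.
    """

    block_size: int
    n_rows: int
    n_cols: int
    residual_pixels: int

    @property
    def n_blocks(self) -> int:
        return self.n_rows * self.n_cols

    def block_slices(self, row: int, col: int) -> Tuple[slice, slice]:
        b = self.block_size
        return slice(row * b, (row + 1) * b), slice(col * b, (col + 1) * b)


@dataclass
class BlockSpectrum:
    """One block's pixel-averaged one-sided power spectrum."""

    row: int
    col: int
    frequencies: np.ndarray  # Hz, 0 .. fps/2
    power: np.ndarray  # same length, >= 0
    noise_floor: float  # median in-band power


@dataclass(frozen=True)
class BlockResult:
    """Classification of one block: moving (with its beat frequency) or not."""

    row: int
    col: int
    is_moving: bool
    dominant_freq_hz: Optional[float]
    peak_power: float
    noise_floor: float


@dataclass
class CBFMap:
    """Per-block beat-frequency map for one field of view.

    Array-backed: ``is_moving``, ``dominant_freq_hz`` (NaN where not
    moving), ``peak_power`` and ``noise_floor`` all have shape
    ``(grid.n_rows, grid.n_cols)``.
    """

    grid: BlockGrid
    is_moving: np.ndarray
    dominant_freq_hz: np.ndarray
    peak_power: np.ndarray
    noise_floor: np.ndarray
    params: SpectralParams
    fps: float
    fov_id: str = ""

    def __post_init__(self) -> None:
        shape = (self.grid.n_rows, self.grid.n_cols)
        for name in ("is_moving", "dominant_freq_hz", "peak_power", "noise_floor"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)

    @property
    def n_blocks_moving(self) -> int:
        return int(np.count_nonzero(self.is_moving))

    def __iter__(self) -> Iterator[BlockResult]:
        for r in range(self.grid.n_rows):
            for c in range(self.grid.n_cols):
                moving = bool(self.is_moving[r, c])
                yield BlockResult(
                    row=r,
                    col=c,
                    is_moving=moving,
                    dominant_freq_hz=float(self.dominant_freq_hz[r, c]) if moving else None,
                    peak_power=float(self.peak_power[r, c]),
                    noise_floor=float(self.noise_floor[r, c]),
                )

    def to_frame(self) -> pd.DataFrame:
        """One row per block: row, col, is_moving, freq_hz, peak_power, noise_floor."""
        rows, cols = np.meshgrid(
            np.arange(self.grid.n_rows), np.arange(self.grid.n_cols), indexing="ij"
        )
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "is_moving": self.is_moving.ravel().astype(bool),
                "freq_hz": np.where(
                    self.is_moving.ravel(), self.dominant_freq_hz.ravel(), np.nan
                ),
                "peak_power": self.peak_power.ravel(),
                "noise_floor": self.noise_floor.ravel(),
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        header = (
            f"# fov_id = {self.fov_id}\n"
            f"# fps = {self.fps}\n"
            f"# block_size = {self.grid.block_size}\n"
            f"# residual_pixels = {self.grid.residual_pixels}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, index=False, float_format="%.10g")


def tile(height: int, width: int, params: SpectralParams) -> BlockGrid:
    """Tile an H×W frame into non-overlapping ``block_size`` squares.

    Residual edge pixels (when a dimension is not a multiple of the
    block size) are excluded; their count is reported on the grid.
    """
    b = params.block_size
    if height < b or width < b:
        raise ValueError(
            f"frame {height}×{width} is smaller than one {b}×{b} block"
        )
    n_rows, n_cols = height // b, width // b
    residual = height * width - n_rows * n_cols * b * b
    return BlockGrid(block_size=b, n_rows=n_rows, n_cols=n_cols, residual_pixels=residual)


def _power_spectra(
    series: np.ndarray, fps: float, params: SpectralParams
) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided power spectra of time series, columns = independent series.

    Normalised so that (window="none", detrend on) the power in each
    column sums to that series' variance-energy Σ(x − x̄)² — a Parseval
    identity that anchors the units.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, np.newaxis]
    t = x.shape[0]
    if t < MIN_FRAMES:
        raise ValueError(
            f"insufficient frames: {t} < {MIN_FRAMES} (frequency grid too coarse)"
        )
    if params.detrend:
        x = x - x.mean(axis=0)
    if params.window == "hann":
        x = x * np.hanning(t).reshape((-1,) + (1,) * (x.ndim - 1))
    spec = np.fft.rfft(x, axis=0)
    power = (spec.real**2 + spec.imag**2) / t
    power[1:] *= 2.0
    if t % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not mirrored
    freqs = np.fft.rfftfreq(t, d=1.0 / fps)
    return freqs, power


def _band_mask(freqs: np.ndarray, params: SpectralParams) -> np.ndarray:
    # inclusive band edges; a hair of tolerance guards float bin values
    tol = 1e-9 * max(1.0, freqs[-1] if len(freqs) else 1.0)
    mask = (freqs >= params.f_min - tol) & (freqs <= params.f_max + tol)
    mask[0] = False  # DC never a candidate
    return mask


def block_spectrum(
    stack: FrameStack, block: Tuple[int, int], params: SpectralParams
) -> BlockSpectrum:
    """Pixel-averaged power spectrum of one grid block of a stack."""
    params.validate_against(stack.fps)
    grid = tile(stack.height, stack.width, params)
    row, col = block
    if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
        raise ValueError(f"block {block} outside grid {grid.n_rows}×{grid.n_cols}")
    ys, xs = grid.block_slices(row, col)
    pixels = stack.frames[:, ys, xs].reshape(stack.n_frames, -1)
    freqs, power = _power_spectra(pixels, stack.fps, params)
    mean_power = power.mean(axis=1)
    band = _band_mask(freqs, params)
    floor = float(np.median(mean_power[band])) if band.any() else 0.0
    return BlockSpectrum(
        row=row, col=col, frequencies=freqs, power=mean_power, noise_floor=floor
    )


def trace_spectrum(
    intensity: np.ndarray, fps: float, params: SpectralParams
) -> BlockSpectrum:
    """Spectrum of a single 1-D intensity trace, treated as a 1-pixel block."""
    params.validate_against(fps)
    freqs, power = _power_spectra(np.asarray(intensity, dtype=float), fps, params)
    power = power[:, 0]
    band = _band_mask(freqs, params)
    floor = float(np.median(power[band])) if band.any() else 0.0
    return BlockSpectrum(row=0, col=0, frequencies=freqs, power=power, noise_floor=floor)


def dominant_frequency(
    spec: BlockSpectrum, params: SpectralParams
) -> Optional[Tuple[float, float]]:
    """Frequency and power of the strongest in-band spectral peak.

    Ties break toward the lower frequency.  Returns ``None`` when the
    band holds no bins or carries no power.
    """
    band = _band_mask(spec.frequencies, params)
    if not band.any():
        return None
    band_power = spec.power[band]
    idx = int(np.argmax(band_power))  # first max = lowest frequency on ties
    if band_power[idx] <= REL_POWER_FLOOR * spec.power[1:].sum():
        return None  # band holds no power beyond numerical dust
    return float(spec.frequencies[band][idx]), float(band_power[idx])


def classify_block(spec: BlockSpectrum, params: SpectralParams) -> BlockResult:
    """Moving/non-moving call for one block spectrum.

    Moving requires an in-band dominant peak whose power exceeds
    ``power_ratio_k`` times the in-band median (the noise floor).
    """
    dom = dominant_frequency(spec, params)
    if dom is None:
        return BlockResult(spec.row, spec.col, False, None, 0.0, spec.noise_floor)
    freq, peak = dom
    moving = peak > params.power_ratio_k * spec.noise_floor
    return BlockResult(
        row=spec.row,
        col=spec.col,
        is_moving=moving,
        dominant_freq_hz=freq if moving else None,
        peak_power=peak,
        noise_floor=spec.noise_floor,
    )


def compute_cbf_map(
    stack: FrameStack, params: Optional[SpectralParams] = None, fov_id: str = ""
) -> CBFMap:
    """Tile, transform and classify every block of a field of view.

    Vectorised over blocks but numerically identical to calling
    :func:`block_spectrum` + :func:`classify_block` per block.
    Deterministic for a fixed stack and parameters.
    """
    if params is None:
        params = SpectralParams()
    params.validate_against(stack.fps)
    grid = tile(stack.height, stack.width, params)
    b = grid.block_size
    t = stack.n_frames
    cropped = stack.frames[:, : grid.n_rows * b, : grid.n_cols * b]
    # (T, nr, b, nc, b) -> (T, nr*nc, b*b): one column per pixel, grouped by block
    blocks = (
        cropped.reshape(t, grid.n_rows, b, grid.n_cols, b)
        .transpose(0, 1, 3, 2, 4)
        .reshape(t, grid.n_blocks, b * b)
    )
    freqs, power = _power_spectra(blocks.reshape(t, -1), stack.fps, params)
    block_power = power.reshape(-1, grid.n_blocks, b * b).mean(axis=2)

    band = _band_mask(freqs, params)
    band_freqs = freqs[band]
    band_power = block_power[band]  # (n_band_bins, n_blocks)
    if band_freqs.size == 0:
        raise ValueError(
            f"detection band [{params.f_min}, {params.f_max}] Hz holds no bins "
            f"at resolution {stack.fps / t:.3g} Hz"
        )
    peak_idx = np.argmax(band_power, axis=0)
    peak_power = band_power[peak_idx, np.arange(grid.n_blocks)]
    noise_floor = np.median(band_power, axis=0)
    has_power = peak_power > REL_POWER_FLOOR * block_power[1:].sum(axis=0)
    moving = has_power & (peak_power > params.power_ratio_k * noise_floor)
    freq = np.where(moving, band_freqs[peak_idx], np.nan)

    shape = (grid.n_rows, grid.n_cols)
    return CBFMap(
        grid=grid,
        is_moving=moving.reshape(shape),
        dominant_freq_hz=freq.reshape(shape),
        peak_power=np.where(has_power, peak_power, 0.0).reshape(shape),
        noise_floor=noise_floor.reshape(shape),
        params=params,
        fps=stack.fps,
        fov_id=fov_id,
    )


def read_cbf_map_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a serialised CBF map table (``#``-prefixed header preserved as attrs)."""
    import io

    meta: dict = {}
    lines = Path(path).read_text().splitlines(keepends=True)
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, value = line[1:].partition("=")
        meta[key.strip()] = value.strip()
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    df.attrs.update(meta)
    return df
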