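"""Reading and writing video stacks, metadata sidecars and rendered frequency maps.

High-speed video microscopy (HSVM) stacks are exchanged as multi-page
grayscale TIFF files, or as raw frame binaries, each accompanied by a
flat key-value metadata sidecar (``<video file>.meta``) that records at
minimum the acquisition frame rate.  The frame rate is never defaulted:
every spectral conversion downstream depends on it, so a stack without a
known rate is an error, not a guess.

Rendered ciliary-beat-frequency maps follow the conventional monochrome
ramp: 0 Hz maps to black and frequencies at or above the display maximum
(25 Hz by default) map to white; non-moving blocks are black.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "FrameStack",
    "StackMetadata",
    "read_metadata_sidecar",
    "write_metadata_sidecar",
    "read_stack",
    "write_stack",
    "write_cbf_map_image",
    "render_cbf_map",
]

PathLike = Union[str, Path]

#: Default display clip for rendered maps, in Hz.  Frequencies above this
#: (but still inside the detection band) render white while remaining
#: distinct in the underlying data.
DISPLAY_F_MAX_HZ = 25.0


@dataclass
class FrameStack:
    """A (time, row, column) grayscale intensity series with its frame rate.

    Parameters
    ----------
    frames
        3-D array indexed ``(t, y, x)``; non-negative, finite intensities.
    fps
        Acquisition frame rate in Hz (e.g. 500 for diagnostic HSVM).
    pixel_size_um
        Optional physical pixel size in microns.
    source_id
        Free-text provenance label.
    """

    frames: np.ndarray
    fps: float
    pixel_size_um: Optional[float] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (time, row, column); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("a stack needs at least 2 frames")
        if not np.isfinite(self.fps) or self.fps <= 0:
            raise ValueError(f"fps must be positive and finite, got {self.fps}")
        if np.issubdtype(self.frames.dtype, np.floating) and not np.all(
            np.isfinite(self.frames)
        ):
            raise ValueError("frame intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class StackMetadata:
    """Acquisition context for a stack stored outside the pixel data."""

    fps: float
    width: int = 0
    height: int = 0
    bit_depth: int = 16
    frame_count: int = 0
    objective: str = ""

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"bit_depth must be 8, 12 or 16, got {self.bit_depth}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


def write_metadata_sidecar(meta: StackMetadata, path: PathLike) -> None:
    """Write a flat ``key = value`` sidecar file."""
    lines = [
        f"fps = {meta.fps}",
        f"width = {meta.width}",
        f"height = {meta.height}",
        f"bit_depth = {meta.bit_depth}",
        f"frame_count = {meta.frame_count}",
        f"objective = {meta.objective}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata_sidecar(path: PathLike) -> StackMetadata:
    """Parse a flat key-value sidecar; unknown keys are ignored."""
    fields: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    if "fps" not in fields or not fields["fps"]:
        raise ValueError(f"frame rate unknown: sidecar {path} has no 'fps' entry")
    return StackMetadata(
        fps=float(fields["fps"]),
        width=int(fields.get("width", 0) or 0),
        height=int(fields.get("height", 0) or 0),
        bit_depth=int(fields.get("bit_depth", 16) or 16),
        frame_count=int(fields.get("frame_count", 0) or 0),
        objective=fields.get("objective", ""),
    )


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".meta")


def _dtype_for_bit_depth(bit_depth: int) -> np.dtype:
    return np.dtype(np.uint8) if bit_depth == 8 else np.dtype(np.uint16)


def read_stack(path: PathLike, metadata: Optional[StackMetadata] = None) -> FrameStack:
    """Read a multi-page TIFF or raw frame binary into a :class:`FrameStack`.

    The frame rate is taken from ``metadata`` if supplied, otherwise from
    the ``<path>.meta`` sidecar.  Raw binaries additionally require width,
    height and bit depth.  Multi-channel TIFF frames are converted to
    single-channel luminance by averaging channels.

    Raises
    ------
    ValueError
        If no frame rate can be determined ("frame rate unknown"), if a
        raw binary is truncated (the failing frame index is named), or if
        frames do not share one H×W geometry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    if metadata is None and _sidecar_path(path).exists():
        metadata = read_metadata_sidecar(_sidecar_path(path))

    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            frames = tifffile.imread(path)
        except Exception as exc:  # corrupt container
            raise ValueError(f"unreadable TIFF stack {path}: {exc}") from exc
        frames = np.asarray(frames)
        if frames.ndim == 2:
            frames = frames[np.newaxis]
        if frames.ndim == 4:  # (T, H, W, C) -> luminance
            frames = frames.mean(axis=-1)
        if frames.ndim != 3:
            raise ValueError(
                f"cannot interpret TIFF of shape {frames.shape} as a (T, H, W) stack"
            )
        if metadata is None:
            raise ValueError(
                f"frame rate unknown for {path}: supply StackMetadata or a "
                f"'{_sidecar_path(path).name}' sidecar with an fps entry"
            )
        return FrameStack(frames=frames, fps=metadata.fps, source_id=str(path))

    # raw frame binary
    if metadata is None:
        raise ValueError(
            f"frame rate unknown for raw stack {path}: metadata sidecar required"
        )
    if metadata.width < 1 or metadata.height < 1:
        raise ValueError("raw stacks need width and height metadata")
    dtype = _dtype_for_bit_depth(metadata.bit_depth)
    frame_bytes = metadata.width * metadata.height * dtype.itemsize
    size = path.stat().st_size
    n_frames = size // frame_bytes
    if size % frame_bytes:
        raise ValueError(
            f"truncated raw stack {path}: frame {n_frames} is incomplete "
            f"({size % frame_bytes} of {frame_bytes} bytes)"
        )
    if metadata.frame_count and metadata.frame_count != n_frames:
        raise ValueError(
            f"raw stack {path}: sidecar says {metadata.frame_count} frames "
            f"but file holds {n_frames}"
        )
    frames = np.fromfile(path, dtype=dtype).reshape(
        n_frames, metadata.height, metadata.width
    )
    return FrameStack(frames=frames, fps=metadata.fps, source_id=str(path))


def write_stack(stack: FrameStack, path: PathLike, bit_depth: int = 16) -> None:
    """Write a stack as multi-page grayscale TIFF plus metadata sidecar."""
    path = Path(path)
    dtype = _dtype_for_bit_depth(bit_depth)
    frames = stack.frames
    if not np.issubdtype(frames.dtype, np.integer):
        frames = np.clip(np.rint(frames), 0, 2**bit_depth - 1)
    frames = frames.astype(dtype)
    tifffile.imwrite(path, frames, photometric="minisblack")
    write_metadata_sidecar(
        StackMetadata(
            fps=stack.fps,
            width=stack.width,
            height=stack.height,
            bit_depth=bit_depth,
            frame_count=stack.n_frames,
        ),
        _sidecar_path(path),
    )


def render_cbf_map(
    cbf_map, f_display_max: float = DISPLAY_F_MAX_HZ, cell_px: Optional[int] = None
) -> np.ndarray:
    """Render a CBF map as an 8-bit grayscale image array.

    Each block becomes one ``cell_px``-sided square (default: the
    analysis block size, so the image overlays the field of view).
    Non-moving blocks are black; moving blocks follow a linear ramp with
    0 Hz at black and ``f_display_max`` (and above) at white.
    """
    moving = np.asarray(cbf_map.is_moving, dtype=bool)
    freq = np.nan_to_num(np.asarray(cbf_map.dominant_freq_hz, dtype=float), nan=0.0)
    ramp = np.clip(freq / float(f_display_max), 0.0, 1.0)
    cell = np.where(moving, np.rint(ramp * 255.0), 0.0).astype(np.uint8)
    if cell_px is None:
        cell_px = cbf_map.grid.block_size
    return np.kron(cell, np.ones((cell_px, cell_px), dtype=np.uint8))


def write_cbf_map_image(cbf_map, path: PathLike, f_display_max: float = DISPLAY_F_MAX_HZ) -> None:
    """Write the rendered map to an image file (PNG or TIFF by extension).

    Rendering is a pure function of the map: identical maps give
    byte-identical files.
    """
    img = render_cbf_map(cbf_map, f_display_max=f_display_max)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img, photometric="minisblack")
    else:
        iio.imwrite(path, img, extension=path.suffix or ".png")
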