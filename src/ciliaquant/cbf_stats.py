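"""Ciliary beat frequency summaries over regions of interest.

Diagnostic CBF is read from intensity traces over "strips" of ciliated
epithelium: each region of interest (ROI) yields one dominant beat
frequency via the same spectral criterion used for block maps, and a
sample is summarised by the mean over its moving ROIs.  Conventions:

* at least 6 ROIs are required for a reportable summary — fewer gives
  status ``insufficient``;
* a sample whose ROIs are all static is reported with mean CBF 0 Hz and
  status ``static``;
* otherwise the mean (over moving ROIs only) is flagged against the
  normal ex vivo range of 11–20 Hz, bounds inclusive.  Samples mixing
  static and moving ROIs keep their mean but carry a ``mixed_motility``
  warning, since such samples typically show a variable beat pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .spectral import SpectralParams, classify_block, trace_spectrum

__all__ = [
    "ROITrace",
    "CBFSummary",
    "roi_cbf",
    "summarise_sample",
    "read_roi_traces",
    "write_cbf_summary",
    "NORMAL_CBF_RANGE_HZ",
    "MIN_ROIS",
]

#: Normal mean CBF for ex vivo samples at 37 °C, Hz (inclusive bounds).
NORMAL_CBF_RANGE_HZ: Tuple[float, float] = (11.0, 20.0)

#: Minimum number of ciliated strips for a reportable mean CBF.
MIN_ROIS = 6


@dataclass
class ROITrace:
    """One region-of-interest intensity time series."""

    roi_id: str
    intensity: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float).ravel()
        if self.intensity.size < 16:
            raise ValueError(
                f"ROI {self.roi_id!r}: trace too short ({self.intensity.size} < 16 samples)"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")


@dataclass(frozen=True)
class CBFSummary:
    """Sample-level mean CBF with the numeric reporting conventions applied."""

    sample_id: str
    per_roi_freq_hz: tuple  # one entry per ROI; None = non-moving
    mean_cbf_hz: Optional[float]
    n_rois: int
    n_static: int
    status: str  # within_normal | below_normal | above_normal | static | insufficient
    mixed_motility: bool
    normal_range_hz: Tuple[float, float] = NORMAL_CBF_RANGE_HZ


def roi_cbf(trace: ROITrace, params: Optional[SpectralParams] = None) -> Optional[float]:
    """Dominant beat frequency of one ROI trace, or ``None`` if non-moving.

    The trace is treated as a one-pixel block: same detection band,
    taper and peak-over-noise-floor significance rule as the block maps.
    """
    if params is None:
        params = SpectralParams()
    spec = trace_spectrum(trace.intensity, trace.fps, params)
    result = classify_block(spec, params)
    return result.dominant_freq_hz if result.is_moving else None


def summarise_sample(
    traces: Sequence[ROITrace],
    params: Optional[SpectralParams] = None,
    sample_id: str = "sample",
    normal_range_hz: Tuple[float, float] = NORMAL_CBF_RANGE_HZ,
    min_rois: int = MIN_ROIS,
) -> CBFSummary:
    """Mean CBF over a sample's ROIs with status flags.

    Insufficient ROI count is a result (status ``insufficient``), not an
    error; the mean is still reported when computable.  The summary is
    invariant to the order of the traces.
    """
    if params is None:
        params = SpectralParams()
    freqs = tuple(roi_cbf(t, params) for t in traces)
    n = len(freqs)
    moving = [f for f in freqs if f is not None]
    n_static = n - len(moving)

    if moving:
        mean_cbf: Optional[float] = float(np.mean(moving))
    elif n > 0:
        mean_cbf = 0.0  # all-static convention
    else:
        mean_cbf = None

    low, high = normal_range_hz
    if n < min_rois:
        status = "insufficient"
    elif not moving:
        status = "static"
    elif mean_cbf < low:
        status = "below_normal"
    elif mean_cbf > high:
        status = "above_normal"
    else:
        status = "within_normal"

    return CBFSummary(
        sample_id=sample_id,
        per_roi_freq_hz=freqs,
        mean_cbf_hz=mean_cbf,
        n_rois=n,
        n_static=n_static,
        status=status,
        mixed_motility=0 < n_static < n,
        normal_range_hz=(float(low), float(high)),
    )


def read_roi_traces(path: Union[str, Path]) -> List[ROITrace]:
    """Read ROI traces from delimited text: one column per ROI.

    The time index is implicit; the frame rate comes from a leading
    comment line of the form ``# fps = 500``.
    """
    import io

    fps = None
    lines = Path(path).read_text().splitlines(keepends=True)
    body_start = 0
    for i, line in enumerate(lines):
        stripped = line.strip()
        if not stripped.startswith("#"):
            body_start = i
            break
        key, _, value = stripped[1:].partition("=")
        if key.strip().lower() == "fps":
            fps = float(value)
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    if fps is None:
        raise ValueError(f"frame rate unknown: {path} has no '# fps = ...' header line")
    return [ROITrace(roi_id=str(col), intensity=df[col].to_numpy(), fps=fps) for col in df.columns]


def write_cbf_summary(summary: CBFSummary, path: Union[str, Path]) -> None:
    """Serialise a summary as flat key-value text plus a per-ROI table."""
    lines = [
        f"sample_id = {summary.sample_id}",
        f"mean_cbf_hz = {'' if summary.mean_cbf_hz is None else f'{summary.mean_cbf_hz:.10g}'}",
        f"n_rois = {summary.n_rois}",
        f"n_static = {summary.n_static}",
        f"status = {summary.status}",
        f"mixed_motility = {summary.mixed_motility}",
        f"normal_range_hz = {summary.normal_range_hz[0]}-{summary.normal_range_hz[1]}",
        "",
        "roi_index,freq_hz,moving",
    ]
    for i, f in enumerate(summary.per_roi_freq_hz):
        lines.append(f"{i},{'' if f is None else f'{f:.10g}'},{f is not None}")
    Path(path).write_text("\n".join(lines) + "\n")
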