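"""Percent area of ciliary movement per field of view, and insert-level aggregation.

"Cilia coverage" is the fraction of the epithelial surface showing
detectable ciliary beating.  It is measured at the granularity of the
analysis blocks: a field of view's coverage is the percentage of blocks
classified as moving, and an insert's coverage is the unweighted mean of
its fields' percentages (fields sampled every 3rd position across the
insert midline, up to 16 fields).  Residual edge pixels excluded from
the tiling are likewise excluded from the denominator.

Fields contaminated by drifting particulates or mucus debris can be
excluded by the operator via an explicit flag; there is no automatic
debris detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .spectral import CBFMap

__all__ = [
    "CoverageResult",
    "CoverageSummary",
    "SamplingPlan",
    "percent_area_moving",
    "aggregate_coverage",
    "make_sampling_plan",
    "write_coverage_summary",
    "read_coverage_table",
]


@dataclass(frozen=True)
class CoverageResult:
    """Percent area of movement for one field of view."""

    fov_id: str
    percent_moving: float
    n_blocks_moving: int
    n_blocks_total: int
    mean_moving_freq_hz: Optional[float] = None
    excluded: bool = False  # operator flag: debris / moving particulates

    def __post_init__(self) -> None:
        if self.n_blocks_total <= 0:
            raise ValueError("a coverage result needs at least one block")
        expected = 100.0 * self.n_blocks_moving / self.n_blocks_total
        if abs(self.percent_moving - expected) > 1e-9:
            raise ValueError(
                f"inconsistent percent_moving {self.percent_moving} for "
                f"{self.n_blocks_moving}/{self.n_blocks_total} blocks"
            )


@dataclass(frozen=True)
class CoverageSummary:
    """Cross-field aggregate: the insert-level cilia-coverage surrogate."""

    per_fov: tuple
    mean_percent: float
    sd_percent: Optional[float]  # sample SD; absent when n_fov == 1
    n_fov: int
    n_excluded: int = 0


@dataclass(frozen=True)
class SamplingPlan:
    """Every-k-th field selection along the insert midline."""

    n_positions_available: int
    step: int
    selected_indices: tuple

    @property
    def n_fields(self) -> int:
        return len(self.selected_indices)


def percent_area_moving(cbf_map: CBFMap, excluded: bool = False) -> CoverageResult:
    """Fraction of analysis blocks moving in one field of view, as a percent."""
    total = cbf_map.grid.n_blocks
    if total == 0:
        raise ValueError("empty CBF map: no blocks to count")
    moving = cbf_map.n_blocks_moving
    if moving:
        mean_freq = float(np.nanmean(np.where(cbf_map.is_moving, cbf_map.dominant_freq_hz, np.nan)))
    else:
        mean_freq = None
    return CoverageResult(
        fov_id=cbf_map.fov_id,
        percent_moving=100.0 * moving / total,
        n_blocks_moving=moving,
        n_blocks_total=total,
        mean_moving_freq_hz=mean_freq,
        excluded=excluded,
    )


def aggregate_coverage(results: Sequence[CoverageResult]) -> CoverageSummary:
    """Unweighted mean (± sample SD) of per-field percentages.

    Fields carrying the operator ``excluded`` flag are dropped before
    averaging but remain listed in ``per_fov``.  Fields are weighted
    equally even if their block counts differ.
    """
    results = list(results)
    if not results:
        raise ValueError("no coverage results to aggregate")
    kept = [r for r in results if not r.excluded]
    if not kept:
        raise ValueError("all fields of view are excluded; nothing to aggregate")
    percents = np.array([r.percent_moving for r in kept], dtype=float)
    sd = float(np.std(percents, ddof=1)) if len(percents) > 1 else None
    return CoverageSummary(
        per_fov=tuple(results),
        mean_percent=float(percents.mean()),
        sd_percent=sd,
        n_fov=len(kept),
        n_excluded=len(results) - len(kept),
    )


def make_sampling_plan(
    n_positions_available: int, step: int = 3, max_fields: int = 16
) -> SamplingPlan:
    """Deterministically pick every ``step``-th position from index 0.

    Selection is truncated at ``max_fields`` (16 fields by default,
    matching the standard insert-midline protocol).
    """
    if n_positions_available < 1:
        raise ValueError("need at least one available position")
    if step < 1:
        raise ValueError("step must be >= 1")
    indices = tuple(range(0, n_positions_available, step))[:max_fields]
    return SamplingPlan(
        n_positions_available=n_positions_available, step=step, selected_indices=indices
    )


def _results_frame(results: Iterable[CoverageResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fov_id": r.fov_id,
                "percent_moving": r.percent_moving,
                "n_blocks_moving": r.n_blocks_moving,
                "n_blocks_total": r.n_blocks_total,
                "mean_moving_freq_hz": r.mean_moving_freq_hz,
                "excluded": r.excluded,
            }
            for r in results
        ]
    )


def write_coverage_summary(summary: CoverageSummary, path: Union[str, Path]) -> None:
    """Serialise per-FOV rows plus a trailing summary block, as flat text."""
    df = _results_frame(summary.per_fov)
    with open(path, "w") as fh:
        df.to_csv(fh, index=False, float_format="%.10g")
        fh.write(f"# mean_percent = {summary.mean_percent:.10g}\n")
        sd = "" if summary.sd_percent is None else f"{summary.sd_percent:.10g}"
        fh.write(f"# sd_percent = {sd}\n")
        fh.write(f"# n_fov = {summary.n_fov}\n")
        fh.write(f"# n_excluded = {summary.n_excluded}\n")


def read_coverage_table(path: Union[str, Path]) -> List[CoverageResult]:
    """Read per-FOV coverage rows back from a serialised table."""
    df = pd.read_csv(path, comment="#")
    out = []
    for _, row in df.iterrows():
        freq = row.get("mean_moving_freq_hz")
        out.append(
            CoverageResult(
                fov_id=str(row["fov_id"]),
                # counts are the source of truth; the serialised percent may
                # carry fewer digits than the exact ratio
                percent_moving=100.0 * int(row["n_blocks_moving"]) / int(row["n_blocks_total"]),
                n_blocks_moving=int(row["n_blocks_moving"]),
                n_blocks_total=int(row["n_blocks_total"]),
                mean_moving_freq_hz=None if pd.isna(freq) else float(freq),
                excluded=bool(row.get("excluded", False)),
            )
        )
    return out
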