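"""Trans-epithelial electrical resistance (TEER) of culture inserts.

TEER quantifies epithelial barrier integrity.  The convention: take the
mean of (typically three) resistance readings on the test insert,
subtract the mean reading of a cell-free blank insert, and multiply by
the membrane growth area:

    TEER (Ω·cm²) = (mean(test Ω) − mean(blank Ω)) × area (cm²)

The membrane area is a required input — insert formats differ (12 mm
and 6.5 mm Transwells are common) and manufacturers state the growth
area, so no default is assumed.  A negative corrected resistance is
returned (it carries information about a failed blank) but flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["TEERMeasurement", "compute_teer", "read_teer_table", "teer_table", "summarise_teer"]


@dataclass(frozen=True)
class TEERMeasurement:
    """One insert's readings and its derived area-normalised resistance."""

    test_readings_ohm: tuple
    blank_readings_ohm: tuple
    membrane_area_cm2: float
    result_ohm_cm2: float
    mean_test_ohm: float
    mean_blank_ohm: float
    negative: bool  # corrected resistance fell below zero


def compute_teer(
    test: Sequence[float], blank: Sequence[float], area_cm2: float
) -> TEERMeasurement:
    """Blank-corrected, area-normalised resistance of one insert.

    Warns (does not fail) when either reading set departs from the
    triplicate convention.
    """
    test = tuple(float(x) for x in test)
    blank = tuple(float(x) for x in blank)
    if not test or not blank:
        raise ValueError("need at least one test and one blank reading")
    if area_cm2 <= 0 or not np.isfinite(area_cm2):
        raise ValueError(f"membrane area must be positive, got {area_cm2}")
    for name, readings in (("test", test), ("blank", blank)):
        if any(not np.isfinite(x) or x < 0 for x in readings):
            raise ValueError(f"{name} readings must be finite and non-negative")
        if len(readings) != 3:
            warnings.warn(
                f"{name} insert has {len(readings)} readings; the convention is triplicate",
                stacklevel=2,
            )
    mean_test = float(np.mean(test))
    mean_blank = float(np.mean(blank))
    corrected = mean_test - mean_blank
    result = corrected * area_cm2
    return TEERMeasurement(
        test_readings_ohm=test,
        blank_readings_ohm=blank,
        membrane_area_cm2=float(area_cm2),
        result_ohm_cm2=result,
        mean_test_ohm=mean_test,
        mean_blank_ohm=mean_blank,
        negative=corrected < 0,
    )


def read_teer_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a delimited TEER table: one row per insert.

    Required columns: ``test_1..test_n``, ``blank_1..blank_n`` and
    ``area_cm2``; optional ``insert_id`` and ``group``.
    """
    df = pd.read_csv(path, comment="#")
    if "area_cm2" not in df.columns:
        raise ValueError(f"{path}: missing required 'area_cm2' column")
    if not any(c.startswith("test_") for c in df.columns):
        raise ValueError(f"{path}: no 'test_*' reading columns")
    if not any(c.startswith("blank_") for c in df.columns):
        raise ValueError(f"{path}: no 'blank_*' reading columns")
    return df


def teer_table(df: pd.DataFrame) -> pd.DataFrame:
    """Compute TEER per insert row; appends result and flag columns."""
    test_cols = sorted(c for c in df.columns if c.startswith("test_"))
    blank_cols = sorted(c for c in df.columns if c.startswith("blank_"))
    out = df.copy()
    results, negatives = [], []
    for _, row in df.iterrows():
        test = [row[c] for c in test_cols if pd.notna(row[c])]
        blank = [row[c] for c in blank_cols if pd.notna(row[c])]
        m = compute_teer(test, blank, float(row["area_cm2"]))
        results.append(m.result_ohm_cm2)
        negatives.append(m.negative)
    out["teer_ohm_cm2"] = results
    out["negative_flag"] = negatives
    return out


def summarise_teer(computed: pd.DataFrame, by: Optional[str] = "group") -> pd.DataFrame:
    """Mean ± sample SD of TEER, overall or per group."""
    if by is not None and by in computed.columns:
        grouped = computed.groupby(by)["teer_ohm_cm2"]
        return grouped.agg(mean_ohm_cm2="mean", sd_ohm_cm2=lambda s: s.std(ddof=1), n="count").reset_index()
    s = computed["teer_ohm_cm2"]
    return pd.DataFrame(
        {"mean_ohm_cm2": [s.mean()], "sd_ohm_cm2": [s.std(ddof=1)], "n": [len(s)]}
    )
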