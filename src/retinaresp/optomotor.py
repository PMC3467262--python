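"""Optomotor contrast sensitivity: Michelson contrast and CSF summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastMeasurement",
    "michelson_contrast",
    "contrast_sensitivity",
    "contrast_percent",
    "summarize_csf",
    "DEFAULT_SPATIAL_FREQUENCIES",
]

#: Spatial frequencies (cyc/deg) at which contrast thresholds are measured.
DEFAULT_SPATIAL_FREQUENCIES = (0.031, 0.064, 0.092, 0.103, 0.192, 0.272)


@dataclass(frozen=True)
class ContrastMeasurement:
    lum_max: float
    lum_min: float
    spatial_frequency: float | None = None

    @property
    def contrast(self) -> float:
        return michelson_contrast(self.lum_max, self.lum_min)

    @property
    def sensitivity(self) -> float:
        return contrast_sensitivity(self.contrast)


def michelson_contrast(lum_max: float, lum_min: float) -> float:
    """``(max - min) / (max + min)`` of two luminances (cd/m²)."""
    if lum_min < 0 or lum_max < lum_min:
        raise ValueError("need lum_max >= lum_min >= 0")
    if lum_max + lum_min == 0:
        raise ValueError("contrast undefined for two zero luminances")
    return (lum_max - lum_min) / (lum_max + lum_min)


def contrast_sensitivity(threshold_contrast: float) -> float:
    """Reciprocal of the threshold Michelson contrast."""
    if not 0 < threshold_contrast <= 1:
        raise ValueError("threshold_contrast must be in (0, 1]")
    return 1.0 / threshold_contrast


def contrast_percent(threshold_contrast: float, decimals: int = 1) -> float:
    """Threshold contrast as a percentage, rounded for display."""
    return round(100.0 * threshold_contrast, decimals)


def summarize_csf(
    thresholds: pd.DataFrame,
    group_col: str = "genotype",
    equal_var: bool = False,
) -> tuple[pd.DataFrame, float | None]:
    """Contrast-sensitivity-function summary from a threshold table.

    ``thresholds`` needs columns ``spatial_frequency`` and
    ``threshold_contrast`` (one row per animal x frequency); an optional
    group column triggers per-frequency two-sample t-tests (Welch by
    default, pooled variance with ``equal_var=True``).

    Returns the per-frequency summary table and the peak frequency (the
    frequency with the highest mean sensitivity; ``None`` with fewer than
    two frequencies).
    """
    df = thresholds.copy()
    if not {"spatial_frequency", "threshold_contrast"} <= set(df.columns):
        raise ValueError("need columns spatial_frequency and threshold_contrast")
    df["sensitivity"] = 1.0 / df["threshold_contrast"]

    rows = []
    groups = sorted(df[group_col].unique()) if group_col in df.columns else []
    for sf, sub in df.groupby("spatial_frequency"):
        row = {
            "spatial_frequency": sf,
            "mean_sensitivity": sub["sensitivity"].mean(),
            "sem_sensitivity": stats.sem(sub["sensitivity"]) if len(sub) > 1 else np.nan,
            "n": len(sub),
        }
        if len(groups) == 2:
            a = sub.loc[sub[group_col] == groups[0], "sensitivity"]
            b = sub.loc[sub[group_col] == groups[1], "sensitivity"]
            for g, vals in zip(groups, (a, b)):
                row[f"mean_{g}"] = vals.mean()
                row[f"sem_{g}"] = stats.sem(vals) if len(vals) > 1 else np.nan
            if len(a) > 1 and len(b) > 1:
                t, p = stats.ttest_ind(a, b, equal_var=equal_var)
                row["t"], row["p"] = t, p
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("spatial_frequency").reset_index(drop=True)

    peak = None
    if len(table) >= 2:
        peak = float(table.loc[table["mean_sensitivity"].idxmax(), "spatial_frequency"])
    return table, peak
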