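"""Stimulus-series aggregation and group comparison.

Per-cell response metrics are collected across an ordered stimulus series
(spot size, intensity, or flicker frequency), amplitudes are normalized to
the per-cell maximum, and genotype groups are compared with a
repeated-measures two-way ANOVA (group x level, level repeated within
cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy.ndimage import gaussian_filter1d

from .core import SpikeTrain
from .psth import ResponseMetrics, StimulusEpoch, response_metrics

__all__ = [
    "StimulusSeries",
    "SeriesResult",
    "GroupComparison",
    "analyze_series",
    "flicker_amplitude",
    "compare_genotypes",
    "normalize_amplitudes",
    "spot_size_series",
    "intensity_series",
    "flicker_series",
]

SERIES_KINDS = ("spot_size", "intensity", "flicker")


@dataclass(frozen=True)
class StimulusSeries:
    kind: str
    levels: tuple[float, ...]
    fixed_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SERIES_KINDS:
            raise ValueError(f"kind must be one of {SERIES_KINDS}")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly increasing")


def spot_size_series() -> StimulusSeries:
    """Spot diameters 75-1700 µm at fixed 6.9 cd*s/m² intensity."""
    return StimulusSeries(
        "spot_size", (75, 150, 300, 600, 1200, 1700), {"intensity_cds_m2": 6.9}
    )


def intensity_series() -> StimulusSeries:
    """Flash intensities -4.0 to 2.0 log cd*s/m² at a 300 µm spot."""
    return StimulusSeries(
        "intensity", (-4.0, -3.0, -2.0, -1.0, 0.0, 1.0, 2.0), {"spot_size_um": 300}
    )


def flicker_series() -> StimulusSeries:
    """Flicker frequencies 1-15 Hz at a 300 µm spot, 6.9 cd*s/m²."""
    return StimulusSeries(
        "flicker", (1, 2, 3, 5, 7, 10, 12, 15),
        {"spot_size_um": 300, "intensity_cds_m2": 6.9},
    )


@dataclass
class SeriesResult:
    series: StimulusSeries
    metrics: dict[float, ResponseMetrics | None]
    normalized_a: dict[float, float] = field(default_factory=dict)
    preferred_level: float | None = None
    responsive: bool = True


@dataclass
class GroupComparison:
    """Group main effect of a two-group repeated-measures ANOVA."""

    f_stat: float
    df1: int
    df2: int
    p_value: float
    within_eps: float | None = None  # Greenhouse-Geisser epsilon (within factor)
    within_p_gg: float | None = None


def analyze_series(
    trains_by_level: dict[float, SpikeTrain | None],
    series: StimulusSeries,
    epoch: StimulusEpoch | None = None,
    **metric_kwargs,
) -> SeriesResult:
    """Response metrics per stimulus level, normalized amplitude, preferred level.

    Missing levels (``None`` values) are recorded as absent, never imputed.
    The preferred level is the argmax of A1 with ties broken toward the
    smaller stimulus.
    """
    if epoch is None:
        epoch = StimulusEpoch()
    metrics: dict[float, ResponseMetrics | None] = {}
    for level in series.levels:
        train = trains_by_level.get(level)
        metrics[level] = (
            None if train is None else response_metrics(train, epoch, **metric_kwargs)
        )
    result = SeriesResult(series=series, metrics=metrics)
    amps = {
        lvl: m.a1 for lvl, m in metrics.items() if m is not None and m.a1_responsive
    }
    positive = {lvl: a for lvl, a in amps.items() if a > 0}
    if not positive:
        result.responsive = False
        return result
    best = max(positive.values())
    # ties toward the smaller level
    result.preferred_level = min(lvl for lvl, a in positive.items() if a == best)
    return normalize_amplitudes(result)


def normalize_amplitudes(result: SeriesResult) -> SeriesResult:
    """Divide each level's A1 by the per-cell maximum (idempotent)."""
    amps = {
        lvl: m.a1
        for lvl, m in result.metrics.items()
        if m is not None and m.a1_responsive
    }
    max_a = max(amps.values(), default=0.0)
    if max_a <= 0:
        result.responsive = False
        result.normalized_a = {}
        return result
    result.normalized_a = {lvl: max(a, 0.0) / max_a for lvl, a in amps.items()}
    return result


def flicker_amplitude(
    train: SpikeTrain,
    frequency: float,
    n_bins: int = 50,
    smooth_bins: float = 2.0,
) -> float:
    """Cycle-peak minus cycle-minimum of the period-folded rate histogram.

    The cycle histogram is smoothed with a wrap-around Gaussian; the cycle
    minimum stands in for the baseline since a periodic stimulus has no
    pre-stimulus window.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    duration = train.block_duration
    if duration is None:
        raise ValueError("train needs a block_duration to count cycles")
    n_cycles = duration * frequency
    if n_cycles < 5:
        raise ValueError(f"need >=5 complete cycles, got {n_cycles:.1f}")
    n_cycles = int(np.floor(n_cycles))
    period = 1.0 / frequency

    ts = train.all_timestamps()
    ts = ts[ts < n_cycles * period]  # complete cycles only
    phase = np.mod(ts, period)
    edges = np.linspace(0.0, period, n_bins + 1)
    counts, _ = np.histogram(phase, bins=edges)
    bin_w = period / n_bins
    rates = counts / (train.n_blocks * n_cycles * bin_w)
    smoothed = gaussian_filter1d(rates, smooth_bins, mode="wrap")
    return float(smoothed.max() - smoothed.min())


def compare_genotypes(
    group_a: np.ndarray,
    group_b: np.ndarray,
    levels: tuple[float, ...] | None = None,
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Repeated-measures two-way ANOVA; returns the group main effect.

    ``group_a`` / ``group_b`` are (n_cells, n_levels) arrays of one metric
    measured at the same stimulus levels in every cell.  The test is a
    split-plot (mixed) ANOVA with group as the between-cell factor and
    level as the repeated within-cell factor; the Greenhouse-Geisser
    epsilon for the within factor is reported alongside.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"unbalanced level sets: group a has {a.shape[1]} levels, "
            f"group b has {b.shape[1]}"
        )
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >=2 cells per group")
    n_levels = a.shape[1]
    if levels is None:
        levels = tuple(range(n_levels))

    frames = []
    for label, block in zip(labels, (a, b)):
        n = block.shape[0]
        frames.append(
            pd.DataFrame(
                {
                    "subject": np.repeat([f"{label}{i}" for i in range(n)], n_levels),
                    "group": label,
                    "level": np.tile(levels, n),
                    "value": block.ravel(),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    aov = pg.mixed_anova(
        df, dv="value", within="level", subject="subject", between="group",
        correction=True,
    )
    grp = aov.loc[aov["Source"] == "group"].iloc[0]
    within = aov.loc[aov["Source"] == "level"].iloc[0]
    return GroupComparison(
        f_stat=float(grp["F"]),
        df1=int(grp["DF1"]),
        df2=int(grp["DF2"]),
        p_value=float(grp["p-unc"]) if "p-unc" in grp else float(grp["p_unc"]),
        within_eps=float(within.get("eps", np.nan)),
        within_p_gg=(
            float(within["p-GG-corr"]) if "p-GG-corr" in within.index else None
        ),
    )
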