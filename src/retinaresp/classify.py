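"""Ganglion-cell classification from response metrics.

Polarity comes from the bias index of the ON and OFF response amplitudes;
kinetics (transient vs sustained) from the ON response duration against a
200 ms boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

from .psth import ResponseMetrics

__all__ = [
    "NonResponsiveError",
    "CellClassification",
    "bias_index",
    "classify_polarity",
    "classify_kinetics",
    "classify_cell",
]

#: ON-response duration boundary (ms) separating transient from sustained.
KINETICS_BOUNDARY_MS = 200.0

#: Default symmetric polarity thresholds (tertile split of the BI range).
DEFAULT_BI_THRESHOLDS = (-1.0 / 3.0, 1.0 / 3.0)


class NonResponsiveError(ValueError):
    """Both response amplitudes are zero; the bias index is undefined."""


@dataclass
class CellClassification:
    bi: float | None
    polarity: str  # ON | OFF | ON-OFF | non-responsive
    kinetics: str  # transient | sustained | n/a
    tau2_censored: bool = False


def bias_index(a1: float, a2: float) -> float:
    """``(A1 - A2) / (A1 + A2)`` after clamping negative amplitudes to 0.

    Clamping keeps the index inside [-1, 1] when a baseline-corrected
    amplitude comes out negative.
    """
    a1 = max(a1, 0.0)
    a2 = max(a2, 0.0)
    if a1 + a2 == 0:
        raise NonResponsiveError("A1 + A2 = 0: bias index undefined")
    return (a1 - a2) / (a1 + a2)


def classify_polarity(
    bi: float, thresholds: tuple[float, float] = DEFAULT_BI_THRESHOLDS
) -> str:
    """ON above the upper threshold, OFF below the lower, else ON-OFF."""
    lower, upper = thresholds
    if not lower < upper:
        raise ValueError(f"thresholds must satisfy lower < upper, got {thresholds}")
    if bi >= upper:
        return "ON"
    if bi <= lower:
        return "OFF"
    return "ON-OFF"


def classify_kinetics(
    a1_tau2_ms: float,
    censored: bool = False,
    boundary_ms: float = KINETICS_BOUNDARY_MS,
) -> str:
    """Transient iff the ON response duration is below the boundary.

    A censored duration (no criterion crossing before the window end) is a
    lower bound, so the cell is classified sustained.  Exactly at the
    boundary the cell is sustained (tie rule; the source criterion uses
    strict inequalities on both sides and leaves the boundary open).
    """
    if censored:
        return "sustained"
    return "transient" if a1_tau2_ms < boundary_ms else "sustained"


def classify_cell(
    metrics: ResponseMetrics,
    thresholds: tuple[float, float] = DEFAULT_BI_THRESHOLDS,
    kinetics_boundary_ms: float = KINETICS_BOUNDARY_MS,
) -> CellClassification:
    """Full classification of one cell from its response metrics.

    Amplitudes flagged non-responsive are treated as 0 for the bias index;
    kinetics is assigned only to ON-polarity cells.
    """
    a1 = metrics.a1 if metrics.a1_responsive else 0.0
    a2 = metrics.a2 if metrics.a2_responsive else 0.0
    try:
        bi = bias_index(a1, a2)
    except NonResponsiveError:
        return CellClassification(None, "non-responsive", "n/a")
    polarity = classify_polarity(bi, thresholds)
    if polarity == "ON":
        kinetics = classify_kinetics(
            metrics.a1_tau2_ms, metrics.a1_censored, kinetics_boundary_ms
        )
        return CellClassification(bi, polarity, kinetics, metrics.a1_censored)
    return CellClassification(bi, polarity, "n/a")
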