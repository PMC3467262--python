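"""Peri-stimulus time histograms and response parameterization.

The response of a unit is summarized by six numbers: a baseline-corrected
peak rate, a latency to that peak, and a decay time to the ``peak/e``
criterion level — once for the window following stimulus onset (A1, L1,
A1tau2) and once for the window following stimulus offset (A2, L2, A2tau2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import SpikeTrain

__all__ = [
    "StimulusEpoch",
    "PSTH",
    "LobeMetrics",
    "ResponseMetrics",
    "build_psth",
    "smooth_psth",
    "estimate_baseline",
    "extract_on_metrics",
    "extract_off_metrics",
    "response_metrics",
]

#: Length of the pre-onset window used for the baseline estimate (s).
BASELINE_WINDOW_S = 0.100

#: How far past stimulus offset the ON-response search window extends (s).
ON_WINDOW_PAD_S = 0.050


@dataclass(frozen=True)
class StimulusEpoch:
    """One stimulus presentation within a recording block.

    Defaults follow the spot-stimulation protocol: 2 s blocks containing a
    300 ms stimulus that starts 100 ms into the block, repeated 5 times.
    """

    onset: float = 0.100
    offset: float = 0.400
    spot_size: float = 300.0
    intensity: float | None = None
    frequency: float | None = None
    n_blocks: int = 5
    block_duration: float = 2.0

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must be after onset")
        if self.block_duration < self.offset:
            raise ValueError("block_duration must cover the stimulus")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class PSTH:
    """Trial-averaged firing-rate histogram.

    ``rates`` holds the per-bin firing rate in Hz; bin ``i`` covers
    ``[t0 + i*bw, t0 + (i+1)*bw)`` with ``bw = bin_width_ms / 1000``.
    """

    rates: np.ndarray
    bin_width_ms: float = 1.0
    t0: float = 0.0
    smoothing_sigma_ms: float | None = None
    n_blocks_averaged: int = 1

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.bin_width_ms <= 0:
            raise ValueError("bin_width_ms must be positive")

    @property
    def bin_width_s(self) -> float:
        return self.bin_width_ms / 1000.0

    @property
    def bin_centers(self) -> np.ndarray:
        bw = self.bin_width_s
        return self.t0 + (np.arange(self.rates.size) + 0.5) * bw

    @property
    def bin_edges(self) -> np.ndarray:
        bw = self.bin_width_s
        return self.t0 + np.arange(self.rates.size + 1) * bw

    def spike_counts(self) -> np.ndarray:
        """Reconstruct per-bin pooled spike counts (exact if unsmoothed)."""
        return self.rates * self.bin_width_s * self.n_blocks_averaged


@dataclass
class LobeMetrics:
    """Amplitude / latency / decay triple for one response lobe."""

    amplitude: float
    latency_ms: float
    tau2_ms: float
    censored: bool = False
    responsive: bool = True


@dataclass
class ResponseMetrics:
    """The six response parameters plus the baseline firing rate."""

    baseline: float
    a1: float
    l1_ms: float
    a1_tau2_ms: float
    a2: float
    l2_ms: float
    a2_tau2_ms: float
    a1_censored: bool = False
    a2_censored: bool = False
    a1_responsive: bool = True
    a2_responsive: bool = True


def build_psth(
    train: SpikeTrain,
    epoch: StimulusEpoch,
    bin_width_ms: float = 1.0,
    duration: float | None = None,
) -> PSTH:
    """Bin pooled block timestamps into a trial-averaged rate histogram.

    Per-bin rate is ``count / (n_blocks * bin_width)`` so that an
    unsmoothed PSTH exactly conserves spike counts.
    """
    if bin_width_ms <= 0:
        raise ValueError("bin_width_ms must be positive")
    n_blocks = max(train.n_blocks, 1)
    if duration is None:
        duration = train.block_duration or epoch.block_duration
    bw = bin_width_ms / 1000.0
    n_bins = int(round(duration / bw))
    edges = np.arange(n_bins + 1) * bw
    ts = train.all_timestamps()
    if ts.size == 0:
        warnings.warn("empty spike train: returning all-zero PSTH", stacklevel=2)
        counts = np.zeros(n_bins)
    else:
        counts, _ = np.histogram(ts, bins=edges)
    rates = counts / (n_blocks * bw)
    return PSTH(rates=rates, bin_width_ms=bin_width_ms, t0=0.0, n_blocks_averaged=n_blocks)


def smooth_psth(psth: PSTH, sigma_ms: float = 25.0) -> PSTH:
    """Gaussian-smooth a PSTH (kernel standard deviation in ms).

    Boundaries are reflection-padded; total rate mass is conserved away
    from the edges.
    """
    if sigma_ms <= 0:
        raise ValueError("sigma_ms must be positive")
    sigma_bins = sigma_ms / psth.bin_width_ms
    smoothed = gaussian_filter1d(psth.rates, sigma_bins, mode="reflect")
    return replace(psth, rates=smoothed, smoothing_sigma_ms=sigma_ms)


def estimate_baseline(psth: PSTH, epoch: StimulusEpoch) -> float:
    """Mean rate over the 100 ms window immediately preceding stimulus onset."""
    start = epoch.onset - BASELINE_WINDOW_S
    if start < psth.t0 - 1e-12:
        raise ValueError(
            f"PSTH must cover at least {BASELINE_WINDOW_S * 1000:.0f} ms "
            f"before onset (needs data from t={start:.3f} s)"
        )
    centers = psth.bin_centers
    mask = (centers >= start) & (centers < epoch.onset)
    if not mask.any():
        raise ValueError("no PSTH bins fall in the pre-onset baseline window")
    return float(psth.rates[mask].mean())


def _baseline_se(psth: PSTH, epoch: StimulusEpoch) -> float:
    """Standard error of the mean over the baseline-window bins."""
    centers = psth.bin_centers
    mask = (centers >= epoch.onset - BASELINE_WINDOW_S) & (centers < epoch.onset)
    vals = psth.rates[mask]
    if vals.size < 2:
        return 0.0
    return float(vals.std(ddof=1) / np.sqrt(vals.size))


def _extract_lobe(
    psth: PSTH,
    baseline: float,
    anchor: float,
    window: tuple[float, float],
    response_se: float,
) -> LobeMetrics:
    """Peak / latency / decay extraction within ``window`` (s, absolute).

    The decay time tau2 is measured from the peak to the first subsequent
    crossing of the baseline-corrected rate below ``amplitude / e``, with
    linear interpolation between bin centers.  If no crossing occurs before
    the window end the value is censored at the remaining window length.
    """
    centers = psth.bin_centers
    corrected = psth.rates - baseline
    mask = (centers >= window[0]) & (centers <= window[1])
    if not mask.any():
        raise ValueError("search window contains no PSTH bins")
    idx = np.flatnonzero(mask)
    peak_rel = int(np.argmax(corrected[idx]))
    peak_idx = idx[peak_rel]
    amplitude = float(corrected[peak_idx])
    latency_ms = (centers[peak_idx] - anchor) * 1000.0

    responsive = amplitude > 2.0 * response_se

    criterion = amplitude / np.e
    tail = idx[peak_rel:]
    below = corrected[tail] < criterion
    censored = True
    cross_t = centers[tail[-1]]
    if below.any():
        j = int(np.argmax(below))
        if j > 0:
            t_hi, t_lo = centers[tail[j - 1]], centers[tail[j]]
            v_hi, v_lo = corrected[tail[j - 1]], corrected[tail[j]]
            frac = (v_hi - criterion) / (v_hi - v_lo) if v_hi != v_lo else 0.0
            cross_t = t_hi + frac * (t_lo - t_hi)
            censored = False
        else:  # peak bin itself below criterion (flat / non-responsive)
            cross_t = centers[peak_idx]
            censored = False
    tau2_ms = max((cross_t - centers[peak_idx]) * 1000.0, 0.0)
    return LobeMetrics(amplitude, max(latency_ms, 0.0), tau2_ms, censored, responsive)


def extract_on_metrics(
    psth: PSTH, baseline: float, epoch: StimulusEpoch
) -> LobeMetrics:
    """A1 / L1 / A1tau2 from the window following stimulus onset.

    The search window runs from onset to 50 ms past offset (configurable
    only through the module constant; the underlying protocol never states
    a window).
    """
    se = _baseline_se(psth, epoch)
    window = (epoch.onset, epoch.offset + ON_WINDOW_PAD_S)
    return _extract_lobe(psth, baseline, epoch.onset, window, se)


def extract_off_metrics(
    psth: PSTH, baseline: float, epoch: StimulusEpoch
) -> LobeMetrics:
    """A2 / L2 / A2tau2 from the window following stimulus offset."""
    se = _baseline_se(psth, epoch)
    end = psth.t0 + psth.rates.size * psth.bin_width_s
    window = (epoch.offset + psth.bin_width_s, end)
    return _extract_lobe(psth, baseline, epoch.offset, window, se)


def response_metrics(
    train: SpikeTrain,
    epoch: StimulusEpoch,
    bin_width_ms: float = 1.0,
    smoothing_sigma_ms: float = 25.0,
) -> ResponseMetrics:
    """Full pipeline for one unit: PSTH, smoothing, baseline, both lobes."""
    psth = build_psth(train, epoch, bin_width_ms=bin_width_ms)
    sm = smooth_psth(psth, smoothing_sigma_ms)
    baseline = estimate_baseline(sm, epoch)
    on = extract_on_metrics(sm, baseline, epoch)
    off = extract_off_metrics(sm, baseline, epoch)
    return ResponseMetrics(
        baseline=baseline,
        a1=on.amplitude,
        l1_ms=on.latency_ms,
        a1_tau2_ms=on.tau2_ms,
        a2=off.amplitude,
        l2_ms=off.latency_ms,
        a2_tau2_ms=off.tau2_ms,
        a1_censored=on.censored,
        a2_censored=off.censored,
        a1_responsive=on.responsive,
        a2_responsive=off.responsive,
    )
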