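"""Flash electroretinogram metrics: a-/b-wave extraction and flicker series.

The b-wave amplitude is measured from the trough of the a-wave to the
following positive peak; b-wave latency is the time from flash onset to
that peak.  For dim flashes with no negative a-deflection the pre-flash
baseline level stands in for the trough.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "ERGTrace",
    "ERGMetrics",
    "FlickerSeries",
    "measure_single_flash",
    "analyze_flicker",
    "DEFAULT_FLICKER_FREQUENCIES",
]

#: Flash frequencies of the flicker protocol (Hz).
DEFAULT_FLICKER_FREQUENCIES = (0.5, 1, 2, 3, 5, 7, 10, 12, 15, 18, 20, 30)

#: Search window for the a-wave trough, ms after flash onset.
DEFAULT_A_WINDOW_MS = (5.0, 50.0)

#: End of the b-wave search window, ms after flash onset.
DEFAULT_B_WINDOW_END_MS = 150.0


@dataclass
class ERGTrace:
    """Flash-aligned voltage trace; time in ms relative to flash onset."""

    time_ms: np.ndarray
    voltage_uv: np.ndarray
    intensity: float | None = None
    adaptation: str = "scotopic"
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_uv = np.asarray(self.voltage_uv, dtype=float)
        if self.time_ms.shape != self.voltage_uv.shape:
            raise ValueError("time and voltage must have equal length")
        if self.time_ms.size >= 2:
            dt = np.diff(self.time_ms)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("trace must be uniformly sampled")
        if self.adaptation not in ("scotopic", "photopic"):
            raise ValueError("adaptation must be 'scotopic' or 'photopic'")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def sampling_rate(self) -> float:
        return 1000.0 / self.dt_ms


@dataclass
class ERGMetrics:
    """a-/b-wave summary of one single-flash trace."""

    a_amplitude: float  # baseline-to-trough magnitude, µV
    b_amplitude: float  # trough-to-peak, µV
    b_latency_ms: float  # onset-to-peak, ms (nan when flagged)
    a_latency_ms: float = float("nan")
    flat: bool = False


@dataclass
class FlickerSeries:
    """Per-frequency flicker amplitudes and the estimated fusion frequency."""

    frequencies: np.ndarray
    amplitudes: np.ndarray
    fusion_frequency: float | None = None
    all_noise: bool = False

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")


def _smooth(voltage: np.ndarray, dt_ms: float, sigma_ms: float) -> np.ndarray:
    if sigma_ms <= 0:
        return voltage
    return gaussian_filter1d(voltage, sigma_ms / dt_ms, mode="nearest")


def measure_single_flash(
    trace: ERGTrace,
    a_window_ms: tuple[float, float] = DEFAULT_A_WINDOW_MS,
    b_window_end_ms: float = DEFAULT_B_WINDOW_END_MS,
    smooth_sigma_ms: float = 1.0,
) -> ERGMetrics:
    """Extract a-trough and b-peak metrics from one flash-aligned trace.

    A light Gaussian smoothing (default sigma 1 ms) is applied before the
    extremum search so oscillatory-potential peaks are not captured.
    """
    t = trace.time_ms
    if t[0] > a_window_ms[0] or t[-1] < b_window_end_ms:
        raise ValueError(
            f"trace [{t[0]:.1f}, {t[-1]:.1f}] ms does not span the search "
            f"windows (a: {a_window_ms}, b-end: {b_window_end_ms} ms)"
        )
    v = _smooth(trace.voltage_uv, trace.dt_ms, smooth_sigma_ms)

    pre = v[t < 0]
    baseline = float(pre.mean()) if pre.size else float(v[0])

    a_mask = (t >= a_window_ms[0]) & (t <= a_window_ms[1])
    a_idx = np.flatnonzero(a_mask)
    trough_idx = a_idx[int(np.argmin(v[a_idx]))]
    trough = float(v[trough_idx])
    a_latency = float(t[trough_idx])
    if trough >= baseline:  # no negative deflection: dim-flash convention
        trough = baseline
        a_latency = float("nan")

    b_start = t[trough_idx] if np.isfinite(a_latency) else 0.0
    b_mask = (t > b_start) & (t <= b_window_end_ms)
    b_idx = np.flatnonzero(b_mask)
    peak_idx = b_idx[int(np.argmax(v[b_idx]))]
    peak = float(v[peak_idx])

    a_amp = baseline - trough
    b_amp = peak - trough
    if np.isclose(a_amp, 0.0) and np.isclose(b_amp, 0.0):
        return ERGMetrics(0.0, 0.0, float("nan"), float("nan"), flat=True)
    return ERGMetrics(a_amp, b_amp, float(t[peak_idx]), a_latency)


def cycle_average(trace: ERGTrace, frequency: float, n_bins: int = 100) -> np.ndarray:
    """Average the post-onset trace over the stimulus period."""
    period_ms = 1000.0 / frequency
    t = trace.time_ms
    mask = t >= 0
    phase = np.mod(t[mask], period_ms) / period_ms
    v = trace.voltage_uv[mask]
    edges = np.linspace(0, 1, n_bins + 1)
    which = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=v, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    counts[counts == 0] = 1
    return sums / counts


def flicker_amplitude(trace: ERGTrace, frequency: float, n_bins: int = 100) -> float:
    """Trough-to-peak amplitude of the cycle-averaged waveform."""
    t = trace.time_ms
    n_cycles = (t[-1] - max(t[0], 0.0)) * frequency / 1000.0
    if n_cycles < 3:
        raise ValueError(f"need >=3 cycles, got {n_cycles:.1f} at {frequency} Hz")
    avg = cycle_average(trace, frequency, n_bins=n_bins)
    return float(avg.max() - avg.min())


def flicker_fundamental_amplitude(trace: ERGTrace, frequency: float) -> float:
    """Peak-to-peak amplitude of the fundamental Fourier component.

    Alternative flicker measure; the default is trough-to-peak of the
    cycle average (:func:`flicker_amplitude`).
    """
    t = trace.time_ms
    mask = t >= 0
    v = trace.voltage_uv[mask] - trace.voltage_uv[mask].mean()
    phase = 2 * np.pi * frequency * t[mask] / 1000.0
    c = np.mean(v * np.cos(phase))
    s = np.mean(v * np.sin(phase))
    return float(4.0 * np.hypot(c, s))  # 2*|component| peak-to-peak


def analyze_flicker(
    traces: dict[float, ERGTrace],
    noise_sd: float | None = None,
    noise_criterion_factor: float = 3.0,
    mode: str = "trough_to_peak",
) -> FlickerSeries:
    """Per-frequency flicker amplitudes and the fusion frequency.

    Fusion is the lowest frequency whose cycle-averaged amplitude falls
    below ``noise_criterion_factor`` times the pre-stimulus noise standard
    deviation.  ``noise_sd`` defaults to the pooled standard deviation of
    the pre-onset samples of all traces.
    """
    if not traces:
        raise ValueError("no flicker traces supplied")
    freqs = np.array(sorted(traces))
    if noise_sd is None:
        pre = [
            traces[f].voltage_uv[traces[f].time_ms < 0]
            for f in freqs
            if (traces[f].time_ms < 0).any()
        ]
        if not pre:
            raise ValueError("noise_sd not given and traces have no pre-onset samples")
        noise_sd = float(np.concatenate(pre).std(ddof=1))
    measure = (
        flicker_amplitude if mode == "trough_to_peak" else flicker_fundamental_amplitude
    )
    amps = np.array([measure(traces[f], f) for f in freqs])

    criterion = noise_criterion_factor * noise_sd
    below = amps < criterion
    fusion = float(freqs[int(np.argmax(below))]) if below.any() else None
    return FlickerSeries(freqs, amps, fusion, all_noise=bool(below.all()))
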