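"""File formats and configuration.

Everything on disk is delimited text (tab-separated) or JSON/YAML: spike
tables with columns ``unit_id, block, timestamp_s``, two-column traces
with a JSON sidecar, and a YAML analysis configuration that round-trips
losslessly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from .core import RawTrace, SpikeTrain
from .erg import ERGTrace

__all__ = [
    "AnalysisConfig",
    "load_config",
    "save_config",
    "read_spike_table",
    "write_spike_table",
    "read_trace",
    "write_trace",
    "read_erg_trace",
    "write_erg_trace",
]

SPIKE_COLUMNS = ("unit_id", "block", "timestamp_s")


@dataclass
class AnalysisConfig:
    """All tunable constants of the pipeline, with protocol defaults."""

    seed: int = 0
    out_dir: str = "results"
    # stimulus protocol
    stimulus_onset_s: float = 0.100
    stimulus_offset_s: float = 0.400
    block_duration_s: float = 2.0
    n_blocks: int = 5
    flicker_block_duration_s: float = 10.0
    # PSTH analysis
    bin_width_ms: float = 1.0
    smoothing_sigma_ms: float = 25.0
    # detection
    filter_low_hz: float = 300.0
    filter_high_hz: float = 5000.0
    detect_k_sigma: float = 2.8
    refractory_ms: float = 1.0
    sampling_rate_hz: float = 20000.0
    # classification
    bi_lower: float = -1.0 / 3.0
    bi_upper: float = 1.0 / 3.0
    kinetics_boundary_ms: float = 200.0
    # synthetic fixture
    n_cells_per_class: int = 20
    # ERG
    erg_a_window_ms: tuple[float, float] = (5.0, 50.0)
    erg_b_window_end_ms: float = 150.0
    erg_noise_criterion: float = 3.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["erg_a_window_ms"] = list(d["erg_a_window_ms"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "erg_a_window_ms" in d:
            d = {**d, "erg_a_window_ms": tuple(d["erg_a_window_ms"])}
        return cls(**d)


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig.from_dict(data)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def write_spike_table(
    trains: list[SpikeTrain] | SpikeTrain, path: str | Path, sep: str = "\t"
) -> None:
    if isinstance(trains, SpikeTrain):
        trains = [trains]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(SPIKE_COLUMNS)
        for train in trains:
            for block_idx, block in enumerate(train.blocks):
                for ts in block:
                    writer.writerow([train.unit_id, block_idx, repr(float(ts))])


def read_spike_table(
    path: str | Path, sep: str = "\t", block_duration: float | None = None
) -> dict[str, SpikeTrain]:
    """Parse a spike table into per-unit trains.

    Malformed rows are rejected with their line number; missing header
    columns are named in the error.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        missing = [c for c in SPIKE_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        idx = {c: header.index(c) for c in SPIKE_COLUMNS}

        data: dict[str, dict[int, list[float]]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                unit = row[idx["unit_id"]]
                block = int(row[idx["block"]])
                ts = float(row[idx["timestamp_s"]])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {row!r}") from exc
            data.setdefault(unit, {}).setdefault(block, []).append(ts)

    trains = {}
    for unit, blocks in data.items():
        n_blocks = max(blocks) + 1
        trains[unit] = SpikeTrain(
            unit_id=unit,
            blocks=[np.sort(blocks.get(i, [])) for i in range(n_blocks)],
            block_duration=block_duration,
        )
    return trains


def _sidecar(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_trace(trace: RawTrace, path: str | Path, sep: str = "\t") -> None:
    """Two-column (time_s, value_uv) text file plus a JSON sidecar."""
    times = trace.times
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["time_s", "voltage_uv"])
        for t, v in zip(times, trace.samples):
            writer.writerow([f"{t:.6f}", f"{v:.4f}"])
    meta = {"sampling_rate_hz": trace.sampling_rate, "units": "uV",
            "start_time_s": trace.start_time}
    if trace.true_spike_times is not None:
        meta["true_spike_times_s"] = [float(t) for t in trace.true_spike_times]
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_trace(path: str | Path, sep: str = "\t") -> RawTrace:
    arr = np.loadtxt(path, delimiter=sep, skiprows=1)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing trace sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    truth = meta.get("true_spike_times_s")
    return RawTrace(
        samples=arr[:, 1],
        sampling_rate=float(meta["sampling_rate_hz"]),
        start_time=float(meta.get("start_time_s", 0.0)),
        true_spike_times=None if truth is None else np.asarray(truth, dtype=float),
    )


def write_erg_trace(trace: ERGTrace, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["time_ms", "voltage_uv"])
        for t, v in zip(trace.time_ms, trace.voltage_uv):
            writer.writerow([f"{t:.4f}", f"{v:.4f}"])
    meta = {
        "intensity_log_cds_m2": trace.intensity,
        "adaptation": trace.adaptation,
        "ground_truth": trace.ground_truth,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_erg_trace(path: str | Path, sep: str = "\t") -> ERGTrace:
    arr = np.loadtxt(path, delimiter=sep, skiprows=1)
    sidecar = _sidecar(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ERGTrace(
        time_ms=arr[:, 0],
        voltage_uv=arr[:, 1],
        intensity=meta.get("intensity_log_cds_m2"),
        adaptation=meta.get("adaptation", "scotopic"),
        ground_truth=meta.get("ground_truth", {}),
    )
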