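"""Shared data containers used across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeTrain", "RawTrace"]


@dataclass
class SpikeTrain:
    """Spike timestamps of one unit over repeated stimulus blocks.

    Timestamps are in seconds relative to the start of each block.
    """

    unit_id: str
    blocks: list[np.ndarray]
    block_duration: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.blocks = [np.asarray(b, dtype=float) for b in self.blocks]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_spikes(self) -> int:
        return int(sum(b.size for b in self.blocks))

    def all_timestamps(self) -> np.ndarray:
        """Timestamps of all blocks pooled, still block-relative."""
        if not self.blocks:
            return np.empty(0)
        return np.concatenate(self.blocks)


@dataclass
class RawTrace:
    """Uniformly sampled extracellular voltage trace (microvolts)."""

    samples: np.ndarray
    sampling_rate: float = 20_000.0
    start_time: float = 0.0
    true_spike_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate
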