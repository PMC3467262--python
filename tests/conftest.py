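import numpy as np
import pytest

from retinaresp.psth import PSTH, StimulusEpoch
from retinaresp.synth import Lobe, RateProfile, evaluate_rate

#: Canonical fixture seed used by the classification and detection checks.
DEMO_SEED = 0


@pytest.fixture
def epoch() -> StimulusEpoch:
    return StimulusEpoch()


@pytest.fixture
def on_profile() -> RateProfile:
    """Noise-free reference profile: A=50 Hz, L=80 ms, tau=60 ms."""
    return RateProfile(baseline_rate=10.0, on_lobe=Lobe(50.0, 80.0, 60.0))


def exact_psth(profile: RateProfile, epoch: StimulusEpoch, bin_width_ms: float = 1.0) -> PSTH:
    """PSTH whose bin rates equal the generating profile exactly (no sampling)."""
    duration_ms = epoch.block_duration * 1000.0
    centers = np.arange(bin_width_ms / 2.0, duration_ms, bin_width_ms)
    rates = evaluate_rate(profile, centers, epoch)
    return PSTH(rates=rates, bin_width_ms=bin_width_ms)
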