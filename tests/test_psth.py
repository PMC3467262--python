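import numpy as np
import pytest

from retinaresp.core import SpikeTrain
from retinaresp.psth import (
    PSTH,
    StimulusEpoch,
    build_psth,
    estimate_baseline,
    extract_off_metrics,
    extract_on_metrics,
    response_metrics,
    smooth_psth,
)
from retinaresp.synth import Lobe, RateProfile, SyntheticCellSpec, simulate_spike_train

from conftest import exact_psth


class TestBuildPsth:
    def test_five_coincident_spikes_give_1000_hz(self, epoch):
        # one spike per block in the same 1 ms bin: 5 / (5 blocks x 1 ms)
        train = SpikeTrain("u", [np.array([0.2505])] * 5, block_duration=2.0)
        psth = build_psth(train, epoch)
        assert psth.rates.max() == pytest.approx(1000.0)
        assert (psth.rates > 0).sum() == 1

    def test_empty_train_warns_and_zeroes(self, epoch):
        train = SpikeTrain("u", [np.empty(0)] * 5, block_duration=2.0)
        with pytest.warns(UserWarning):
            psth = build_psth(train, epoch)
        assert np.all(psth.rates == 0)

    def test_count_conservation_integer(self, epoch):
        spec = SyntheticCellSpec(
            "ON-transient", RateProfile(20.0, Lobe(100, 80, 60)), n_blocks=5, seed=5
        )
        train = simulate_spike_train(spec, epoch)
        psth = build_psth(train, epoch)
        counts = psth.spike_counts()
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
        assert counts.sum() == pytest.approx(train.n_spikes)

    def test_constant_rate_mean(self, epoch):
        spec = SyntheticCellSpec(
            "ON-transient", RateProfile(100.0, Lobe(1e-9, 80, 60)), n_blocks=5, seed=2
        )
        psth = build_psth(simulate_spike_train(spec, epoch), epoch)
        assert psth.rates.mean() == pytest.approx(100.0, rel=0.05)

    def test_rejects_bad_bin_width(self, epoch):
        train = SpikeTrain("u", [np.array([0.1])], block_duration=2.0)
        with pytest.raises(ValueError):
            build_psth(train, epoch, bin_width_ms=0.0)


class TestSmoothPsth:
    def test_impulse_becomes_gaussian(self):
        rates = np.zeros(501)
        rates[250] = 1000.0
        psth = PSTH(rates=rates, bin_width_ms=1.0)
        sm = smooth_psth(psth, sigma_ms=25.0)
        x = np.arange(501) - 250
        expected = 1000.0 * np.exp(-(x**2) / (2 * 25.0**2)) / (25.0 * np.sqrt(2 * np.pi))
        # discrete kernel is truncated at 4 sigma: compare the central region
        np.testing.assert_allclose(sm.rates[150:351], expected[150:351], atol=5e-2)
        assert sm.rates.sum() == pytest.approx(1000.0, rel=1e-6)

    def test_constant_unchanged(self):
        psth = PSTH(rates=np.full(400, 37.0), bin_width_ms=1.0)
        sm = smooth_psth(psth)
        np.testing.assert_allclose(sm.rates[100:300], 37.0, rtol=1e-10)

    def test_mass_conserved(self, epoch, on_profile):
        psth = exact_psth(on_profile, epoch)
        sm = smooth_psth(psth, sigma_ms=25.0)
        before = psth.rates.sum() * psth.bin_width_s
        after = sm.rates.sum() * sm.bin_width_s
        assert after == pytest.approx(before, rel=1e-3)

    def test_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            smooth_psth(PSTH(rates=np.zeros(10)), sigma_ms=0.0)


class TestEstimateBaseline:
    def test_constant_rate(self, epoch):
        psth = PSTH(rates=np.full(2000, 20.0), bin_width_ms=1.0)
        assert estimate_baseline(psth, epoch) == pytest.approx(20.0)

    def test_zero_preonset(self, epoch):
        rates = np.zeros(2000)
        rates[200:] = 50.0
        psth = PSTH(rates=rates, bin_width_ms=1.0)
        assert estimate_baseline(psth, epoch) == 0.0

    def test_insufficient_window_rejected(self):
        epoch = StimulusEpoch(onset=0.05, offset=0.35)
        psth = PSTH(rates=np.zeros(2000), bin_width_ms=1.0)
        with pytest.raises(ValueError, match="100 ms"):
            estimate_baseline(psth, epoch)

    def test_simulated_baseline_recovery(self, epoch):
        spec = SyntheticCellSpec(
            "ON-transient", RateProfile(15.0, Lobe(1e-9, 80, 60)), n_blocks=5, seed=9
        )
        psth = build_psth(simulate_spike_train(spec, epoch), epoch)
        # 15 Hz x 0.1 s x 5 blocks = 7.5 expected spikes: generous Poisson bound
        assert estimate_baseline(psth, epoch) == pytest.approx(15.0, abs=12.0)


class TestExtractOnMetrics:
    def test_analytic_recovery(self, epoch, on_profile):
        psth = exact_psth(on_profile, epoch)
        m = extract_on_metrics(psth, 10.0, epoch)
        assert m.amplitude == pytest.approx(50.0, rel=0.05)
        assert m.latency_ms == pytest.approx(80.0, rel=0.05)
        assert m.tau2_ms == pytest.approx(60.0, rel=0.05)
        assert not m.censored

    def test_constant_psth_non_responsive(self, epoch):
        psth = PSTH(rates=np.full(2000, 20.0), bin_width_ms=1.0)
        m = extract_on_metrics(psth, 20.0, epoch)
        assert m.amplitude == pytest.approx(0.0)
        assert not m.responsive

    def test_amplitude_invariant_to_constant_shift(self, epoch, on_profile):
        psth = exact_psth(on_profile, epoch)
        shifted = PSTH(rates=psth.rates + 30.0, bin_width_ms=1.0)
        a = extract_on_metrics(psth, 10.0, epoch).amplitude
        b = extract_on_metrics(shifted, 40.0, epoch).amplitude
        assert b == pytest.approx(a)

    def test_monotone_in_generating_amplitude(self, epoch):
        amps = [10.0, 30.0, 60.0, 120.0]
        extracted = []
        for a in amps:
            prof = RateProfile(10.0, Lobe(a, 80, 60))
            extracted.append(extract_on_metrics(exact_psth(prof, epoch), 10.0, epoch).amplitude)
        assert np.all(np.diff(extracted) > 0)

    def test_simulated_tau_recovery(self, epoch):
        # ON-transient ground truth tau = 150 ms, 5 blocks, fixed seed
        spec = SyntheticCellSpec(
            "ON-transient", RateProfile(8.0, Lobe(250.0, 80.0, 150.0)), n_blocks=5, seed=4
        )
        m = response_metrics(simulate_spike_train(spec, epoch), epoch)
        assert m.a1_tau2_ms == pytest.approx(150.0, rel=0.20)

    def test_censoring_flagged(self, epoch):
        # decay too slow to cross A/e inside the ON window
        prof = RateProfile(0.0, Lobe(100.0, 80.0, 5000.0))
        m = extract_on_metrics(exact_psth(prof, epoch), 0.0, epoch)
        assert m.censored


class TestExtractOffMetrics:
    def test_pure_on_cell_small_a2(self, epoch, on_profile):
        psth = exact_psth(on_profile, epoch)
        m = extract_off_metrics(psth, 10.0, epoch)
        assert m.amplitude < 5.0

    def test_analytic_off_recovery(self, epoch):
        prof = RateProfile(10.0, off_lobe=Lobe(40.0, 90.0, 50.0))
        m = extract_off_metrics(exact_psth(prof, epoch), 10.0, epoch)
        assert m.amplitude == pytest.approx(40.0, rel=0.05)
        assert m.latency_ms == pytest.approx(90.0, rel=0.05)
        assert m.tau2_ms == pytest.approx(50.0, rel=0.05)

    def test_on_off_equal_lobes_noise_free(self, epoch):
        prof = RateProfile(10.0, Lobe(50.0, 80.0, 60.0), Lobe(50.0, 80.0, 60.0))
        psth = exact_psth(prof, epoch)
        on = extract_on_metrics(psth, 10.0, epoch)
        off = extract_off_metrics(psth, 10.0, epoch)
        assert on.amplitude == pytest.approx(off.amplitude, rel=0.02)

    def test_on_off_equal_lobes_simulated(self, epoch):
        prof = RateProfile(8.0, Lobe(250.0, 80.0, 60.0), Lobe(250.0, 150.0, 60.0))
        spec = SyntheticCellSpec("ON-OFF", prof, n_blocks=5, seed=6)
        m = response_metrics(simulate_spike_train(spec, epoch), epoch)
        assert m.a1 == pytest.approx(m.a2, rel=0.25)  # sampling error with 5 blocks


class TestEndToEnd:
    def test_fine_bin_zero_noise_limit(self, epoch):
        # with 0.1 ms bins the extracted triple matches the generator closely
        prof = RateProfile(5.0, Lobe(80.0, 100.0, 120.0))
        psth = exact_psth(prof, epoch, bin_width_ms=0.1)
        m = extract_on_metrics(psth, 5.0, epoch)
        assert m.amplitude == pytest.approx(80.0, rel=0.01)
        assert m.latency_ms == pytest.approx(100.0, rel=0.01)
        assert m.tau2_ms == pytest.approx(120.0, rel=0.01)
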