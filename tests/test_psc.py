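import numpy as np
import pandas as pd
import pytest
from scipy.special import i0, i1

from cfchmm.preprocess import Trace
from cfchmm.psc import (PSCEventTrain, charge_transfer, detect_events,
                        event_phase_locking, plv_band_comparison,
                        recursive_threshold_search)
from cfchmm.synth import PSCSynthConfig, _biexp_kernel, generate_psc_train


def _train(times, amps, thr=6.0):
    return PSCEventTrain(times=np.asarray(times, float),
                         amplitudes=np.asarray(amps, float),
                         polarity="EPSC", detection_threshold=thr)


class TestDetection:
    def test_single_inserted_event_found_at_peak(self, rng):
        fs = 1000.0
        x = rng.standard_normal(60000) * 2.0
        kern = _biexp_kernel(fs, 2.0, 10.0)
        x[30000:30000 + kern.size] += -60.0 * kern
        ev = detect_events(Trace(x, fs, units="pA"), (0.0, 10.0),
                           polarity="EPSC")
        big = ev.times[ev.amplitudes > 30]
        peak_t = 30.0 + np.argmax(kern) / fs
        assert big.size == 1
        assert abs(big[0] - peak_t) < 0.002

    def test_refractory_merges_close_events(self, rng):
        fs = 1000.0
        x = rng.standard_normal(60000) * 2.0
        kern = _biexp_kernel(fs, 2.0, 10.0)
        for i0_ in (40000, 40020):  # 20 ms apart < 50-ms minimum distance
            x[i0_:i0_ + kern.size] += -60.0 * kern
        ev = detect_events(Trace(x, fs, units="pA"), (0.0, 10.0))
        sel = (ev.times > 39.9) & (ev.times < 40.2)
        assert sel.sum() == 1

    def test_synthetic_train_recovered(self, rng):
        phase = np.angle(np.exp(1j * 2 * np.pi * 4 * np.arange(0, 120, 1e-3)))
        cfg = PSCSynthConfig(mean_event_rate=1.0, baseline_rate=0.0,
                             von_mises_kappa=0.0, pcc_amp=60.0,
                             noise_sd=2.0, seed=9)
        tr, truth = generate_psc_train(cfg, phase, 1000.0)
        # event-free quiet stretch prepended so the baseline SD is honest
        x = np.concatenate([rng.standard_normal(5000) * 2.0, tr.samples])
        full = Trace(x, 1000.0, units="pA")
        ev = detect_events(full, (0.0, 5.0), polarity="EPSC", k_sd=4.0)
        hits = sum(bool(np.any(np.abs(ev.times - (t + 5.0)) < 0.01))
                   for t in truth.time_s)
        assert hits >= 0.9 * len(truth)
        # no false positives in the quiet stretch
        assert np.sum(ev.times < 4.95) == 0

    def test_zero_variance_baseline_rejected(self):
        with pytest.raises(ValueError):
            detect_events(Trace(np.zeros(5000), 1000.0, "pA"), (0.0, 1.0))


class TestChargeTransfer:
    def test_constant_current_energy_per_bin(self):
        x = np.zeros(12000)
        x[1000:11000] = -5.0
        prof = charge_transfer(Trace(x, 1000.0, "pA"), [(1.0, 11.0)],
                               polarity="EPSC")
        np.testing.assert_allclose(prof.energy[0], 5.0, rtol=0.01)
        assert prof.baseline[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_current_zero_energy(self):
        prof = charge_transfer(Trace(np.zeros(12000), 1000.0, "pA"),
                               [(1.0, 11.0)])
        np.testing.assert_array_equal(prof.energy, 0.0)

    def test_ramp_current_strictly_increasing(self):
        x = np.zeros(12000)
        x[1000:11000] = -np.linspace(0, 10, 10000)
        prof = charge_transfer(Trace(x, 1000.0, "pA"), [(1.0, 11.0)],
                               polarity="EPSC")
        assert np.all(np.diff(prof.energy[0]) > 0)

    def test_energy_additive_over_disjoint_intervals(self, rng):
        x = np.abs(rng.standard_normal(30000))
        tr = Trace(-x, 1000.0, "pA")
        a = charge_transfer(tr, [(2.0, 12.0)], polarity="EPSC")
        b = charge_transfer(tr, [(2.0, 7.0)], polarity="EPSC")
        c = charge_transfer(tr, [(7.0, 12.0)], polarity="EPSC")
        # same integrand: halves sum to the whole (baselines equalized)
        tot = a.energy.sum() + a.baseline[0] * 0
        np.testing.assert_allclose(
            a.energy.sum(),
            b.energy.sum() + c.energy.sum()
            + (b.baseline[0] - a.baseline[0]) * 0,
            rtol=0.15)

    def test_bonferroni_comparisons_when_enough_sles(self, rng):
        # nine SLEs: the signed-rank test's smallest attainable p-value
        # survives a ten-fold Bonferroni correction only for n >= 9
        x = np.zeros(200000)
        ivs = []
        for k in range(9):
            a = 5000 + k * 20000
            x[a:a + 10000] = -8.0 - rng.uniform()
            ivs.append((a / 1000.0, (a + 10000) / 1000.0))
        prof = charge_transfer(Trace(x, 1000.0, "pA"), ivs, polarity="EPSC")
        assert prof.comparisons is not None
        assert prof.comparisons.significant.all()

    def test_short_interval_rejected(self):
        with pytest.raises(ValueError):
            charge_transfer(Trace(np.zeros(1000), 1000.0, "pA"),
                            [(0.5, 0.505)])


class TestPhaseLocking:
    def test_coincident_phasors_unit_plv(self):
        phase = np.zeros(10000)
        ev = _train([1.0, 2.0, 3.0], [10, 12, 14])
        res = event_phase_locking(ev, phase, 4.0, 1000.0)
        assert res.plv == pytest.approx(1.0)

    def test_antipodal_phasors_cancel(self):
        phase = np.concatenate([np.zeros(5000), np.full(5000, np.pi)])
        ev = _train([1.0, 7.0], [10, 10])
        res = event_phase_locking(ev, phase, 4.0, 1000.0)
        assert res.plv == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_oracle(self, rng):
        phases = rng.vonmises(0.0, 2.0, 2000)
        ev = _train(np.arange(2000) * 0.001, np.full(2000, 10.0))
        res = event_phase_locking(ev, phases, 4.0, 1000.0)
        assert res.plv == pytest.approx(i1(2) / i0(2), abs=0.03)
        assert res.rayleigh_p < 1e-10

    def test_plv_invariant_to_global_rotation(self, rng):
        phases = rng.vonmises(0.5, 3.0, 500)
        ev = _train(np.arange(500) * 0.001, np.full(500, 10.0))
        a = event_phase_locking(ev, phases, 4.0, 1000.0).plv
        b = event_phase_locking(ev, np.angle(np.exp(1j * (phases + 1.2))),
                                4.0, 1000.0).plv
        assert a == pytest.approx(b, abs=1e-9)

    def test_rayleigh_p_superuniform_under_null(self, rng):
        hits = 0
        for _ in range(1000):
            phases = rng.uniform(-np.pi, np.pi, 50)
            ev = _train(np.arange(50) * 0.001, np.full(50, 10.0))
            p = event_phase_locking(ev, phases, 4.0, 1000.0).rayleigh_p
            hits += p < 0.05
        assert hits <= 60

    def test_no_events_rejected(self):
        ev = PSCEventTrain(times=np.array([]), amplitudes=np.array([]),
                           polarity="EPSC", detection_threshold=6.0)
        with pytest.raises(ValueError):
            event_phase_locking(ev, np.zeros(100), 4.0, 1000.0)


@pytest.fixture(scope="module")
def two_population_current():
    """Low-amplitude uniform events plus large kappa=4 locked events."""
    phase = np.angle(np.exp(1j * 2 * np.pi * 4 * np.arange(0, 400, 1e-3)))
    locked = PSCSynthConfig(mean_event_rate=3.0, baseline_rate=8.0,
                            von_mises_kappa=4.0, pcc_amp=48.0,
                            baseline_amp=16.0, noise_sd=2.0, seed=4)
    tr, events = generate_psc_train(locked, phase, 1000.0)
    return tr, phase


class TestThresholdSearch:
    def test_search_isolates_locked_subpopulation(self, two_population_current):
        tr, phase = two_population_current
        res = recursive_threshold_search(tr, phase[None, :], [4.0],
                                         (0.0, 10.0), polarity="EPSC")
        assert res.significant
        assert res.plv > 0.3
        assert res.rayleigh_p < 0.05

    def test_planted_frequency_identified(self, two_population_current):
        tr, phase_4 = two_population_current
        freqs = np.arange(1.0, 13.0)
        t = np.arange(phase_4.size) / 1000.0
        phases = np.angle(np.exp(1j * 2 * np.pi * freqs[:, None] * t[None, :]))
        res = recursive_threshold_search(tr, phases, freqs, (0.0, 10.0),
                                         polarity="EPSC")
        assert res.significant
        assert res.freq in (3.0, 4.0, 5.0)

    def test_uniform_events_not_qualified(self):
        phase = np.angle(np.exp(1j * 2 * np.pi * 4 * np.arange(0, 300, 1e-3)))
        cfg = PSCSynthConfig(mean_event_rate=3.0, baseline_rate=8.0,
                             von_mises_kappa=0.0, noise_sd=2.0, seed=6)
        tr, _ = generate_psc_train(cfg, phase, 1000.0)
        res = recursive_threshold_search(tr, phase[None, :], [4.0],
                                         (0.0, 10.0), polarity="EPSC")
        assert not res.significant

    def test_locking_specific_to_transition_substates(self):
        """Locking planted only in transitions qualifies there and nowhere
        else (pre-SLE baseline, mid state)."""
        fs = 1000.0
        segs = {  # (start_s, dur_s, kappa, locked rate, seed)
            "pre": (0.0, 60.0, 0.0, 0.0, 11),
            "r_o": (60.0, 60.0, 4.0, 3.0, 12),
            "r_s": (120.0, 60.0, 0.0, 0.0, 13),
            "r_e": (180.0, 60.0, 4.0, 3.0, 14),
        }
        t = np.arange(0, 240, 1 / fs)
        phase = np.angle(np.exp(1j * 2 * np.pi * 4 * t))
        current = np.random.default_rng(0).standard_normal(t.size) * 2.0
        for name, (a, dur, kappa, rate, seed) in segs.items():
            cfg = PSCSynthConfig(mean_event_rate=rate, baseline_rate=8.0,
                                 von_mises_kappa=kappa, noise_sd=0.0,
                                 seed=seed)
            seg_tr, _ = generate_psc_train(
                cfg, phase[int(a * fs):int((a + dur) * fs)], fs)
            current[int(a * fs):int((a + dur) * fs)] += seg_tr.samples
        tr = Trace(current, fs, units="pA")
        results = {}
        for name, (a, dur, _, _, _) in segs.items():
            results[name] = recursive_threshold_search(
                tr, phase[None, :], [4.0], (0.0, 30.0),
                region=(a, a + dur), polarity="EPSC")
        assert results["r_o"].significant
        assert results["r_e"].significant
        assert not results["pre"].significant
        assert not results["r_s"].significant


class TestBandComparison:
    def _plv_table(self, rng, n, shift=None):
        cols = {f: np.clip(0.2 + 0.05 * rng.standard_normal(n), 0, 1)
                for f in range(1, 13)}
        if shift:
            for f, d in shift.items():
                cols[f] = np.clip(cols[f] + d, 0, 1)
        return pd.DataFrame(cols)

    def test_identical_groups_nothing_significant(self, rng):
        a = self._plv_table(rng, 12)
        out = plv_band_comparison(a, a.copy())
        assert not out.significant.any()

    def test_ipsc_locking_at_4_and_5_hz_detected(self, rng):
        epsc = self._plv_table(rng, 15, shift={2: 0.4})
        ipsc = self._plv_table(rng, 15, shift={4: 0.4, 5: 0.4})
        out = plv_band_comparison(epsc, ipsc)
        sig = out[out.significant]
        assert {4, 5}.issubset(set(sig[sig.favors == "IPSC"].freq))
        assert 2 in set(sig[sig.favors == "EPSC"].freq)

    def test_single_band_shift_flagged(self, rng):
        a = self._plv_table(rng, 20)
        b = self._plv_table(rng, 20, shift={7: 0.3})
        out = plv_band_comparison(a, b)
        assert bool(out.loc[out.freq == 7, "significant"].iloc[0])
        assert out.significant.sum() == 1

    def test_too_few_sles_rejected(self, rng):
        with pytest.raises(ValueError):
            plv_band_comparison(self._plv_table(rng, 2),
                                self._plv_table(rng, 5))
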