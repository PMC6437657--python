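import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfchmm.cfc import (build_feature_set, cfc_power_correlation, cfc_series,
                        modulation_index, modulation_index_from_binned,
                        surrogate_significance)
from cfchmm.preprocess import Trace


def _brute_force_mi(phase, amplitude, n_bins=18):
    """Independent histogram implementation of the coupling index."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(np.mod(phase + np.pi, 2 * np.pi) - np.pi,
                              edges) - 1, 0, n_bins - 1)
    means = np.array([amplitude[idx == j].mean() if np.any(idx == j) else 0.0
                      for j in range(n_bins)])
    p = means / means.sum()
    p = np.where(p > 0, p, np.finfo(float).eps)
    p /= p.sum()
    return (np.sum(p * np.log(p)) + np.log(n_bins)) / np.log(n_bins)


class TestModulationIndex:
    def test_uniform_distribution_is_zero(self):
        assert modulation_index_from_binned(np.full(18, 1 / 18)) == 0.0

    def test_single_bin_delta_is_one(self):
        d = np.zeros(18)
        d[7] = 1.0
        assert modulation_index_from_binned(d) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_histogram(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 100000)
        amp = 1 + 0.5 * np.cos(phase)
        assert modulation_index(phase, amp) == pytest.approx(
            _brute_force_mi(phase, amp), abs=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           depth=st.floats(min_value=0.0, max_value=0.95))
    def test_invariant_to_amplitude_rescaling(self, scale, depth):
        rng = np.random.default_rng(42)
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = 1 + depth * np.cos(phase)
        assert modulation_index(phase, scale * amp) == pytest.approx(
            modulation_index(phase, amp), abs=1e-12)

    @pytest.mark.parametrize("k_bins", [1, 3, 9])
    def test_invariant_to_rotation_by_whole_bins(self, k_bins, rng):
        phase = rng.uniform(-np.pi, np.pi, 20000)
        amp = 1 + 0.6 * np.cos(2 * phase)
        rot = k_bins * np.deg2rad(20.0)
        assert modulation_index(phase + rot, amp) == pytest.approx(
            modulation_index(phase, amp), abs=1e-12)

    def test_all_zero_amplitude_rejected(self, rng):
        with pytest.raises(ValueError):
            modulation_index(rng.uniform(-np.pi, np.pi, 100), np.zeros(100))


class TestCFCSeries:
    def test_window_count_at_95_percent_overlap(self, rng):
        tr = Trace(rng.standard_normal(10000), 1000.0)
        c = cfc_series(tr, phase_freqs=[4.0], amp_freqs=[60.0],
                       window_s=2.0, overlap=0.95)
        assert c.n_windows == (10000 - 2000) // 100 + 1 == 81

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            cfc_series(Trace(np.full(5000, 2.0), 1000.0),
                       phase_freqs=[4.0], amp_freqs=[60.0])

    def test_window_longer_than_trace_rejected(self, rng):
        with pytest.raises(ValueError):
            cfc_series(Trace(rng.standard_normal(500), 1000.0),
                       phase_freqs=[4.0], amp_freqs=[60.0], window_s=2.0)

    def test_blocked_accumulation_matches_direct_windows(self, rng):
        """The fast hop-blocked path equals per-window recomputation."""
        from cfchmm.cfc import _phase_bin_indices
        from cfchmm.preprocess import morlet_cwt

        tr = Trace(np.sin(2 * np.pi * 4 * np.arange(0, 8, 1e-3)) +
                   0.1 * rng.standard_normal(8000), 1000.0)
        c = cfc_series(tr, phase_freqs=[3.0, 4.0], amp_freqs=[60.0],
                       window_s=2.0, overlap=0.5)
        amp = np.abs(morlet_cwt(tr, [60.0]).coefficients)
        ph = np.angle(morlet_cwt(tr, [3.0, 4.0]).coefficients)
        for w in range(c.n_windows):
            sl = slice(w * 1000, w * 1000 + 2000)
            for i in range(2):
                idx = _phase_bin_indices(ph[i, sl], 18)
                counts = np.bincount(idx, minlength=18)
                sums = np.bincount(idx, weights=amp[0, sl], minlength=18)
                means = np.where(counts > 0, sums / np.maximum(counts, 1), 0)
                assert c.mi[i, 0, w] == pytest.approx(
                    modulation_index_from_binned(means), abs=1e-12)

    def test_planted_coupling_beats_white_noise(self, rng):
        t = np.arange(0, 30, 1e-3)
        theta = 2 * np.pi * 4 * t
        coupled = (0.3 * np.cos(theta) +
                   (1 + 0.9 * np.cos(theta)) * rng.standard_normal(t.size) * 0.1)
        noise = 0.1 * rng.standard_normal(t.size)
        mi_c = cfc_series(Trace(coupled, 1000.0), [4.0], [60.0]).mi
        mi_n = cfc_series(Trace(noise, 1000.0), [4.0], [60.0]).mi
        assert np.median(mi_c) > np.median(mi_n)


@pytest.fixture(scope="module")
def cfc():
    rng = np.random.default_rng(1)
    tr = Trace(np.sin(2 * np.pi * 4 * np.arange(0, 30, 1e-3)) +
               0.2 * rng.standard_normal(30000), 1000.0)
    return cfc_series(tr, window_s=2.0, overlap=0.0)


class TestFeatureSet:
    def test_sixteen_base_rows_and_derivatives(self, cfc):
        f = build_feature_set(cfc)
        assert f.n_base == 16
        assert f.matrix.shape[0] == 32

    def test_rows_normalized_to_unit_interval(self, cfc):
        f = build_feature_set(cfc)
        assert f.matrix.min() >= 0.0 and f.matrix.max() <= 1.0
        # every non-constant row attains both extremes
        for row in f.matrix:
            if np.ptp(row) > 0:
                assert row.min() == 0.0 and row.max() == pytest.approx(1.0)

    def test_constant_cfc_has_zero_derivative_rows(self):
        from cfchmm.cfc import CFCSeries

        mi = np.full((12, 45, 30), 0.25)
        c = CFCSeries(mi=mi, phase_freqs=np.arange(1.0, 13.0),
                      amp_freqs=np.arange(30.0, 255.0, 5.0), window_s=2.0,
                      overlap=0.0, window_times=np.arange(30) * 2.0)
        f = build_feature_set(c)
        np.testing.assert_array_equal(f.matrix[16:], 0.0)


@pytest.fixture(scope="module")
def coupled_trace():
    rng = np.random.default_rng(0)
    from scipy import signal as sg

    t = np.arange(0, 20, 1e-3)
    theta = 2 * np.pi * 4 * t
    sos = sg.butter(4, [55, 65], btype="band", fs=1000, output="sos")
    carrier = sg.sosfiltfilt(sos, rng.standard_normal(t.size))
    x = (0.3 * np.cos(theta) +
         (1 + 0.9 * np.cos(theta)) * carrier * 0.15 +
         0.05 * rng.standard_normal(t.size))
    return Trace(x, 1000.0)


class TestSurrogates:
    def test_planted_band_flagged_significant(self, coupled_trace):
        res = surrogate_significance(coupled_trace, at=7.0, n=100, seed=1)
        i4 = int(np.where(res.phase_freqs == 4.0)[0][0])
        j60 = int(np.argmin(np.abs(res.amp_freqs - 60.0)))
        assert res.sig_mask[i4, j60]
        assert res.z[i4, j60] > 10

    def test_planted_z_dominates_null_z(self, coupled_trace, rng):
        res = surrogate_significance(coupled_trace, at=7.0, n=50, seed=1)
        null = surrogate_significance(
            Trace(rng.standard_normal(20000), 1000.0), at=7.0, n=50, seed=1)
        i4 = int(np.where(res.phase_freqs == 4.0)[0][0])
        j60 = int(np.argmin(np.abs(res.amp_freqs - 60.0)))
        assert res.z[i4, j60] > null.z.max()

    def test_too_few_surrogates_rejected(self, coupled_trace):
        with pytest.raises(ValueError):
            surrogate_significance(coupled_trace, at=7.0, n=1)


class TestPowerCorrelation:
    def test_self_correlation(self, rng):
        x = rng.standard_normal(50)
        r, p, genuine = cfc_power_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert not genuine  # positively correlated with power

    def test_anticorrelation_flags_genuine(self, rng):
        x = rng.standard_normal(50)
        r, _, genuine = cfc_power_correlation(x, -x)
        assert r == pytest.approx(-1.0)
        assert genuine

    def test_independent_series_mostly_uncorrelated(self):
        hits = 0
        for s in range(40):
            rng = np.random.default_rng(s)
            r, _, _ = cfc_power_correlation(rng.standard_normal(100),
                                            rng.standard_normal(100))
            hits += abs(r) < 0.3
        assert hits >= 38
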