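import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from cfchmm.hmm import (HMMParams, SubstateHMM, em_train, forward_backward_log,
                        forward_backward_mpd, kmeans_init)
from cfchmm.hmm import _forward_backward


def _two_regime_features(rng, T=400, d=6, sep=0.5, noise=0.15):
    states = (np.arange(T) // 50) % 2
    mu = np.array([[0.2] * d, [0.2 + sep] * d])
    return mu[states] + noise * rng.standard_normal((T, d)), states


def _small_params(rng):
    return HMMParams(
        initial=np.array([0.6, 0.4]),
        transition=np.array([[0.8, 0.2], [0.3, 0.7]]),
        weights=np.ones((2, 1)),
        means=np.array([[[0.0, 0.0]], [[1.0, 0.5]]]),
        covariances=np.array([[np.eye(2) * 0.3], [np.eye(2) * 0.5]]),
    )


class TestKMeansInit:
    def test_recovers_separated_blob_centers(self, rng):
        x, states = _two_regime_features(rng, sep=1.0, noise=0.1)
        params = kmeans_init(x, q=2, m=1, seed=0)
        centers = np.sort(params.means[:, 0, 0])
        assert abs(centers[0] - 0.2) < 0.01  # within 0.1 sigma
        assert abs(centers[1] - 1.2) < 0.01

    def test_deterministic_under_fixed_seed(self, rng):
        x, _ = _two_regime_features(rng)
        a = kmeans_init(x, seed=7)
        b = kmeans_init(x, seed=7)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.transition, b.transition)

    def test_identical_points_regularized_not_crashing(self):
        x = np.ones((40, 4))
        with pytest.warns(UserWarning):
            params = kmeans_init(x, q=2, m=2, seed=0)
        for j in range(2):
            for m in range(2):
                np.linalg.cholesky(params.covariances[j, m])  # PD

    def test_too_few_windows_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_init(rng.standard_normal((3, 4)), q=2, m=2)


class TestEMTraining:
    def test_loglik_monotone_nondecreasing(self, rng):
        x, _ = _two_regime_features(rng)
        res = em_train(x, kmeans_init(x, seed=0))
        assert np.all(np.diff(res.loglik_path) > -1e-8)
        assert res.n_iter <= 100

    def test_planted_regime_recovery(self, rng):
        x, states = _two_regime_features(rng, sep=0.45, noise=0.15)  # SNR 3
        res = SubstateHMM(x, n_mix=2).fit(seed=0)
        pred = res.predict_states()
        acc = max((pred == states).mean(), (pred == 1 - states).mean())
        assert acc >= 0.95

    def test_single_regime_has_no_state_structure(self, rng):
        """One regime: the fitted states overlap (mean gap below the
        regime's spread) and the posterior delimits no persistent SLE."""
        import warnings

        from cfchmm.substates import extract_substates

        x = 0.3 + 0.05 * rng.standard_normal((300, 4))
        res = SubstateHMM(x, n_mix=1).fit(seed=0)
        gap = np.abs(res.params.means[0, 0] - res.params.means[1, 0]).max()
        assert gap < 3 * 0.05  # no separated regimes discovered
        mpd = res.posterior()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            iv = extract_substates(mpd, min_dwell_s=5.0)
        assert iv.n_sles == 0


class TestForwardBackward:
    def test_posteriors_normalized(self, rng):
        x, _ = _two_regime_features(rng)
        res = SubstateHMM(x).fit(seed=0)
        mpd = res.posterior()
        np.testing.assert_allclose(mpd.s1 + mpd.s2, 1.0, atol=1e-9)

    def test_absorbing_prior_pins_posterior(self, rng):
        params = HMMParams(
            initial=np.array([1.0, 0.0]),
            transition=np.eye(2),
            weights=np.ones((2, 1)),
            means=np.array([[[0.0]], [[0.0]]]),   # identical emissions
            covariances=np.array([[np.eye(1)], [np.eye(1)]]),
        )
        x = rng.standard_normal((20, 1))
        gamma, _, _, _ = _forward_backward(x, params)
        np.testing.assert_allclose(gamma[:, 0], 1.0, atol=1e-12)

    def test_matches_exhaustive_path_enumeration(self, rng):
        """T=5 marginals equal the brute-force sum over all 2^5 paths."""
        params = _small_params(rng)
        x = rng.standard_normal((5, 2)) * 0.8 + 0.3

        def b(j, o):
            return multivariate_normal.pdf(o, params.means[j, 0],
                                           params.covariances[j, 0])

        post = np.zeros((5, 2))
        total = 0.0
        for path in itertools.product([0, 1], repeat=5):
            p = params.initial[path[0]] * b(path[0], x[0])
            for t in range(1, 5):
                p *= params.transition[path[t - 1], path[t]] * b(path[t], x[t])
            total += p
            for t in range(5):
                post[t, path[t]] += p
        post /= total

        gamma, _, _, _ = _forward_backward(x, params)
        np.testing.assert_allclose(gamma, post, atol=1e-10)

    def test_scaled_and_log_space_agree(self, rng):
        params = _small_params(rng)
        x = rng.standard_normal((200, 2))
        gamma, _, _, ll = _forward_backward(x, params)
        gamma_log, ll_log = forward_backward_log(x, params)
        np.testing.assert_allclose(gamma, gamma_log, atol=1e-8)
        assert ll == pytest.approx(ll_log, abs=1e-6)

    def test_agrees_with_hmmlearn_oracle(self, rng):
        """Independent cross-check of likelihood and posteriors."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        params = _small_params(rng)
        x = rng.standard_normal((150, 2)) * 0.7

        model = hmmlearn.GaussianHMM(n_components=2, covariance_type="full",
                                     init_params="")
        model.startprob_ = params.initial
        model.transmat_ = params.transition
        model.means_ = params.means[:, 0, :]
        model.covars_ = params.covariances[:, 0, :, :]
        ll_ref, post_ref = model.score_samples(x)

        gamma, _, _, ll = _forward_backward(x, params)
        assert ll == pytest.approx(ll_ref, abs=1e-6)
        np.testing.assert_allclose(gamma, post_ref, atol=1e-8)


class TestResultsObject:
    def test_summary_reports_fit(self, rng):
        x, _ = _two_regime_features(rng)
        res = SubstateHMM(x).fit(seed=0)
        text = res.summary()
        assert "log likelihood" in text
        assert "transition matrix" in text

    def test_params_json_roundtrip(self, rng, tmp_path):
        x, _ = _two_regime_features(rng)
        res = SubstateHMM(x).fit(seed=0)
        path = tmp_path / "model.json"
        res.save(path)
        loaded = HMMParams.from_json(path.read_text())
        np.testing.assert_allclose(loaded.means, res.params.means)
        np.testing.assert_allclose(loaded.transition, res.params.transition)

    def test_state_labels_ordered_by_coupling(self, rng):
        x, states = _two_regime_features(rng, sep=1.0)
        res = SubstateHMM(x).fit(seed=0)
        mpd = res.posterior()
        # s2 must track the high-mean regime
        assert mpd.s2[states == 1].mean() > 0.9
        assert mpd.s2[states == 0].mean() < 0.1
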