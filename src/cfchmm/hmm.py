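"""Two-state hidden Markov model with Gaussian-mixture emissions.

The classifier that separates the seizure-like-event (SLE) state S2 from
the inter-SLE state S1.  Observations are the 32-row coupling feature
vectors; each state emits from a mixture of one or two full-covariance
Gaussians.  Parameters {s, A, B} are initialised by k-means clustering and
refined by Baum-Welch EM; the per-window marginal posterior distribution
(MPD)

    MPD_t(i) = alpha_t(i) beta_t(i) / sum_i alpha_t(i) beta_t(i)

is computed with per-step-scaled forward-backward recursions, which are
stable for arbitrarily long feature sequences.

The module follows the statsmodels convention: ``SubstateHMM`` is the model
object built from data, ``fit()`` returns a ``SubstateHMMResults`` carrying
the estimates, the likelihood path and diagnostics, with ``posterior()``,
``predict_states()`` and ``summary()`` methods.  The functional layer
(``kmeans_init``, ``em_train``, ``forward_backward_mpd``) underlies the
class and is usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import warnings

import numpy as np
from scipy.linalg import solve_triangular
from sklearn.cluster import KMeans

from .cfc import FeatureSet

__all__ = [
    "HMMParams",
    "TrainingResult",
    "MPD",
    "kmeans_init",
    "em_train",
    "forward_backward_mpd",
    "SubstateHMM",
    "SubstateHMMResults",
]

_RIDGE = 1e-6
_EMISSION_FLOOR = 1e-300


@dataclass
class HMMParams:
    """Parameters {s, A, B} of the two-state mixture-emission HMM."""

    initial: np.ndarray          # (n_states,)
    transition: np.ndarray       # (n_states, n_states), row-stochastic
    weights: np.ndarray          # (n_states, n_mix)
    means: np.ndarray            # (n_states, n_mix, n_features)
    covariances: np.ndarray      # (n_states, n_mix, n_features, n_features)

    @property
    def n_states(self) -> int:
        return self.initial.size

    @property
    def n_mix(self) -> int:
        return self.weights.shape[1]

    @property
    def n_features(self) -> int:
        return self.means.shape[2]

    def validate(self) -> None:
        if not np.allclose(self.initial.sum(), 1.0, atol=1e-8):
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("mixture weights must sum to 1")

    def to_json(self) -> str:
        return json.dumps({
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "HMMParams":
        d = json.loads(text)
        return cls(*(np.asarray(d[k]) for k in
                     ("initial", "transition", "weights", "means", "covariances")))


@dataclass
class TrainingResult:
    params: HMMParams
    loglik_path: np.ndarray
    converged: bool
    n_iter: int


@dataclass
class MPD:
    """Per-window marginal posterior probabilities of the two states."""

    s1: np.ndarray
    s2: np.ndarray
    window_times: np.ndarray

    def __post_init__(self) -> None:
        if np.max(np.abs(self.s1 + self.s2 - 1.0)) > 1e-9:
            raise ValueError("posteriors must sum to 1 at every window")

    @property
    def n_windows(self) -> int:
        return self.s1.size


def _as_matrix(features) -> np.ndarray:
    """Features as (T, d) observations."""
    if isinstance(features, FeatureSet):
        return features.matrix.T
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be 2-d")
    return x


def _window_times(features, T: int) -> np.ndarray:
    if isinstance(features, FeatureSet):
        return features.window_times
    return np.arange(T, dtype=float)


def _regularize(cov: np.ndarray, rel_floor: float = 0.5) -> np.ndarray:
    """Ridge plus a relative eigenvalue floor.

    Band-averaged coupling features are strongly correlated, so sample
    covariances have near-null directions; unfloored, tiny distribution
    shifts along them dominate the Mahalanobis distance and destroy
    generalisation to recordings the model was not trained on.  Eigenvalues
    below ``rel_floor`` times the mean variance are raised to that floor.
    """
    d = cov.shape[0]
    ridge = max(_RIDGE * np.trace(cov) / d, _RIDGE)
    cov = cov + ridge * np.eye(d)
    mean_var = np.trace(cov) / d
    w, v = np.linalg.eigh(cov)
    floor = rel_floor * mean_var
    if w[0] >= floor:
        return cov
    w = np.maximum(w, floor)
    return (v * w) @ v.T


def _log_gauss(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log multivariate normal density for all rows of x (T, d)."""
    d = mean.size
    chol = np.linalg.cholesky(cov)
    diff = x - mean
    z = solve_triangular(chol, diff.T, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + np.sum(z * z, axis=0))


def _log_emissions(x: np.ndarray, params: HMMParams):
    """Per-window log emission likelihood log b_j(O_t) and per-component logs.

    Returns (log_b: (T, n_states), log_comp: (T, n_states, n_mix)).
    """
    T = x.shape[0]
    log_comp = np.full((T, params.n_states, params.n_mix), -np.inf)
    for j in range(params.n_states):
        for m in range(params.n_mix):
            log_comp[:, j, m] = (np.log(max(params.weights[j, m], 1e-300)) +
                                 _log_gauss(x, params.means[j, m],
                                            params.covariances[j, m]))
    mx = log_comp.max(axis=2, keepdims=True)
    log_b = (mx[:, :, 0] +
             np.log(np.sum(np.exp(log_comp - mx), axis=2)))
    return log_b, log_comp


def kmeans_init(features, q: int = 2, m: int = 2, seed: int | None = 0,
                n_init: int = 10) -> HMMParams:
    """Initial HMM parameters from k-means clustering of the feature windows.

    Windows are clustered into q*m clusters which are ranked by their mean
    coupling level (the first half of the feature rows, i.e. the raw
    band-averaged indices); the lowest-coupling m clusters initialise the
    mixture components of the inter-SLE state and the highest m those of
    the SLE state.  The transition matrix comes from the run-length
    structure of the state-level assignment.  Ranking by coupling rather
    than splitting a 2-means solution keeps windows of intermediate
    coupling (the transitions) from forming a spurious mode of the
    inter-SLE state.  Deterministic under a fixed seed.
    """
    x = _as_matrix(features)
    T, d = x.shape
    if T < q * m:
        raise ValueError("need at least q*m windows")
    n_base = max(d // 2, 1)
    if np.allclose(np.ptp(x, axis=0), 0):
        warnings.warn("degenerate (identical) features; "
                      "using ridge-regularized covariance", stacklevel=2)
    km = KMeans(n_clusters=q * m, n_init=n_init, random_state=seed).fit(x)
    labels = km.labels_
    level = np.array([
        x[labels == c, :n_base].mean() if np.any(labels == c) else -np.inf
        for c in range(q * m)
    ])
    order = np.argsort(level)
    state_of = np.empty(q * m, dtype=int)
    for rank, c in enumerate(order):
        state_of[c] = min(rank // m, q - 1)
    state_labels = state_of[labels]

    initial = np.full(q, 1.0 / q)
    trans = np.zeros((q, q))
    for a, b in zip(state_labels[:-1], state_labels[1:]):
        trans[a, b] += 1
    trans += 1.0  # Laplace smoothing keeps rows stochastic for short runs
    trans /= trans.sum(axis=1, keepdims=True)

    weights = np.zeros((q, m))
    means = np.zeros((q, m, d))
    covs = np.zeros((q, m, d, d))
    for j in range(q):
        comps = [c for c in range(q * m) if state_of[c] == j]
        for k, c in enumerate(comps):
            sel = x[labels == c]
            if sel.shape[0] < 2:
                sel = x[state_labels == j]
            if sel.shape[0] < 2:
                sel = x
            weights[j, k] = max(np.sum(labels == c), 1)
            means[j, k] = sel.mean(axis=0)
            covs[j, k] = _regularize(np.cov(sel.T, bias=True).reshape(d, d))
        weights[j] /= weights[j].sum()
    params = HMMParams(initial, trans, weights, means, covs)
    params.validate()
    return params


def _rescale_transition(A: np.ndarray, scale: float) -> np.ndarray:
    """A**scale (fractional matrix power), re-projected to row-stochastic."""
    if scale == 1.0:
        return A
    from scipy.linalg import fractional_matrix_power

    out = fractional_matrix_power(A, scale).real
    out = np.clip(out, 1e-12, None)
    return out / out.sum(axis=1, keepdims=True)


def _forward_backward(x: np.ndarray, params: HMMParams, temper: float = 1.0,
                      hop_scale: float = 1.0):
    """Scaled forward-backward.

    ``temper`` multiplies the per-window log emission likelihood and
    ``hop_scale`` exponentiates the transition matrix; both default to the
    plain recursions.  When posteriors are evaluated on windows overlapping
    by a fraction v, only (1 - v) of each window is new data and the
    per-step transition probability refers to a (1 - v)-scaled time step,
    so temper = hop_scale = 1 - v corrects the evidence overcounting.

    Returns (gamma (T, q), xi_sum (q, q), log_comp_post (T, q, m), loglik).
    """
    log_b, log_comp = _log_emissions(x, params)
    log_b = log_b * temper
    # scale emission likelihoods per window to avoid under/overflow
    offset = log_b.max(axis=1, keepdims=True)
    b = np.exp(log_b - offset)
    b = np.maximum(b, _EMISSION_FLOOR)
    T, q = b.shape
    A = _rescale_transition(params.transition, hop_scale)
    alpha = np.empty((T, q))
    c = np.empty(T)
    alpha[0] = params.initial * b[0]
    c[0] = alpha[0].sum()
    if c[0] <= 0:
        raise FloatingPointError("zero likelihood at first window")
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * b[t]
        c[t] = alpha[t].sum()
        if c[t] <= 0:
            raise FloatingPointError(f"zero likelihood at window {t}")
        alpha[t] /= c[t]
    beta = np.empty((T, q))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((q, q))
    for t in range(T - 1):
        xi = (alpha[t][:, None] * A * (b[t + 1] * beta[t + 1])[None, :]) / c[t + 1]
        xi_sum += xi
    loglik = float(np.sum(np.log(c)) + np.sum(offset))
    # mixture-component posteriors within each state
    mx = log_comp.max(axis=2, keepdims=True)
    comp = np.exp(log_comp - mx)
    comp /= comp.sum(axis=2, keepdims=True)
    comp_post = gamma[:, :, None] * comp
    return gamma, xi_sum, comp_post, loglik


def forward_backward_log(x: np.ndarray, params: HMMParams):
    """Log-space forward-backward; returns (gamma, loglik).

    Independent of the scaled implementation; used as a numerical
    cross-check.
    """
    from scipy.special import logsumexp

    log_b, _ = _log_emissions(x, params)
    T, q = log_b.shape
    logA = np.log(np.maximum(params.transition, 1e-300))
    la = np.empty((T, q))
    la[0] = np.log(np.maximum(params.initial, 1e-300)) + log_b[0]
    for t in range(1, T):
        la[t] = logsumexp(la[t - 1][:, None] + logA, axis=0) + log_b[t]
    lb = np.zeros((T, q))
    for t in range(T - 2, -1, -1):
        lb[t] = logsumexp(logA + log_b[t + 1] + lb[t + 1], axis=1)
    loglik = float(logsumexp(la[-1]))
    lg = la + lb
    gamma = np.exp(lg - logsumexp(lg, axis=1, keepdims=True))
    return gamma, loglik


def em_train(features, init: HMMParams, tol: float = 1e-5,
             max_iter: int = 100) -> TrainingResult:
    """Baum-Welch refinement of {s, A, mixture emissions}.

    Iterates until the log-likelihood improvement drops below ``tol`` or
    ``max_iter`` iterations elapse.  The log-likelihood path is
    non-decreasing (EM monotonicity) up to numerical round-off.
    """
    x = _as_matrix(features)
    T, d = x.shape
    params = HMMParams(init.initial.copy(), init.transition.copy(),
                       init.weights.copy(), init.means.copy(),
                       init.covariances.copy())
    path = []
    converged = False
    for it in range(max_iter):
        gamma, xi_sum, comp_post, loglik = _forward_backward(x, params)
        if not np.isfinite(loglik):
            raise FloatingPointError(
                f"non-finite log likelihood at iteration {it}")
        path.append(loglik)
        if len(path) > 1 and abs(path[-1] - path[-2]) < tol:
            converged = True
            break
        # M step
        params.initial = gamma[0] / gamma[0].sum()
        row = xi_sum.sum(axis=1, keepdims=True)
        params.transition = np.where(row > 0, xi_sum / np.maximum(row, 1e-300),
                                     params.transition)
        params.transition /= params.transition.sum(axis=1, keepdims=True)
        for j in range(params.n_states):
            for m in range(params.n_mix):
                w = comp_post[:, j, m]
                wsum = w.sum()
                if wsum <= 1e-12:
                    continue  # starved component: keep previous parameters
                mu = (w[:, None] * x).sum(axis=0) / wsum
                diff = x - mu
                cov = (w[:, None, None] *
                       np.einsum("ti,tj->tij", diff, diff)).sum(axis=0) / wsum
                params.means[j, m] = mu
                params.covariances[j, m] = _regularize(cov)
            state_mass = comp_post[:, j, :].sum(axis=0)
            if state_mass.sum() > 0:
                params.weights[j] = state_mass / state_mass.sum()
    return TrainingResult(params=params, loglik_path=np.asarray(path),
                          converged=converged, n_iter=len(path))


def forward_backward_mpd(features, params: HMMParams, temper: float = 1.0,
                         hop_scale: float = 1.0) -> MPD:
    """Marginal posterior distributions of the two states per window.

    State labels are aligned so that s2 is the state with the larger mean
    emission (the coupling-rich SLE state).  ``temper`` / ``hop_scale``
    apply the overlapped-window evidence correction (see
    :func:`_forward_backward`); pass 1 - overlap for features computed on
    windows overlapping by that fraction.
    """
    x = _as_matrix(features)
    gamma, _, _, _ = _forward_backward(x, params, temper=temper,
                                       hop_scale=hop_scale)
    order = _state_order(params)
    times = _window_times(features, x.shape[0])
    return MPD(s1=gamma[:, order[0]].copy(), s2=gamma[:, order[1]].copy(),
               window_times=np.asarray(times, dtype=float))


def _state_order(params: HMMParams):
    """(inter-SLE state index, SLE state index) by mean emission level."""
    level = (params.weights[:, :, None] * params.means).sum(axis=1).mean(axis=1)
    return int(np.argmin(level)), int(np.argmax(level))


class SubstateHMM:
    """Two-state Gaussian-mixture HMM over coupling features.

    Parameters
    ----------
    features : FeatureSet or ndarray (T, d)
        Training observations.
    n_states : int
        Number of hidden states (the pipeline uses 2: inter-SLE and SLE).
    n_mix : int
        Gaussians per state emission mixture (1 or 2).
    """

    def __init__(self, features, n_states: int = 2, n_mix: int = 2):
        self.features = features
        self.endog = _as_matrix(features)
        self.n_states = n_states
        self.n_mix = n_mix

    @classmethod
    def from_featureset(cls, features: FeatureSet, n_mix: int = 2):
        return cls(features, n_states=2, n_mix=n_mix)

    def fit(self, tol: float = 1e-5, max_iter: int = 100,
            seed: int | None = 0) -> "SubstateHMMResults":
        init = kmeans_init(self.endog, q=self.n_states, m=self.n_mix,
                           seed=seed)
        res = em_train(self.endog, init, tol=tol, max_iter=max_iter)
        return SubstateHMMResults(self, res)


class SubstateHMMResults:
    """Fitted HMM: parameter estimates, likelihood path, posteriors."""

    def __init__(self, model: SubstateHMM, training: TrainingResult):
        self.model = model
        self.params = training.params
        self.loglik_path = training.loglik_path
        self.converged = training.converged
        self.n_iter = training.n_iter

    @property
    def loglik(self) -> float:
        return float(self.loglik_path[-1])

    def posterior(self, features=None, overlap: float = 0.0) -> MPD:
        """MPD on the training features or on a new test feature set.

        ``overlap`` is the window-overlap fraction of the supplied feature
        grid; overlapped grids get the evidence correction (temper and
        transition rescale by 1 - overlap).
        """
        feats = self.model.features if features is None else features
        corr = 1.0 - overlap
        return forward_backward_mpd(feats, self.params, temper=corr,
                                    hop_scale=corr)

    def predict_states(self, features=None) -> np.ndarray:
        """Hard window labels (0 = inter-SLE S1, 1 = SLE S2) by argmax MPD."""
        mpd = self.posterior(features)
        return (mpd.s2 > mpd.s1).astype(int)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.params.to_json())

    def plot_posterior(self, features=None, ax=None):
        """Plot the SLE-state posterior against window time."""
        import matplotlib.pyplot as plt

        mpd = self.posterior(features)
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 2.5))
        ax.plot(mpd.window_times, mpd.s2, lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("Pr(S2)")
        ax.set_ylim(-0.05, 1.05)
        return ax

    def summary(self) -> str:
        o = _state_order(self.params)
        lines = [
            "Two-state Gaussian-mixture HMM",
            "=" * 34,
            f"observations:      {self.model.endog.shape[0]}",
            f"features:          {self.model.endog.shape[1]}",
            f"mixture components {self.params.n_mix}",
            f"log likelihood:    {self.loglik:.3f}",
            f"EM iterations:     {self.n_iter} "
            f"({'converged' if self.converged else 'max-iter stop'})",
            "",
            "state labels: S1 = inter-SLE, S2 = SLE (higher mean coupling)",
            f"initial Pr:        S1={self.params.initial[o[0]]:.3f} "
            f"S2={self.params.initial[o[1]]:.3f}",
            "transition matrix (S1,S2 order):",
        ]
        A = self.params.transition[np.ix_(o, o)]
        for row in A:
            lines.append("    " + "  ".join(f"{v:.4f}" for v in row))
        lines.append("state mean emission level: "
                     f"S1={self._level(o[0]):.4f}  S2={self._level(o[1]):.4f}")
        return "\n".join(lines)

    def _level(self, j: int) -> float:
        p = self.params
        return float((p.weights[j, :, None] * p.means[j]).sum(axis=0).mean())
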