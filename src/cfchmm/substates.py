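"""Sub-state extraction from posterior fluctuations and duration dynamics.

The 0-to-1 and 1-to-0 fluctuations of the SLE-state posterior delimit three
sub-states per event: an onset transition r_o (posterior rising from below
``lo_thr`` to above ``hi_thr``), the mid state r_s (posterior above
``hi_thr``), and a termination transition r_e (posterior falling back below
``lo_thr``).  Crossing times are located by linear interpolation between
window times, so the three intervals are exactly contiguous and a step-like
posterior yields transition intervals of about one window.

Duration histograms of each sub-state are summarised by maximum-likelihood
gamma fits; the shape parameter alpha classifies the generating dynamics:
alpha < 1 stochastic (clustered, bursty), alpha = 1 Poisson-like
(memoryless), alpha > 1 statistically deterministic (quasi-regular).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .hmm import MPD
from .preprocess import Trace

__all__ = [
    "SubStateIntervals",
    "SLEMetrics",
    "GammaFit",
    "extract_substates",
    "duration_intensity",
    "fit_gamma_durations",
    "correlate_metrics",
]


@dataclass
class SubStateIntervals:
    """Per-SLE (r_o, r_s, r_e) intervals plus inter-SLE gaps, in seconds."""

    r_o: list  # (start_s, end_s) per SLE
    r_s: list
    r_e: list
    inter_sle: list  # gaps between consecutive SLEs

    @property
    def n_sles(self) -> int:
        return len(self.r_o)

    def durations(self, which: str) -> np.ndarray:
        seq = {"r_o": self.r_o, "r_s": self.r_s, "r_e": self.r_e,
               "inter": self.inter_sle}[which]
        return np.array([b - a for a, b in seq])

    def sle_spans(self) -> list:
        """(start, end) of each full SLE, onset start to termination end."""
        return [(o[0], e[1]) for o, e in zip(self.r_o, self.r_e)]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("start_s\tend_s\tlabel\tsle_index\n")
            for k, (o, s, e) in enumerate(zip(self.r_o, self.r_s, self.r_e)):
                for lab, iv in (("r_o", o), ("r_s", s), ("r_e", e)):
                    fh.write(f"{iv[0]:.6f}\t{iv[1]:.6f}\t{lab}\t{k}\n")


@dataclass
class SLEMetrics:
    """Duration and intensity of each classified SLE.

    ``intensity`` follows the (V_L)^2 / L convention: sum of squared LFP
    samples within the interval divided by the interval length in seconds
    (mean square times the sampling rate); units mV^2/s for an mV trace.
    """

    duration: np.ndarray          # per-SLE total duration (s)
    sub_durations: dict           # label -> per-SLE duration array
    intensity: np.ndarray         # per-SLE total intensity
    sub_intensity: dict           # label -> per-SLE intensity array
    convention: str = "sum(V^2)/L_seconds"


@dataclass
class GammaFit:
    """Maximum-likelihood gamma fit of a duration histogram."""

    shape: float
    scale: float
    ci95: tuple            # (lo, hi) for the shape, asymptotic
    label: str             # stochastic / Poisson / deterministic
    n: int

    def to_dict(self) -> dict:
        return {"shape": self.shape, "scale": self.scale,
                "ci95": list(self.ci95), "n": self.n, "label": self.label}


def _crossing(times: np.ndarray, s2: np.ndarray, i: int, level: float) -> float:
    """Time at which s2 crosses ``level`` between windows i and i+1."""
    y0, y1 = s2[i], s2[i + 1]
    if y1 == y0:
        return float(times[i])
    frac = (level - y0) / (y1 - y0)
    frac = min(max(frac, 0.0), 1.0)
    return float(times[i] + frac * (times[i + 1] - times[i]))


def _runs(mask: np.ndarray) -> list:
    """Maximal runs of True as (start, end) index pairs, end inclusive."""
    out = []
    i, n = 0, mask.size
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        out.append((i, j))
        i = j + 1
    return out


def extract_substates(mpd: MPD, lo_thr: float = 0.05, hi_thr: float = 0.95,
                      min_dwell_s: float = 0.0,
                      smooth_s: float = 0.0) -> SubStateIntervals:
    """Delimit r_o / r_s / r_e intervals from SLE-posterior fluctuations.

    Windows with s2 above ``hi_thr`` (below ``lo_thr``) that persist for at
    least ``min_dwell_s`` form committed SLE (inter-SLE) spans; brief
    excursions shorter than the dwell are treated as posterior fluctuation
    and absorbed into the transitions.  Each SLE is a block of committed
    high spans with no committed low span between them: r_s runs from the
    first to the last committed-high window (interpolated hi-threshold
    crossings), r_o from the end of the preceding committed-low span (its
    interpolated lo-crossing) to the start of r_s, and r_e mirrors r_o on
    the way down, so the fluctuation regions around state changes are the
    transitions.  With ``min_dwell_s = 0`` the rule reduces to plain
    threshold crossings: a step posterior gives one-window transitions and
    a ramp's interior becomes the transition.  SLEs truncated by the trace
    edges are dropped (censored durations would bias the gamma fits).

    ``smooth_s`` > 0 applies a moving average of that width to the
    posterior before thresholding.  Near state changes the posterior
    fluctuates in bursts; its local average is then the fraction of time
    spent in the SLE state, which ramps smoothly across a transition, so
    the crossing rule delimits the whole fluctuation span rather than
    individual bursts.
    """
    if not (0 < lo_thr < hi_thr < 1):
        raise ValueError("need 0 < lo_thr < hi_thr < 1")
    s2 = np.asarray(mpd.s2, dtype=float)
    times = np.asarray(mpd.window_times, dtype=float)
    n = s2.size
    if smooth_s > 0 and n > 2:
        dt_ = float(np.median(np.diff(times)))
        w = max(int(round(smooth_s / dt_)), 1)
        if w > 1:
            kernel = np.ones(w) / w
            s2 = np.convolve(s2, kernel, mode="same")
    if n < 3:
        warnings.warn("posterior too short for sub-state extraction",
                      stacklevel=2)
        return SubStateIntervals(r_o=[], r_s=[], r_e=[], inter_sle=[])
    dt = float(np.median(np.diff(times)))
    min_run = max(int(np.ceil(min_dwell_s / dt)), 1)
    high_runs = [r for r in _runs(s2 > hi_thr) if r[1] - r[0] + 1 >= min_run]
    low_runs = [r for r in _runs(s2 < lo_thr) if r[1] - r[0] + 1 >= min_run]
    r_o, r_s, r_e = [], [], []

    # group committed-high runs separated by no committed-low run
    groups = []
    for run in high_runs:
        if groups and not any(lr[0] > groups[-1][-1][1] and lr[1] < run[0]
                              for lr in low_runs):
            groups[-1].append(run)
        else:
            groups.append([run])
    for grp in groups:
        i = grp[0][0]       # first committed-high window
        j = grp[-1][1]      # last committed-high window
        prev_lows = [lr for lr in low_runs if lr[1] < i]
        next_lows = [lr for lr in low_runs if lr[0] > j]
        if not prev_lows or not next_lows or i == 0 or j == n - 1:
            continue        # truncated at a trace edge
        k = prev_lows[-1][1]   # last window of the preceding committed low
        l = next_lows[0][0]    # first window of the following committed low
        t_lo_up = _crossing(times, s2, k, lo_thr) if k + 1 < n else times[k]
        t_hi_up = _crossing(times, s2, i - 1, hi_thr)
        t_hi_dn = _crossing(times, s2, j, hi_thr)
        t_lo_dn = _crossing(times, s2, l - 1, lo_thr)
        if not (t_lo_up <= t_hi_up <= t_hi_dn <= t_lo_dn):
            continue
        r_o.append((t_lo_up, t_hi_up))
        r_s.append((t_hi_up, t_hi_dn))
        r_e.append((t_hi_dn, t_lo_dn))

    if not r_o:
        warnings.warn("no complete SLE found in the posterior", stacklevel=2)
    inter = [(r_e[k][1], r_o[k + 1][0]) for k in range(len(r_o) - 1)]
    return SubStateIntervals(r_o=r_o, r_s=r_s, r_e=r_e, inter_sle=inter)


def duration_intensity(lfp: Trace, intervals: SubStateIntervals) -> SLEMetrics:
    """Duration and intensity per classified SLE and sub-interval."""
    fs = lfp.sampling_rate
    labels = ("r_o", "r_s", "r_e")
    sub_d = {lab: [] for lab in labels}
    sub_i = {lab: [] for lab in labels}
    totals_d, totals_i = [], []
    for o, s, e in zip(intervals.r_o, intervals.r_s, intervals.r_e):
        tot_energy = 0.0
        tot_len = 0.0
        for lab, (a, b) in zip(labels, (o, s, e)):
            if b <= a:
                raise ValueError(f"empty {lab} interval ({a}, {b})")
            seg = lfp.slice(a, b)
            energy = float(np.sum(seg.samples ** 2))
            length = b - a
            sub_d[lab].append(length)
            sub_i[lab].append(energy / length)
            tot_energy += energy
            tot_len += length
        totals_d.append(tot_len)
        totals_i.append(tot_energy / tot_len)
    return SLEMetrics(
        duration=np.asarray(totals_d),
        sub_durations={k: np.asarray(v) for k, v in sub_d.items()},
        intensity=np.asarray(totals_i),
        sub_intensity={k: np.asarray(v) for k, v in sub_i.items()},
    )


def fit_gamma_durations(durations, min_n: int = 5) -> GammaFit:
    """Gamma MLE of a duration sample, with an asymptotic shape CI.

    The 95% CI on the shape comes from the observed Fisher information of
    the (shape, scale) likelihood: Var(alpha_hat) = alpha / (n (alpha
    psi1(alpha) - 1)).  The dynamics label uses the CI: hi < 1 stochastic,
    lo > 1 deterministic, CI covering 1 Poisson-compatible.
    """
    x = np.asarray(durations, dtype=float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} durations")
    if np.any(x <= 0):
        raise ValueError("durations must be positive")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    n = x.size
    denom = shape * special.polygamma(1, shape) - 1.0
    if denom <= 0:
        se = np.inf
    else:
        se = np.sqrt(shape / (n * denom))
    lo, hi = shape - 1.959963984540054 * se, shape + 1.959963984540054 * se
    if hi < 1.0:
        label = "stochastic"
    elif lo > 1.0:
        label = "deterministic"
    else:
        label = "Poisson"
    return GammaFit(shape=float(shape), scale=float(scale),
                    ci95=(float(lo), float(hi)), label=label, n=n)


_BANDS = ((0.1, "none"), (0.305, "weak"), (0.695, "moderate"), (1.0001, "strong"))


def correlate_metrics(x, y):
    """Pearson correlation with the study's strength bands on |r|.

    |r| < 0.1 none, 0.1-0.3 weak, 0.31-0.69 moderate, 0.7-1 strong.
    Returns (r, p, label).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    a = abs(r)
    label = next(lab for thr, lab in _BANDS if a < thr)
    return float(r), float(p), label
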