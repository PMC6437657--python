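"""ROC evaluation of the posterior classifier against a power-based reference.

A conventional amplitude/power definition of the SLE state (signal power
rising to 3x a pre-event baseline, termination at the return to baseline
followed by a >10-s quiet refractory period) provides reference intervals.
Sweeping a threshold over the SLE-state posterior yields per-window
confusion counts - windows inside a reference SLE are true positives or
false negatives, windows outside are false positives or true negatives -
and hence an ROC curve, its trapezoidal AUC, and a one-parameter
exponential summary

    sensitivity = 1 - exp(-(1 - specificity) / xi)

whose specificity factor xi approaches 0 for an ideal classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .hmm import MPD
from .preprocess import Trace

__all__ = ["ROCCurve", "power_based_state", "roc_from_mpd",
           "fit_specificity_factor"]


@dataclass
class ROCCurve:
    """Threshold sweep of the posterior classifier."""

    thresholds: np.ndarray
    sensitivity: np.ndarray       # per threshold
    specificity: np.ndarray
    auc: float
    xi: float | None = None
    optimal: tuple | None = None  # (sensitivity, specificity)

    @property
    def points(self) -> np.ndarray:
        """(1 - specificity, sensitivity) pairs."""
        return np.column_stack([1 - self.specificity, self.sensitivity])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("threshold\tsensitivity\tspecificity\n")
            for t, se, sp in zip(self.thresholds, self.sensitivity,
                                 self.specificity):
                fh.write(f"{t:.6f}\t{se:.6f}\t{sp:.6f}\n")


def power_based_state(lfp: Trace, baseline_window: tuple,
                      factor: float = 3.0, smooth_s: float = 1.0,
                      refractory_s: float = 10.0) -> list:
    """Reference SLE intervals from smoothed signal power.

    Power is the squared signal smoothed by a ``smooth_s`` moving average;
    baseline is the median power over ``baseline_window`` (a pre-SLE quiet
    stretch).  An SLE starts when power reaches ``factor`` times baseline
    and terminates at the return below that level; bursts separated by less
    than ``refractory_s`` of quiet are merged into one event.

    Returns a list of (start_s, end_s) tuples (empty if power never
    crosses).
    """
    fs = lfp.sampling_rate
    power = lfp.samples.astype(float) ** 2
    w = max(int(round(smooth_s * fs)), 1)
    kernel = np.ones(w) / w
    power = np.convolve(power, kernel, mode="same")
    b0, b1 = baseline_window
    i0 = max(int(round((b0 - lfp.t0) * fs)), 0)
    i1 = min(int(round((b1 - lfp.t0) * fs)), lfp.n_samples)
    if i1 <= i0:
        raise ValueError("empty baseline window")
    baseline = float(np.median(power[i0:i1]))
    if baseline <= 0:
        baseline = np.finfo(float).tiny
    above = power >= factor * baseline
    if not np.any(above):
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(lfp.n_samples)
    merged = []
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1]) / fs < refractory_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(lfp.t0 + s / fs, lfp.t0 + e / fs) for s, e in merged]


def roc_from_mpd(mpd: MPD, reference: list, thresholds=None) -> ROCCurve:
    """ROC of the SLE posterior against reference intervals.

    For each threshold, a window is classified SLE when its posterior
    exceeds the threshold; reference-SLE windows then count as Tp/Fn and
    inter-SLE windows as Fp/Tn.  AUC is the trapezoidal area over the
    sorted sweep (anchored at (0,0) and (1,1)).
    """
    if not reference:
        raise ValueError("reference intervals are empty")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.asarray(thresholds, dtype=float)
    times = np.asarray(mpd.window_times, dtype=float)
    inside = np.zeros(times.size, dtype=bool)
    for a, b in reference:
        inside |= (times >= a) & (times < b)
    s2 = np.asarray(mpd.s2, dtype=float)
    n_pos = int(inside.sum())
    n_neg = int((~inside).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("reference must leave windows on both sides")
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for k, thr in enumerate(thresholds):
        pred = s2 > thr
        tp = int(np.sum(pred & inside))
        fp = int(np.sum(pred & ~inside))
        sens[k] = tp / n_pos
        spec[k] = 1.0 - fp / n_neg
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # ties in fpr ordered by sensitivity
    xs = np.concatenate([[0.0], fpr[order], [1.0]])
    ys = np.concatenate([[0.0], sens[order], [1.0]])
    auc = float(np.trapezoid(ys, xs))
    return ROCCurve(thresholds=thresholds, sensitivity=sens,
                    specificity=spec, auc=auc)


def fit_specificity_factor(roc: ROCCurve):
    """Fit the exponential ROC summary and locate the optimal point.

    Least-squares fit of sensitivity = 1 - exp(-(1 - specificity)/xi) to
    the swept points; the optimal operating point is the point on the
    fitted curve nearest the ideal corner (fpr, sens) = (0, 1), reported as
    (sensitivity, specificity).  On fit failure the nearest empirical point
    is returned with ``xi = None`` and a warning.
    """
    pts = roc.points
    if pts.shape[0] < 5:
        raise ValueError("need at least 5 ROC points")
    # anchor the sweep at the trivial corners so degenerate (perfect) sweeps
    # still constrain the exponential
    x = np.concatenate([pts[:, 0], [0.0, 1.0]])
    y = np.concatenate([pts[:, 1], [0.0, 1.0]])

    def model(x, xi):
        return 1.0 - np.exp(-x / np.maximum(xi, 1e-12))

    def loss(log_xi):
        return float(np.sum((y - model(x, 10.0 ** log_xi)) ** 2))

    try:
        res = optimize.minimize_scalar(loss, bounds=(-12.0, 3.0),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        if not res.success:
            raise RuntimeError(res.message)
        xi = float(10.0 ** res.x)
    except (RuntimeError, ValueError):
        warnings.warn("specificity-factor fit diverged; "
                      "reporting nearest empirical point", stacklevel=2)
        d = np.hypot(x - 0.0, y - 1.0)
        k = int(np.argmin(d))
        opt = (float(y[k]), float(1 - x[k]))
        roc.xi = None
        roc.optimal = opt
        return None, opt

    grid = np.linspace(0.0, 1.0, 2001)
    curve = model(grid, xi)
    d = np.hypot(grid, curve - 1.0)
    k = int(np.argmin(d))
    opt = (float(curve[k]), float(1.0 - grid[k]))
    roc.xi = xi
    roc.optimal = opt
    return xi, opt
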