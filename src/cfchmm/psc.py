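"""Postsynaptic-current event analysis: detection, charge transfer, phase locking.

Spontaneous EPSCs (held at -70 mV, inward/negative) and IPSCs (held at
0 mV, outward/positive) are detected as rectified peaks exceeding a
multiple of the pre-event baseline SD with a 50-ms minimum separation.
Charge transfer across a sub-state is integrated by the trapezoidal rule in
amortized time (ten equal-duration bins per sub-state, compared against the
10% pre-onset baseline bin).  Phase coherence of event timing with a slow
field rhythm is quantified by the phase-locking value (mean resultant
length of unit phasors at the event phases) with the Rayleigh test for
circular uniformity; a recursive threshold search raises the detection
threshold until a sub-population with moderate locking (PLV > 0.3,
p < 0.05) emerges, if one exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import Trace

__all__ = [
    "PSCEventTrain",
    "ChargeTransferProfile",
    "PhaseLockingResult",
    "detect_events",
    "charge_transfer",
    "event_phase_locking",
    "recursive_threshold_search",
    "plv_band_comparison",
]


@dataclass
class PSCEventTrain:
    """Detected PSC events."""

    times: np.ndarray            # s, strictly increasing
    amplitudes: np.ndarray       # pA, positive (rectified)
    polarity: str                # EPSC or IPSC
    detection_threshold: float   # pA

    def __post_init__(self) -> None:
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be positive")

    @property
    def n_events(self) -> int:
        return self.times.size


@dataclass
class ChargeTransferProfile:
    """Amortized-time charge profile of a sub-state.

    ``energy`` rows are per-SLE, columns the 10 in-state bins; ``baseline``
    holds the pre-onset 10% bin per SLE.  ``comparisons`` is a DataFrame of
    per-bin tests against the baseline bin (Wilcoxon signed-rank,
    Bonferroni corrected) when >= 5 SLEs are available.
    """

    energy: np.ndarray           # (n_sles, 10), pA*s
    baseline: np.ndarray         # (n_sles,)
    comparisons: pd.DataFrame | None = None


@dataclass
class PhaseLockingResult:
    freq: float
    plv: float
    mean_phase: float
    rayleigh_p: float
    n_events: int
    threshold_used: float
    significant: bool = False


def _rectify(current: Trace, polarity: str) -> np.ndarray:
    if polarity == "EPSC":
        return -current.samples      # inward currents deflect negative
    if polarity == "IPSC":
        return current.samples.copy()
    raise ValueError("polarity must be 'EPSC' or 'IPSC'")


def detect_events(current: Trace, baseline_window: tuple,
                  polarity: str = "EPSC", min_dist_ms: float = 50.0,
                  k_sd: float = 3.0) -> PSCEventTrain:
    """Threshold-based peak detection of PSC events.

    ``baseline_window`` is a (start_s, end_s) quiet stretch preceding the
    analysis region; its SD sets the detection threshold ``k_sd`` times SD.
    """
    x = _rectify(current, polarity)
    fs = current.sampling_rate
    base = current.slice(*baseline_window)
    sd = float(np.std(_rectify(base, polarity)))
    if sd == 0:
        raise ValueError("zero-variance baseline window")
    thr = k_sd * sd
    dist = max(int(round(min_dist_ms / 1000.0 * fs)), 1)
    peaks, props = signal.find_peaks(x, height=thr, distance=dist)
    return PSCEventTrain(
        times=current.t0 + peaks / fs,
        amplitudes=props["peak_heights"],
        polarity=polarity,
        detection_threshold=thr,
    )


def charge_transfer(current: Trace, intervals, polarity: str = "EPSC",
                    n_bins: int = 10, alpha: float = 0.05) -> ChargeTransferProfile:
    """Amortized-time charge transfer of a sub-state across SLEs.

    ``intervals`` is a list of (start_s, end_s) sub-state spans, one per
    SLE.  Each span is cut into ``n_bins`` equal-duration bins and the
    baseline-subtracted rectified current integrated per bin by the
    trapezoidal rule; the pre-onset bin covers the 10% of the span duration
    immediately before the span.  Per-bin comparisons against the baseline
    bin use the Wilcoxon signed-rank test with Bonferroni correction when
    at least 5 SLEs are supplied.
    """
    if not intervals:
        raise ValueError("no sub-state intervals given")
    fs = current.sampling_rate
    energies = []
    baselines = []
    for (a, b) in intervals:
        n_samp = int(round((b - a) * fs))
        if n_samp < n_bins:
            raise ValueError(f"interval ({a}, {b}) shorter than {n_bins} samples")
        span = b - a
        pre = current.slice(max(a - 0.1 * span, current.t0), a)
        pre_x = np.abs(_rectify(pre, polarity))
        baseline_level = float(np.median(pre_x))
        row = []
        for k in range(n_bins):
            seg = current.slice(a + span * k / n_bins,
                                a + span * (k + 1) / n_bins)
            y = np.abs(_rectify(seg, polarity)) - baseline_level
            row.append(float(np.trapezoid(y, dx=1.0 / fs)))
        energies.append(row)
        baselines.append(float(np.trapezoid(pre_x - baseline_level,
                                            dx=1.0 / fs)))
    energy = np.asarray(energies)
    baseline = np.asarray(baselines)
    comparisons = None
    if energy.shape[0] >= 5:
        rows = []
        for k in range(n_bins):
            diff = energy[:, k] - baseline
            if np.allclose(diff, 0):
                stat_, p = np.nan, 1.0
            else:
                stat_, p = stats.wilcoxon(energy[:, k], baseline)
            rows.append({"bin": k, "stat": stat_, "p": p})
        comp = pd.DataFrame(rows)
        comp["p_bonf"] = multipletests(comp["p"], method="bonferroni")[1]
        comp["significant"] = comp["p_bonf"] < alpha
        comparisons = comp
    return ChargeTransferProfile(energy=energy, baseline=baseline,
                                 comparisons=comparisons)


def _phase_at_times(phase_series: np.ndarray, t0: float, fs: float,
                    times: np.ndarray) -> np.ndarray:
    idx = np.clip(np.round((times - t0) * fs).astype(int), 0,
                  phase_series.size - 1)
    return phase_series[idx]


def event_phase_locking(events: PSCEventTrain, phase_series: np.ndarray,
                        freq: float, fs: float, t0: float = 0.0,
                        threshold_used: float | None = None,
                        alpha: float = 0.05) -> PhaseLockingResult:
    """PLV and Rayleigh test of event phases on one slow rhythm.

    ``phase_series`` is the instantaneous phase (radians) of the rhythm at
    ``freq`` on the clamp-trace sample grid.
    """
    if events.n_events == 0:
        raise ValueError("phase locking undefined without events")
    phases = _phase_at_times(np.asarray(phase_series, float), t0, fs,
                             events.times)
    vec = np.exp(1j * phases).mean()
    plv = float(np.abs(vec))
    if events.n_events >= 2:
        _, p = pg.circ_rayleigh(phases)
    else:
        p = 1.0
    thr = events.detection_threshold if threshold_used is None else threshold_used
    return PhaseLockingResult(
        freq=float(freq), plv=plv, mean_phase=float(np.angle(vec)),
        rayleigh_p=float(p), n_events=events.n_events,
        threshold_used=float(thr), significant=bool(plv > 0.3 and p < alpha),
    )


def recursive_threshold_search(current: Trace, phases: np.ndarray,
                               phase_freqs, baseline_window: tuple,
                               region: tuple | None = None,
                               polarity: str = "EPSC",
                               plv_min: float = 0.3, alpha: float = 0.05,
                               n_thresholds: int = 20,
                               max_multiplier: float = 30.0,
                               min_events: int = 5) -> PhaseLockingResult:
    """Raise the detection threshold until moderate phase locking emerges.

    Sweeps ``n_thresholds`` log-spaced SD multipliers from 3x up to
    ``max_multiplier``x; at each, events inside ``region`` are detected and
    the PLV computed for every slow frequency.  The first (lowest)
    threshold yielding PLV > ``plv_min`` with Rayleigh p < ``alpha`` at any
    frequency is returned (at its best frequency).  If none qualifies the
    maximum-PLV result is returned flagged non-significant; if no threshold
    leaves ``min_events`` events the result has ``n_events = 0``.

    ``phases`` has shape (n_phase_freqs, n_samples) on the clamp grid.
    """
    phase_freqs = np.atleast_1d(np.asarray(phase_freqs, dtype=float))
    if phases.shape[0] != phase_freqs.size:
        raise ValueError("phases rows must match phase_freqs")
    fs = current.sampling_rate
    base = current.slice(*baseline_window)
    sd = float(np.std(_rectify(base, polarity)))
    if sd == 0:
        raise ValueError("zero-variance baseline window")
    multipliers = np.geomspace(3.0, max_multiplier, n_thresholds)
    best = None
    for mult in multipliers:
        ev = detect_events(current, baseline_window, polarity=polarity,
                           k_sd=mult)
        if region is not None:
            sel = (ev.times >= region[0]) & (ev.times < region[1])
            ev = PSCEventTrain(times=ev.times[sel],
                               amplitudes=ev.amplitudes[sel],
                               polarity=ev.polarity,
                               detection_threshold=ev.detection_threshold)
        if ev.n_events < min_events:
            continue
        for fi, f in enumerate(phase_freqs):
            res = event_phase_locking(ev, phases[fi], f, fs, t0=current.t0,
                                      alpha=alpha)
            if best is None or res.plv > best.plv:
                best = res
        # qualifying threshold: stop at the first one (ascending search)
        cand = [event_phase_locking(ev, phases[fi], f, fs, t0=current.t0,
                                    alpha=alpha)
                for fi, f in enumerate(phase_freqs)]
        qual = [c for c in cand if c.plv > plv_min and c.rayleigh_p < alpha]
        if qual:
            return max(qual, key=lambda c: c.plv)
    if best is None:
        return PhaseLockingResult(freq=np.nan, plv=0.0, mean_phase=np.nan,
                                  rayleigh_p=1.0, n_events=0,
                                  threshold_used=np.nan, significant=False)
    best.significant = False
    return best


def plv_band_comparison(plv_epsc: pd.DataFrame, plv_ipsc: pd.DataFrame,
                        alpha: float = 0.05,
                        method: str = "bonferroni") -> pd.DataFrame:
    """Per-frequency comparison of PLV distributions between current types.

    Inputs are DataFrames with one row per SLE and one column per slow
    frequency (Hz).  Each shared band is compared with a two-sided
    Mann-Whitney U test, corrected for multiplicity; medians and quartiles
    of both groups are reported.
    """
    bands = [c for c in plv_epsc.columns if c in plv_ipsc.columns]
    if not bands:
        raise ValueError("no shared frequency bands")
    if len(plv_epsc) < 3 or len(plv_ipsc) < 3:
        raise ValueError("need >= 3 SLEs per group")
    rows = []
    for b in bands:
        x = plv_epsc[b].dropna().to_numpy()
        y = plv_ipsc[b].dropna().to_numpy()
        if np.array_equal(np.sort(x), np.sort(y)):
            stat_, p = np.nan, 1.0
        else:
            stat_, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append({
            "freq": b, "stat": stat_, "p": p,
            "epsc_median": np.median(x), "ipsc_median": np.median(y),
            "epsc_q1": np.percentile(x, 25), "epsc_q3": np.percentile(x, 75),
            "ipsc_q1": np.percentile(y, 25), "ipsc_q3": np.percentile(y, 75),
        })
    out = pd.DataFrame(rows)
    out["p_corr"] = multipletests(out["p"], method=method)[1]
    out["significant"] = out["p_corr"] < alpha
    out["favors"] = np.where(
        out["significant"],
        np.where(out["ipsc_median"] > out["epsc_median"], "IPSC", "EPSC"),
        "",
    )
    return out
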