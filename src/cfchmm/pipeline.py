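"""End-to-end convenience drivers: trace -> features -> fitted HMM -> sub-states.

Thin glue over the module layer so control analyses, tests and scripts can
run the whole chain with one call.  Training features use non-overlapping
2-s windows; testing features use 95% overlap (0.1-s posterior resolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cfc
from .cfc import CFCSeries, FeatureSet, build_feature_set, cfc_series
from .hmm import MPD, SubstateHMM, SubstateHMMResults
from .preprocess import Trace
from .substates import SubStateIntervals, extract_substates, fit_gamma_durations

__all__ = ["PipelineResult", "compute_cfc", "classify_trace", "substate_gamma_fits"]


@dataclass
class PipelineResult:
    """Everything the trace-level analysis produces."""

    cfc_train: CFCSeries
    cfc_test: CFCSeries
    features_train: FeatureSet
    features_test: FeatureSet
    hmm: SubstateHMMResults
    mpd: MPD
    intervals: SubStateIntervals


def compute_cfc(trace: Trace, overlap: float, phase_freqs=None,
                amp_freqs=None, window_s: float = 2.0) -> CFCSeries:
    """Modulation-index grid for one trace at the given window overlap."""
    return cfc_series(trace, phase_freqs=phase_freqs, amp_freqs=amp_freqs,
                      window_s=window_s, overlap=overlap)


def classify_trace(trace: Trace, train_trace: Trace | None = None,
                   phase_freqs=None, amp_freqs=None,
                   phase_edges=cfc.DEFAULT_PHASE_EDGES,
                   amp_edges=cfc.DEFAULT_AMP_EDGES,
                   n_mix: int = 2, seed: int = 0,
                   test_overlap: float = 0.95,
                   lo_thr: float = 0.1, hi_thr: float = 0.85,
                   min_dwell_s: float = 2.0, smooth_s: float = 4.0,
                   cfc_train: CFCSeries | None = None,
                   cfc_test: CFCSeries | None = None) -> PipelineResult:
    """Train the state HMM and classify sub-states on a trace.

    ``train_trace`` defaults to the test trace itself (self-trained, the
    usual in-vitro workflow); cross-model transfer passes a different
    training trace.  Precomputed CFC grids can be supplied to avoid
    recomputation in ablation studies.
    """
    if cfc_train is None:
        src = trace if train_trace is None else train_trace
        cfc_train = compute_cfc(src, overlap=0.0, phase_freqs=phase_freqs,
                                amp_freqs=amp_freqs)
    if cfc_test is None:
        cfc_test = compute_cfc(trace, overlap=test_overlap,
                               phase_freqs=phase_freqs, amp_freqs=amp_freqs)
    f_train = build_feature_set(cfc_train, phase_edges, amp_edges)
    f_test = build_feature_set(cfc_test, phase_edges, amp_edges)
    if train_trace is not None:
        # cross-recording transfer: the test features must live in the
        # model's feature space, so the training trace's normalization
        # bounds apply
        f_test = build_feature_set(cfc_test, phase_edges, amp_edges,
                                   norm_bounds=f_train.row_norm_bounds)
    else:
        # same recording at two strides: one trace, one set of row
        # normalization bounds (the union), else the fine test grid's
        # extremes shift the normalized features the model was trained on
        lo = np.minimum(f_train.row_norm_bounds[:, 0], f_test.row_norm_bounds[:, 0])
        hi = np.maximum(f_train.row_norm_bounds[:, 1], f_test.row_norm_bounds[:, 1])
        bounds = np.column_stack([lo, hi])
        f_train = build_feature_set(cfc_train, phase_edges, amp_edges,
                                    norm_bounds=bounds)
        f_test = build_feature_set(cfc_test, phase_edges, amp_edges,
                                   norm_bounds=bounds)
    res = SubstateHMM(f_train, n_mix=n_mix).fit(seed=seed)
    mpd = res.posterior(f_test, overlap=cfc_test.overlap)
    # excursions shorter than a few analysis windows are posterior
    # fluctuation, i.e. transition material, not separate state visits;
    # committed states in these preparations last tens of seconds
    intervals = extract_substates(mpd, lo_thr=lo_thr, hi_thr=hi_thr,
                                  min_dwell_s=min_dwell_s, smooth_s=smooth_s)
    return PipelineResult(cfc_train=cfc_train, cfc_test=cfc_test,
                          features_train=f_train, features_test=f_test,
                          hmm=res, mpd=mpd, intervals=intervals)


def substate_gamma_fits(intervals: SubStateIntervals, min_n: int = 5) -> dict:
    """Gamma fits of the pooled r_o / r_s / r_e duration histograms."""
    out = {}
    for lab in ("r_o", "r_s", "r_e"):
        durs = intervals.durations(lab)
        durs = durs[durs > 0]
        if durs.size >= min_n:
            out[lab] = fit_gamma_durations(durs, min_n=min_n)
    return out
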