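"""Phase-amplitude cross-frequency coupling features.

The modulation index quantifies how strongly the amplitude of a fast
oscillation depends on the phase of a slow one: the instantaneous phase is
cut into equal bins (20 degrees by default), the mean fast-band amplitude in
each bin is normalised to a probability-like distribution A_norm, and the
Kullback-Leibler distance of A_norm from the uniform distribution, divided
by log(N_bins), gives an index in [0, 1].  0 means the amplitude carries no
phase information; 1 means all amplitude mass sits in a single phase bin.

A time-resolved grid of indices over (phase frequency x amplitude frequency
x sliding window) is reduced to a 4 x 4 band image (log-spaced amplitude
bands), unwrapped to 16 features, and augmented with their time derivatives
to give the 32-row feature matrix consumed by the state classifier.
Significance of coupling in a single window is assessed against
block-shuffled phase surrogates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import Trace, morlet_cwt

__all__ = [
    "CFCSeries",
    "FeatureSet",
    "SurrogateResult",
    "modulation_index",
    "modulation_index_from_binned",
    "cfc_series",
    "build_feature_set",
    "surrogate_significance",
    "cfc_power_correlation",
    "DEFAULT_PHASE_FREQS",
    "DEFAULT_AMP_FREQS",
    "DEFAULT_PHASE_EDGES",
    "DEFAULT_AMP_EDGES",
]

DEFAULT_PHASE_FREQS = np.arange(1.0, 13.0, 1.0)          # 1-12 Hz, 1-Hz steps
DEFAULT_AMP_FREQS = np.arange(30.0, 255.0, 5.0)          # 30-250 Hz, 5-Hz steps
DEFAULT_PHASE_EDGES = (1.0, 3.75, 6.5, 9.25, 12.0)       # linear split
DEFAULT_AMP_EDGES = (30.0, 51.0, 87.0, 147.0, 250.0)     # log-even split


def modulation_index_from_binned(a_norm: np.ndarray) -> float:
    """Modulation index of an already phase-binned amplitude distribution.

    ``a_norm`` is the normalised mean-amplitude-per-bin distribution (sums
    to 1).  Empty bins receive a machine-epsilon mass so the KL distance
    stays finite, then the distribution is renormalised.
    """
    p = np.asarray(a_norm, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("a_norm must be a 1-d distribution over >= 2 bins")
    if np.any(p < 0):
        raise ValueError("a_norm must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("a_norm has no mass")
    p = p / total
    eps = np.finfo(float).eps
    p = np.where(p > 0, p, eps)
    p = p / p.sum()
    n = p.size
    kl = float(np.sum(p * np.log(p * n)))
    return kl / np.log(n)


def modulation_index(phase: np.ndarray, amplitude: np.ndarray,
                     bin_deg: float = 20.0) -> float:
    """Phase-amplitude modulation index for one phase/amplitude pair.

    Parameters
    ----------
    phase : ndarray
        Instantaneous phase in radians (wrapped to any 2*pi interval).
    amplitude : ndarray
        Instantaneous amplitude, non-negative, same length as ``phase``.
    bin_deg : float
        Phase bin width in degrees; must divide 360.

    Returns
    -------
    float
        Index in [0, 1].
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape or phase.ndim != 1:
        raise ValueError("phase and amplitude must be equal-length 1-d arrays")
    if np.any(amplitude < 0):
        raise ValueError("amplitude must be non-negative")
    if not np.any(amplitude > 0):
        raise ValueError("modulation index undefined for all-zero amplitude")
    n_bins = 360.0 / bin_deg
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_deg must divide 360")
    n_bins = int(round(n_bins))
    idx = _phase_bin_indices(phase, n_bins)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return modulation_index_from_binned(means)


def _phase_bin_indices(phase: np.ndarray, n_bins: int) -> np.ndarray:
    """Map wrapped phases to bin indices 0..n_bins-1 on [-pi, pi)."""
    wrapped = np.mod(phase + np.pi, 2 * np.pi)  # [0, 2pi)
    idx = (wrapped / (2 * np.pi) * n_bins).astype(np.intp)
    return np.minimum(idx, n_bins - 1)


@dataclass
class CFCSeries:
    """Time-resolved modulation-index grid.

    ``mi`` has shape (n_phase_freqs, n_amp_freqs, n_windows); window times
    refer to window starts on the parent trace's clock.
    """

    mi: np.ndarray
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    window_s: float
    overlap: float
    window_times: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.mi < -1e-12) or np.any(self.mi > 1 + 1e-12):
            raise ValueError("modulation indices must lie in [0, 1]")

    @property
    def n_windows(self) -> int:
        return self.mi.shape[2]


@dataclass
class FeatureSet:
    """Normalised feature matrix for the state classifier.

    Rows 0..n_base-1 are band-averaged modulation indices (phase band x
    amplitude band, row-major over (amplitude band, phase band)); rows
    n_base..2*n_base-1 are their time derivatives. Every row is min-max
    normalised across the full trace.
    """

    matrix: np.ndarray                       # (2*n_base, n_windows)
    row_norm_bounds: np.ndarray              # (2*n_base, 2) pre-normalisation (min, max)
    window_times: np.ndarray
    phase_bands: list = field(default_factory=list)   # (lo, hi) per base row
    amp_bands: list = field(default_factory=list)
    phase_edges: tuple = DEFAULT_PHASE_EDGES
    amp_edges: tuple = DEFAULT_AMP_EDGES

    @property
    def n_base(self) -> int:
        return self.matrix.shape[0] // 2

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SurrogateResult:
    """Z-scored coupling against block-shuffled phase surrogates."""

    z: np.ndarray             # (n_phase_freqs, n_amp_freqs)
    real_mi: np.ndarray
    surrogate_mean: np.ndarray
    surrogate_sd: np.ndarray
    n_surrogates: int
    block_len: int
    sig_mask: np.ndarray      # boolean, criterion z >= z_crit
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray


def cfc_series(trace: Trace, phase_freqs=None, amp_freqs=None,
               window_s: float = 2.0, overlap: float = 0.0,
               bin_deg: float = 20.0, fb: float = 3.0, fc: float = 1.0,
               pad_s: float = 5.0) -> CFCSeries:
    """Sliding-window modulation indices over a (phase x amplitude) grid.

    Training features use non-overlapping 2-s windows (``overlap=0``);
    testing features use 95% overlap.  The wavelet transform is computed
    once per frequency over the whole trace; windowed phase-bin statistics
    are accumulated block-wise so heavy overlaps cost nothing extra.
    """
    phase_freqs = DEFAULT_PHASE_FREQS if phase_freqs is None else np.atleast_1d(
        np.asarray(phase_freqs, dtype=float))
    amp_freqs = DEFAULT_AMP_FREQS if amp_freqs is None else np.atleast_1d(
        np.asarray(amp_freqs, dtype=float))
    fs = trace.sampling_rate
    win = int(round(window_s * fs))
    if win > trace.n_samples:
        raise ValueError("window longer than trace")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must lie in [0, 1)")
    hop = max(int(round(win * (1 - overlap))), 1)
    n_bins = int(round(360.0 / bin_deg))
    if np.ptp(trace.samples) == 0:
        raise ValueError("constant trace has no oscillatory amplitude")

    amp = np.abs(
        morlet_cwt(trace, amp_freqs, fb=fb, fc=fc, pad_s=pad_s).coefficients
    )
    phase_dec = morlet_cwt(trace, phase_freqs, fb=fb, fc=fc, pad_s=pad_s)
    phase = np.angle(phase_dec.coefficients)

    n_windows = (trace.n_samples - win) // hop + 1
    starts = np.arange(n_windows) * hop
    mi = np.empty((phase_freqs.size, amp_freqs.size, n_windows))

    if win % hop == 0:
        mi[:] = _windowed_mi_blocked(phase, amp, n_bins, win, hop, n_windows)
    else:
        for w, s0 in enumerate(starts):
            sl = slice(s0, s0 + win)
            for i in range(phase_freqs.size):
                idx = _phase_bin_indices(phase[i, sl], n_bins)
                counts = np.bincount(idx, minlength=n_bins)
                for j in range(amp_freqs.size):
                    sums = np.bincount(idx, weights=amp[j, sl], minlength=n_bins)
                    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
                    mi[i, j, w] = modulation_index_from_binned(means)

    window_times = trace.t0 + starts / fs
    return CFCSeries(mi=np.clip(mi, 0.0, 1.0), phase_freqs=phase_freqs,
                     amp_freqs=amp_freqs, window_s=window_s, overlap=overlap,
                     window_times=window_times)


def _windowed_mi_blocked(phase, amp, n_bins, win, hop, n_windows):
    """Accumulate per-window phase-bin sums from hop-sized blocks.

    For hop | win, per-window bin statistics are sums of win/hop consecutive
    block statistics; blocks are computed once with a batched einsum, which
    makes the 95%-overlap testing mode as cheap as the 0%-overlap one.
    """
    n_phase, n = phase.shape
    n_amp = amp.shape[0]
    blocks_per_win = win // hop
    n_blocks = (n_windows - 1) + blocks_per_win
    usable = n_blocks * hop
    out = np.empty((n_phase, n_amp, n_windows))
    amp_b = amp[:, :usable].reshape(n_amp, n_blocks, hop)
    log_nb = np.log(n_bins)
    eps = np.finfo(float).eps
    for i in range(n_phase):
        idx = _phase_bin_indices(phase[i, :usable], n_bins)
        onehot = np.zeros((n_blocks, hop, n_bins))
        onehot[np.arange(n_blocks)[:, None], np.arange(hop)[None, :],
               idx.reshape(n_blocks, hop)] = 1.0
        # block sums: (n_amp, n_blocks, n_bins) and counts (n_blocks, n_bins)
        bsums = np.einsum("abh,bhk->abk", amp_b, onehot, optimize=True)
        bcounts = onehot.sum(axis=1)
        csums = np.concatenate(
            [np.zeros((n_amp, 1, n_bins)), np.cumsum(bsums, axis=1)], axis=1)
        ccounts = np.concatenate(
            [np.zeros((1, n_bins)), np.cumsum(bcounts, axis=0)], axis=0)
        wsums = csums[:, blocks_per_win:, :] - csums[:, :-blocks_per_win, :]
        wcounts = ccounts[blocks_per_win:, :] - ccounts[:-blocks_per_win, :]
        wsums = wsums[:, :n_windows, :]
        wcounts = wcounts[:n_windows, :]
        means = np.where(wcounts[None] > 0, wsums / np.maximum(wcounts[None], 1), 0.0)
        p = means / means.sum(axis=2, keepdims=True)
        p = np.where(p > 0, p, eps)
        p /= p.sum(axis=2, keepdims=True)
        out[i] = np.sum(p * np.log(p * n_bins), axis=2) / log_nb
    return out


def _band_rows(freqs: np.ndarray, edges) -> list:
    """Assign frequencies to bands given edges; returns per-band index lists."""
    edges = np.asarray(edges, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi == edges[-1]:
            sel = np.where((freqs >= lo) & (freqs <= hi))[0]
        else:
            sel = np.where((freqs >= lo) & (freqs < hi))[0]
        rows.append(sel)
    return rows


def build_feature_set(cfc: CFCSeries, phase_edges=DEFAULT_PHASE_EDGES,
                      amp_edges=DEFAULT_AMP_EDGES,
                      norm_bounds: np.ndarray | None = None) -> FeatureSet:
    """Rebin a CFC grid to band features and append time derivatives.

    The phase axis is split linearly and the amplitude axis log-evenly into
    four bands each; the modulation index is averaged within each cell and
    the 4 x 4 image unwrapped row-major over (amplitude band, phase band).
    Bands left empty by an ablated frequency grid are dropped.  Derivatives
    are first central differences over window index.  Each row is min-max
    normalised across the full trace; constant rows map to zero.
    """
    p_rows = _band_rows(cfc.phase_freqs, phase_edges)
    a_rows = _band_rows(cfc.amp_freqs, amp_edges)
    base = []
    phase_bands, amp_bands = [], []
    p_edges = np.asarray(phase_edges)
    a_edges = np.asarray(amp_edges)
    for ai, a_sel in enumerate(a_rows):
        for pi, p_sel in enumerate(p_rows):
            if a_sel.size == 0 or p_sel.size == 0:
                continue
            cell = cfc.mi[np.ix_(p_sel, a_sel)].mean(axis=(0, 1))
            base.append(cell)
            phase_bands.append((float(p_edges[pi]), float(p_edges[pi + 1])))
            amp_bands.append((float(a_edges[ai]), float(a_edges[ai + 1])))
    if not base:
        raise ValueError("feature rebinning produced no bands")
    base = np.asarray(base)
    if base.shape[1] < 2:
        warnings.warn("single-window trace: derivative rows are all zero",
                      stacklevel=2)
        deriv = np.zeros_like(base)
    else:
        # central difference over a fixed one-window time gap, so heavily
        # overlapped (testing) and non-overlapped (training) grids yield
        # derivative features with the same distribution
        hop_s = cfc.window_s * (1.0 - cfc.overlap)
        if cfc.window_times.size > 1:
            hop_s = float(np.median(np.diff(cfc.window_times)))
        k = max(int(round(cfc.window_s / max(hop_s, 1e-12))), 1)
        k = min(k, base.shape[1] - 1)
        upper = np.concatenate([base[:, k:], np.repeat(base[:, -1:], k, axis=1)],
                               axis=1)
        lower = np.concatenate([np.repeat(base[:, :1], k, axis=1), base[:, :-k]],
                               axis=1)
        deriv = (upper - lower) / (2.0 * k * hop_s)
    raw = np.vstack([base, deriv])
    if norm_bounds is not None:
        lo = np.asarray(norm_bounds)[:, :1]
        hi = np.asarray(norm_bounds)[:, 1:2]
    else:
        lo = raw.min(axis=1, keepdims=True)
        hi = raw.max(axis=1, keepdims=True)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    norm = np.clip(np.where(span > 0, (raw - lo) / safe, 0.0), 0.0, 1.0)
    return FeatureSet(
        matrix=norm,
        row_norm_bounds=np.hstack([lo, hi]),
        window_times=cfc.window_times.copy(),
        phase_bands=phase_bands,
        amp_bands=amp_bands,
        phase_edges=tuple(phase_edges),
        amp_edges=tuple(amp_edges),
    )


def surrogate_significance(trace: Trace, at: float, window_s: float = 5.0,
                           n: int = 200, phase_freqs=None, amp_freqs=None,
                           block_frac: float = 0.01, z_crit: float = 3.0,
                           seed: int | None = None, fb: float = 3.0,
                           fc: float = 1.0) -> SurrogateResult:
    """Test coupling in one window against block-shuffled phase surrogates.

    The phase series of each slow frequency is shuffled in blocks of 1% of
    the sampling rate (10 samples at 1 kHz), the modulation-index grid is
    recomputed ``n`` times, and the real grid is z-scored against the
    surrogate mean and SD.  Cells with z >= ``z_crit`` are flagged
    significant.
    """
    if n < 2:
        raise ValueError("need at least 2 surrogates")
    phase_freqs = DEFAULT_PHASE_FREQS if phase_freqs is None else np.atleast_1d(
        np.asarray(phase_freqs, dtype=float))
    amp_freqs = DEFAULT_AMP_FREQS if amp_freqs is None else np.atleast_1d(
        np.asarray(amp_freqs, dtype=float))
    fs = trace.sampling_rate
    win = int(round(window_s * fs))
    i0 = int(round((at - trace.t0) * fs))
    if i0 < 0 or i0 + win > trace.n_samples:
        raise ValueError("requested window extends outside the trace")
    rng = np.random.default_rng(seed)
    block = max(int(round(block_frac * fs)), 1)

    sub = trace.slice(at, at + window_s)
    amp = np.abs(morlet_cwt(sub, amp_freqs, fb=fb, fc=fc,
                            pad_s=min(5.0, window_s)).coefficients)
    phase = np.angle(morlet_cwt(sub, phase_freqs, fb=fb, fc=fc,
                                pad_s=min(5.0, window_s)).coefficients)

    n_bins = 18
    real = _mi_grid(phase, amp, n_bins)
    n_blocks = phase.shape[1] // block
    usable = n_blocks * block
    sur = np.empty((n, phase_freqs.size, amp_freqs.size))
    for s in range(n):
        perm = rng.permutation(n_blocks)
        shuffled = (phase[:, :usable].reshape(phase_freqs.size, n_blocks, block)
                    [:, perm, :].reshape(phase_freqs.size, usable))
        sur[s] = _mi_grid(shuffled, amp[:, :usable], n_bins)
    mean = sur.mean(axis=0)
    sd = sur.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, np.finfo(float).eps)
    z = (real - mean) / sd
    return SurrogateResult(
        z=z, real_mi=real, surrogate_mean=mean, surrogate_sd=sd,
        n_surrogates=n, block_len=block, sig_mask=z >= z_crit,
        phase_freqs=phase_freqs, amp_freqs=amp_freqs,
    )


def _mi_grid(phase: np.ndarray, amp: np.ndarray, n_bins: int) -> np.ndarray:
    """Modulation-index grid for full-length phase (n_p, T) x amp (n_a, T)."""
    out = np.empty((phase.shape[0], amp.shape[0]))
    for i in range(phase.shape[0]):
        idx = _phase_bin_indices(phase[i], n_bins)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        onehot = np.zeros((idx.size, n_bins))
        onehot[np.arange(idx.size), idx] = 1.0
        sums = amp @ onehot                      # (n_amp, n_bins)
        means = np.where(counts > 0, sums / np.maximum(counts, 1.0), 0.0)
        p = means / means.sum(axis=1, keepdims=True)
        eps = np.finfo(float).eps
        p = np.where(p > 0, p, eps)
        p /= p.sum(axis=1, keepdims=True)
        out[i] = np.sum(p * np.log(p * n_bins), axis=1) / np.log(n_bins)
    return out


def cfc_power_correlation(cfc_band_series: np.ndarray,
                          power_series: np.ndarray,
                          alpha: float = 0.05):
    """Correlate a coupling-index series with a slow-rhythm power series.

    Returns (r, p, genuine) where ``genuine`` flags coupling not explained
    by power co-fluctuation: True when r <= 0 or p > alpha (coupling either
    negatively correlated or uncorrelated with power).
    """
    x = np.asarray(cfc_band_series, dtype=float)
    y = np.asarray(power_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be aligned 1-d arrays")
    if x.size < 3:
        raise ValueError("need at least 3 windows")
    r, p = stats.pearsonr(x, y)
    genuine = bool(r <= 0 or p > alpha)
    return float(r), float(p), genuine
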