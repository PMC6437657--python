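"""Signal conditioning and complex-Morlet wavelet decomposition.

Field-potential traces are decimated to a working rate (1000 Hz for slice
LFP, 500 Hz for clinical iEEG), notch filtered at the mains frequency and
its harmonics, and decomposed with a complex Morlet wavelet

    W(t; f_b, f_c) = (pi f_b)^(-1/2) exp(2 i pi f_c t) exp(-t^2 / f_b)

dilated across scales so that the analysis frequency f corresponds to scale
a = f_c / (f dt).  The modulus of the wavelet coefficients gives the
instantaneous amplitude and the argument the instantaneous phase, which is
all the downstream cross-frequency coupling machinery needs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "Trace",
    "SpectralDecomposition",
    "decimate_trace",
    "notch_filter",
    "bandpass_fir",
    "morlet_cwt",
]


@dataclass
class Trace:
    """Uniformly sampled single-channel time series.

    Parameters
    ----------
    samples : ndarray
        Signal values (mV for LFP, pA for clamp currents).
    sampling_rate : float
        Sampling rate in Hz, > 0.
    units : str
        Physical units of ``samples``.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    units: str = "mV"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Trace samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Trace samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def slice(self, start_s: float, end_s: float) -> "Trace":
        """Return the sub-trace covering [start_s, end_s) in absolute time."""
        i0 = max(int(round((start_s - self.t0) * self.sampling_rate)), 0)
        i1 = min(int(round((end_s - self.t0) * self.sampling_rate)), self.n_samples)
        if i1 <= i0:
            raise ValueError("empty trace slice requested")
        return Trace(
            self.samples[i0:i1],
            self.sampling_rate,
            units=self.units,
            t0=self.t0 + i0 / self.sampling_rate,
        )


@dataclass
class SpectralDecomposition:
    """Complex Morlet coefficients on a frequency-by-time grid."""

    coefficients: np.ndarray  # complex, (n_freqs, n_times)
    center_freqs: np.ndarray  # Hz
    sampling_rate: float
    fb: float = 3.0
    fc: float = 1.0
    pad_removed: bool = True
    t0: float = 0.0

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.coefficients)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.coefficients)

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2


def decimate_trace(trace: Trace, target_rate: float) -> Trace:
    """Anti-alias filter and downsample a trace to ``target_rate``.

    Uses zero-phase IIR anti-alias filtering (scipy's decimator run with
    ``filtfilt``) applied in integer-factor stages, so the passband keeps its
    phase and DC level.
    """
    if target_rate > trace.sampling_rate:
        raise ValueError(
            f"target_rate {target_rate} exceeds sampling rate {trace.sampling_rate}"
        )
    if target_rate == trace.sampling_rate:
        return replace(trace, samples=trace.samples.copy())
    factor = trace.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("decimation requires an integer rate ratio")
    factor = int(round(factor))
    mean = trace.samples.mean()
    x = trace.samples - mean  # decimate around the mean: DC survives ripple
    # stage the decimation to keep IIR anti-alias filters well conditioned
    remaining = factor
    while remaining > 1:
        q = next(d for d in range(min(remaining, 13), 0, -1) if remaining % d == 0)
        if q == 1:  # prime factor > 13; decimate in one (conditioned) step
            q = remaining
        x = signal.decimate(x, q, ftype="iir", zero_phase=True)
        remaining //= q
    return Trace(x + mean, target_rate, units=trace.units, t0=trace.t0)


def notch_filter(trace: Trace, base: float = 60.0, n_harmonics: int = 5,
                 q: float = 30.0) -> Trace:
    """Notch out the mains frequency and its first ``n_harmonics`` harmonics.

    Harmonics at or above the Nyquist frequency are skipped with a log
    message. Each notch is a zero-phase second-order IIR notch of quality
    factor ``q`` (attenuation at the notch centre far exceeds 30 dB while the
    band +/-10 Hz away is essentially untouched).
    """
    nyq = trace.sampling_rate / 2.0
    x = trace.samples.copy()
    for k in range(1, n_harmonics + 2):
        f0 = base * k
        if f0 >= nyq:
            logger.info("notch at %.1f Hz above Nyquist (%.1f Hz); skipped", f0, nyq)
            continue
        b, a = signal.iirnotch(f0, q, fs=trace.sampling_rate)
        x = signal.filtfilt(b, a, x)
    return Trace(x, trace.sampling_rate, units=trace.units, t0=trace.t0)


def bandpass_fir(trace: Trace, lo: float, hi: float, order: int | None = None) -> Trace:
    """Zero-phase FIR band-pass between ``lo`` and ``hi`` Hz.

    The filter is applied forward and reverse (``filtfilt``), so the group
    delay is zero and the impulse response of the operation is symmetric.
    The default order scales with the low cut so narrow low bands still get
    adequate transition width, capped to a third of the trace length.
    """
    nyq = trace.sampling_rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"invalid band ({lo}, {hi}) for Nyquist {nyq}")
    if order is None:
        order = int(min(10 * trace.sampling_rate / lo, trace.n_samples // 3 - 1))
        order = max(order - order % 2, 16)  # even order -> symmetric taps
    order = min(order, max(trace.n_samples // 4, 16))
    taps = signal.firwin(order + 1, [lo, hi], pass_zero=False, fs=trace.sampling_rate)
    padlen = min(3 * order, trace.n_samples - 2)
    x = signal.filtfilt(taps, [1.0], trace.samples, padlen=padlen)
    return Trace(x, trace.sampling_rate, units=trace.units, t0=trace.t0)


def morlet_cwt(trace: Trace, freqs, fb: float = 3.0, fc: float = 1.0,
               pad_s: float = 5.0) -> SpectralDecomposition:
    """Continuous wavelet transform with a complex Morlet mother wavelet.

    A ``pad_s``-second flank is kept on either side of the signal during the
    convolution and removed afterwards to avoid edge effects; when no real
    flanking data exist the trace is reflect-padded and a warning is issued.

    Parameters
    ----------
    trace : Trace
        Input signal.
    freqs : array-like
        Analysis frequencies in Hz (must be non-empty, below Nyquist).
    fb, fc : float
        Bandwidth and centre-frequency parameters of the mother wavelet.
    pad_s : float
        Flank length reflected onto both ends before the transform.

    Returns
    -------
    SpectralDecomposition
        Complex coefficients of shape (n_freqs, n_samples).
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if freqs.size == 0:
        raise ValueError("freqs must be non-empty")
    if np.any(freqs <= 0) or np.any(freqs >= trace.sampling_rate / 2):
        raise ValueError("analysis frequencies must lie in (0, Nyquist)")
    n_pad = int(round(pad_s * trace.sampling_rate))
    x = trace.samples
    if n_pad > 0:
        if n_pad > x.size:
            n_pad = x.size
        warnings.warn(
            "reflect-padding trace flanks for the wavelet transform",
            stacklevel=2,
        ) if x.size < 2 * n_pad else None
        x = np.pad(x, n_pad, mode="reflect")

    wavelet = pywt.ContinuousWavelet(f"cmor{fb}-{fc}")
    dt = 1.0 / trace.sampling_rate
    scales = fc / (freqs * dt)
    coeffs, _ = pywt.cwt(x, scales, wavelet, sampling_period=dt, method="fft")
    if n_pad > 0:
        coeffs = coeffs[:, n_pad:-n_pad]
    return SpectralDecomposition(
        coefficients=coeffs,
        center_freqs=freqs,
        sampling_rate=trace.sampling_rate,
        fb=fb,
        fc=fc,
        pad_removed=True,
        t0=trace.t0,
    )
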