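"""Synthetic field-potential and synaptic-current generators.

No recordings are deposited with the study this pipeline reimplements, so
the package ships generators that emulate the statistical structure the
analysis targets:

* ``generate_lfp_with_sles`` - alternating inter-SLE / SLE regimes.
  Inter-SLE gaps are exponential; the onset (r_o), mid (r_s) and
  termination (r_e) sub-state durations are gamma distributed.  Inside
  coupled segments a band-limited Gaussian-noise carrier (30-250 Hz) is
  amplitude-modulated by the phase of a low-frequency oscillation:
  transitions couple to a 4-Hz rhythm whose depth ramps in (r_o) and out
  (r_e); the mid state couples to a slower 1-3 Hz rhythm at constant depth.
  The defaults reproduce the study conditions: 0.61 SLEs/min recurrence and
  gamma shapes 1.8 / 1.6 / 1.7 with mean durations 29.6 / 25.2 / 25.9 s
  (low-Mg2+ model).

* ``generate_psc_train`` - spontaneous postsynaptic current trains with a
  controllable degree of phase locking: a baseline population with uniform
  phases and modest amplitude (16 pA) and a phase-coherent population whose
  event phases follow a von Mises distribution around a chosen slow rhythm,
  at larger amplitude (48 pA).  Events are biexponential kernels summed
  onto a noisy holding current.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .preprocess import Trace

__all__ = [
    "SynthConfig",
    "SyntheticRecording",
    "PSCSynthConfig",
    "generate_lfp_with_sles",
    "generate_psc_train",
]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic LFP generator.

    Defaults are the low-Mg2+ slice-model conditions: recurrence 0.61
    events/min, sub-state gamma shapes (1.8, 1.6, 1.7) and mean durations
    (29.6, 25.2, 25.9) s.
    """

    sampling_rate: float = 1000.0          # Hz
    total_duration: float = 600.0          # s
    sle_rate: float = 0.61                 # events per minute
    substate_shape_params: tuple = (1.8, 1.6, 1.7)      # gamma shapes r_o, r_s, r_e
    substate_mean_durations: tuple = (29.6, 25.2, 25.9)  # s
    lfo_freqs: tuple = (4.0, 2.5)          # Hz: (transition LFO, mid-state LFO)
    hfo_band: tuple = (30.0, 250.0)        # Hz
    coupling_depth: tuple = (0.9, 0.9)     # (transition, mid), each in [0, 1]
    transition_shared_frac: float = 0.45   # mid-LFO coupling carried into transition bursts
    mid_fluct: float = 0.15                # waxing-waning of mid-state coupling
    mid_edge_exponent: float = 2.0         # U**k law of mid-rhythm birth/death points
    lfo_amp: float = 0.4                   # mV
    hfo_amp: float = 0.1                   # mV (carrier SD)
    noise_sd: float = 0.05                 # mV
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.total_duration <= 0:
            raise ValueError("total_duration must be positive")
        if self.sle_rate < 0:
            raise ValueError("sle_rate must be non-negative")
        if any(s <= 0 for s in self.substate_shape_params):
            raise ValueError("gamma shapes must be positive")
        if any(d <= 0 for d in self.substate_mean_durations):
            raise ValueError("mean durations must be positive")
        if not all(0 <= d <= 1 for d in self.coupling_depth):
            raise ValueError("coupling_depth must lie in [0, 1]")


@dataclass
class SyntheticRecording:
    """Generated LFP with per-sample ground-truth sub-state labels."""

    lfp: Trace
    true_state: np.ndarray     # per-sample label in {inter, r_o, r_s, r_e}
    true_intervals: list       # (start_s, end_s, label) tuples
    metadata: SynthConfig

    def sle_intervals(self) -> list:
        """Ground-truth (start_s, end_s) of each full SLE (r_o..r_e)."""
        out = []
        cur = None
        for s0, s1, lab in self.true_intervals:
            if lab == "r_o":
                cur = s0
            elif lab == "r_e" and cur is not None:
                out.append((cur, s1))
                cur = None
        return out

    def intervals_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("start_s\tend_s\tlabel\n")
            for s0, s1, lab in self.true_intervals:
                fh.write(f"{s0:.6f}\t{s1:.6f}\t{lab}\n")


def _burst_mask(m: int, fs: float, rng, reverse: bool,
                gap_mean: float = 4.5, gap_cap: float = 7.0,
                burst_mean: float = 0.5, burst_floor: float = 1.2,
                burst_cap: float = 2.5) -> np.ndarray:
    """On/off mask of discharge bursts filling a transition segment.

    Bursts of roughly one-to-three seconds separated by capped-exponential
    gaps, so the state posterior flickers throughout the segment: long
    enough to register in a 2-s coupling window, gaps short enough never
    to read as a committed inter-SLE stretch.  The edge adjoining the
    continuous mid state (trailing for onsets, leading when ``reverse``)
    is forced on so the burst train fuses with it.
    """
    on = np.zeros(m)
    pos = 0
    while pos < m:
        gap = min(rng.exponential(gap_mean), gap_cap)
        pos += max(int(gap * fs), 1)
        if pos >= m:
            break
        blen = min(burst_floor + rng.exponential(burst_mean), burst_cap)
        blen = max(int(blen * fs), 1)
        on[pos:min(pos + blen, m)] = 1.0
        pos += blen
    tail = max(int(0.05 * m), 1)
    on[-tail:] = 1.0
    return on[::-1] if reverse else on


def _bandlimited_noise(n: int, fs: float, band, rng) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to ``band`` Hz."""
    x = rng.standard_normal(n)
    lo, hi = band
    hi = min(hi, 0.499 * fs)
    sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    if n < 40:  # too short for zero-phase padding; broadband is fine here
        return x
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def generate_lfp_with_sles(config: SynthConfig | None = None,
                           **overrides) -> SyntheticRecording:
    """Generate a synthetic LFP trace with planted SLE sub-state structure.

    Returns a :class:`SyntheticRecording` whose ``true_state`` labels
    partition the trace and whose interval boundaries sit on the sample
    grid.  Bit-reproducible for a fixed config seed.
    """
    if config is None:
        config = SynthConfig(**overrides)
    elif overrides:
        config = SynthConfig(**{**asdict(config), **overrides})
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_total = int(round(config.total_duration * fs))

    mean_sle = float(sum(config.substate_mean_durations))
    if config.sle_rate > 0:
        cycle = 60.0 / config.sle_rate
        mean_gap = max(cycle - mean_sle, 0.05 * cycle)
    else:
        mean_gap = np.inf

    shapes = config.substate_shape_params
    means = config.substate_mean_durations
    scales = [mean / shp for shp, mean in zip(shapes, means)]

    # 1) lay out the label sequence on the sample grid
    segments = []  # (i0, i1, label)
    i = 0
    while i < n_total:
        if np.isinf(mean_gap):
            segments.append((i, n_total, "inter"))
            break
        gap = rng.exponential(mean_gap)
        i_gap = min(i + max(int(round(gap * fs)), 1), n_total)
        segments.append((i, i_gap, "inter"))
        i = i_gap
        if i >= n_total:
            break
        for lab, shp, scl in zip(("r_o", "r_s", "r_e"), shapes, scales):
            dur = rng.gamma(shp, scl)
            i_end = min(i + max(int(round(dur * fs)), 1), n_total)
            segments.append((i, i_end, lab))
            i = i_end
            if i >= n_total:
                break

    state = np.empty(n_total, dtype=object)
    for i0, i1, lab in segments:
        state[i0:i1] = lab

    # 2) synthesise the signal SLE-by-SLE: a mid-state LFO couples the fast
    # carrier throughout the event (at reduced, ramped depth during the
    # transitions), while a 4-Hz rhythm couples only the transitions, with
    # depth ramping in over r_o and out over r_e.  The classifier therefore
    # sees a continuum of coupling evidence across the transitions, the way
    # posterior fluctuations arise in recordings.
    x = rng.standard_normal(n_total) * config.noise_sd
    depth_tr, depth_mid = config.coupling_depth
    f_tr, f_mid = config.lfo_freqs
    sles, cur = [], []
    for seg in segments:
        if seg[2] == "inter":
            continue
        cur.append(seg)
        if seg[2] == "r_e":
            sles.append(cur)
            cur = []
    if cur:
        sles.append(cur)  # event truncated by the trace end
    for event in sles:
        e0 = event[0][0]
        e1 = event[-1][1]
        n = e1 - e0
        t = np.arange(n) / fs
        phi_mid = rng.uniform(0, 2 * np.pi)
        theta_mid = 2 * np.pi * f_mid * t + phi_mid
        # slow multiplicative waxing-waning of the mid-state coupling
        wax = np.ones(n)
        if config.mid_fluct > 0 and n > 1:
            knots = np.arange(0, n / fs + 4.0, 4.0)
            z = rng.standard_normal(knots.size)
            wax = np.clip(0.85 + config.mid_fluct * np.interp(t, knots, z),
                          0.6, 1.0)
        d4 = np.zeros(n)
        d_mid = np.full(n, depth_mid) * wax
        w4 = np.zeros(n)
        theta_tr = np.zeros(n)
        for i0, i1, lab in event:
            j0, j1 = i0 - e0, i1 - e0
            m = j1 - j0
            if m <= 1:
                continue
            edge_ramp = max(min(int(round(fs)), m - 1), 1)  # ~1-s establish/die
            idx = np.arange(m)
            if lab == "r_o":
                # onset: discrete 4-Hz-coupled bursts whose rate accelerates
                # into the SLE (gaps shrink from ~gap_max to ~gap_min), the
                # way interictal-like discharges condense into the seizure
                on = _burst_mask(m, fs, rng, reverse=False)
                d4[j0:j1] = depth_tr * on
                w4[j0:j1] = on
                # the mid rhythm establishes itself at a random point late
                # in the onset transition (U**k law toward the r_s boundary)
                birth = int((1.0 - rng.uniform() ** config.mid_edge_exponent)
                            * (m - 1))
                fade = np.clip((idx - birth) / edge_ramp, 0.0, 1.0)
                shared = config.transition_shared_frac * on
                d_mid[j0:j1] *= np.maximum(fade, shared)
                phi_tr = rng.uniform(0, 2 * np.pi)
                theta_tr[j0:j1] = 2 * np.pi * f_tr * np.arange(m) / fs + phi_tr
            elif lab == "r_e":
                # termination: 4-Hz-coupled afterdischarge bursts that thin
                # out toward the end of the event
                on = _burst_mask(m, fs, rng, reverse=True)
                d4[j0:j1] = depth_tr * on
                w4[j0:j1] = on
                # the mid rhythm dies at a random point early in the
                # termination, followed by sparse re-ignition bursts over a
                # tail of random extent; without the 4-Hz features nothing
                # else structures the termination
                death = int(rng.uniform() ** config.mid_edge_exponent
                            * (m - 1))
                fade = np.clip(1.0 - (idx - death) / edge_ramp, 0.0, 1.0)
                bursts = np.zeros(m)
                tail_end = death + int(np.sqrt(rng.uniform()) * (m - death))
                pos = death
                while pos < tail_end:
                    pos += int(rng.exponential(2.5) * fs)  # quiet stretch
                    blen = int((1.5 + rng.exponential(0.8)) * fs)
                    if pos >= tail_end:
                        break
                    bursts[pos:min(pos + blen, tail_end)] = 0.55
                    pos += blen
                # no shared slow coupling here: once the mid rhythm has died
                # the afterdischarges couple to the 4-Hz rhythm alone
                d_mid[j0:j1] *= np.maximum(fade, bursts)
                phi_tr = rng.uniform(0, 2 * np.pi)
                theta_tr[j0:j1] = 2 * np.pi * f_tr * np.arange(m) / fs + phi_tr
        w_mid = d_mid / max(depth_mid, 1e-12)
        lfo = config.lfo_amp * (w_mid * np.cos(theta_mid) +
                                0.5 * w4 * np.cos(theta_tr))
        carrier = _bandlimited_noise(n, fs, config.hfo_band, rng) * config.hfo_amp
        envelope = np.clip(1.0 + d_mid * np.cos(theta_mid) +
                           d4 * np.cos(theta_tr), 0.0, None)
        x[e0:e1] += lfo + envelope * carrier

    intervals = [(i0 / fs, i1 / fs, lab) for i0, i1, lab in segments]
    return SyntheticRecording(
        lfp=Trace(x, fs, units="mV"),
        true_state=state,
        true_intervals=intervals,
        metadata=config,
    )


@dataclass
class PSCSynthConfig:
    """Conditions for synthetic postsynaptic-current trains.

    Amplitude classes follow the study: baseline events average 16 pA,
    phase-coherent events 48 pA.  ``von_mises_kappa = 0`` makes the
    "locked" population phase-uniform.
    """

    polarity: str = "EPSC"            # EPSC (held -70 mV) or IPSC (held 0 mV)
    mean_event_rate: float = 4.0      # Hz, phase-coherent population
    baseline_rate: float = 8.0        # Hz, uniform-phase population
    lock_freq: float = 4.0            # Hz of the slow rhythm locked to
    von_mises_kappa: float = 3.0      # concentration, >= 0
    preferred_phase: float = 0.0      # radians
    kernel_rise_ms: float = 2.0
    kernel_decay_ms: float = 10.0
    baseline_amp: float = 16.0        # pA
    pcc_amp: float = 48.0             # pA
    amp_cv: float = 0.25              # lognormal amplitude spread
    noise_sd: float = 2.0             # pA
    seed: int = 0

    def validate(self) -> None:
        if self.mean_event_rate < 0 or self.baseline_rate < 0:
            raise ValueError("event rates must be non-negative")
        if self.von_mises_kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.polarity not in ("EPSC", "IPSC"):
            raise ValueError("polarity must be 'EPSC' or 'IPSC'")


def _biexp_kernel(fs: float, rise_ms: float, decay_ms: float) -> np.ndarray:
    t = np.arange(0, 8 * decay_ms / 1000.0, 1.0 / fs)
    k = np.exp(-t / (decay_ms / 1000.0)) - np.exp(-t / (rise_ms / 1000.0))
    peak = k.max()
    return k / peak if peak > 0 else k


def generate_psc_train(config: PSCSynthConfig, lfo_phase: np.ndarray,
                       sampling_rate: float):
    """Synthesise a PSC current trace locked to a given slow-rhythm phase.

    Parameters
    ----------
    config : PSCSynthConfig
    lfo_phase : ndarray
        Instantaneous phase (radians) of the slow rhythm on the output
        sample grid.
    sampling_rate : float
        Sample rate of ``lfo_phase`` and of the returned trace, Hz.

    Returns
    -------
    (Trace, pandas.DataFrame)
        Current trace (pA; EPSCs deflect negative, IPSCs positive) and the
        ground-truth event table with columns time_s, amplitude_pA, phase,
        population ('baseline'/'pcc').

    Notes
    -----
    Phase-coherent event times are generated by thinning a homogeneous
    Poisson stream against the von Mises density exp(kappa cos(phi - mu)),
    so the accepted phases follow the target distribution exactly.
    """
    import pandas as pd

    config.validate()
    lfo_phase = np.asarray(lfo_phase, dtype=float)
    fs = sampling_rate
    n = lfo_phase.size
    dur = n / fs
    rng = np.random.default_rng(config.seed)

    kappa = config.von_mises_kappa
    from scipy.special import i0 as bessel_i0
    # candidate rate such that the thinned stream keeps the target mean rate
    accept_mean = np.exp(-kappa) * bessel_i0(kappa)
    cand_rate = config.mean_event_rate / max(accept_mean, 1e-12)

    def _poisson_times(rate):
        if rate <= 0:
            return np.empty(0)
        n_ev = rng.poisson(rate * dur)
        return np.sort(rng.uniform(0, dur, n_ev))

    rows = []
    # phase-coherent population, thinned against the von Mises density
    for tcand in _poisson_times(cand_rate):
        idx = min(int(tcand * fs), n - 1)
        phi = lfo_phase[idx]
        accept = np.exp(kappa * (np.cos(phi - config.preferred_phase) - 1.0))
        if rng.uniform() < accept:
            rows.append((tcand, "pcc", phi))
    # baseline population, phase-uniform by construction
    for tcand in _poisson_times(config.baseline_rate):
        idx = min(int(tcand * fs), n - 1)
        rows.append((tcand, "baseline", lfo_phase[idx]))
    rows.sort(key=lambda r: r[0])

    sigma = np.sqrt(np.log(1 + config.amp_cv ** 2))
    kern = _biexp_kernel(fs, config.kernel_rise_ms, config.kernel_decay_ms)
    current = rng.standard_normal(n) * config.noise_sd
    sign = -1.0 if config.polarity == "EPSC" else 1.0

    times, amps, phases, pops = [], [], [], []
    for t_ev, pop, phi in rows:
        base = config.pcc_amp if pop == "pcc" else config.baseline_amp
        amp = base * rng.lognormal(-0.5 * sigma ** 2, sigma)
        i0_ = int(t_ev * fs)
        seg = kern[: n - i0_]
        current[i0_: i0_ + seg.size] += sign * amp * seg
        times.append(t_ev)
        amps.append(amp)
        phases.append(phi)
        pops.append(pop)

    events = pd.DataFrame({
        "time_s": times,
        "amplitude_pA": amps,
        "phase": phases,
        "population": pops,
    })
    trace = Trace(current, fs, units="pA")
    return trace, events
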