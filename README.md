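# cfchmm

Segmentation of seizure-like events (SLEs) and their sub-states in field
potential recordings, using phase–amplitude cross-frequency coupling (CFC)
features and a two-state hidden Markov model.

Epileptiform activity in cortical slice preparations (low-Mg²⁺ or 4-AP
perfusion) and in clinical intracranial EEG alternates between quiet
inter-event stretches and seizure-like events. The transitions into and out
of an event are not instantaneous: they are extended sub-states with their
own dynamics, and the phase of slow rhythms (1–12 Hz) — a 4-Hz rhythm in
particular — modulates the amplitude of fast activity (30–250 Hz) most
strongly while they last. This package turns that observation into an
objective segmentation pipeline, for electrophysiologists who want to
delimit onset/termination sub-states and characterise their statistics
without hand-marking traces.

## Method

1. **CFC features.** The LFP is decimated to 1 kHz, notch filtered, and
   decomposed with a complex Morlet wavelet
   `W(t; f_b, f_c) = (π f_b)^(-1/2) exp(2πi f_c t) exp(-t²/f_b)`
   (f_b = 3, f_c = 1). In 2-s sliding windows the instantaneous phase of
   each slow frequency is cut into 20° bins; the mean fast-band amplitude
   per bin, normalised to a distribution `A_norm`, gives the modulation
   index `MI = KL(A_norm ‖ uniform)/log N ∈ [0, 1]`. The (phase × amplitude
   frequency) grid is rebinned to a 4 × 4 band image (log-spaced amplitude
   bands), unwrapped to 16 features, and augmented with time derivatives —
   32 rows per window, each min–max normalised over the trace.
2. **State model.** A two-state HMM with mixture-of-Gaussians emissions
   (m ≤ 2 per state), initialised by k-means and refined by Baum–Welch EM.
   The scaled forward–backward recursions give the marginal posterior
   distribution (MPD) of the SLE state S2 per window,
   `MPD_t(i) = α_t(i)β_t(i)/Σ_i α_t(i)β_t(i)`.
3. **Sub-states and dynamics.** The 0→1 and 1→0 fluctuations of the S2
   posterior delimit the onset (r_o), mid (r_s) and termination (r_e)
   sub-states. Their duration histograms are summarised by maximum
   likelihood γ fits; the shape α classifies the dynamics (α < 1
   stochastic, α = 1 Poisson-like, α > 1 statistically deterministic).
4. **Evaluation and controls.** ROC analysis against a conventional
   power-threshold definition of the event (sensitivity = 1 −
   exp(−(1 − specificity)/ξ) summarises the sweep); envelope-reconstruction
   and spike-melting controls; 3–6 Hz feature ablation; phase-locking
   analysis (PLV, Rayleigh test, recursive threshold search) of synaptic
   currents against the slow field rhythm.

Because no recordings are deposited with the study this pipeline
reimplements, a synthetic-data module generates LFP recordings with planted
SLE/sub-state structure (and PSC trains with controllable phase locking) at
the study's conditions: 0.61 events/min, sub-state γ shapes 1.8/1.6/1.7.

## Worked example

```python
import numpy as np
from cfchmm import (SynthConfig, generate_lfp_with_sles, classify_trace,
                    substate_gamma_fits, roc_from_mpd)

rec = generate_lfp_with_sles(SynthConfig(
    total_duration=900, sle_rate=1.2,
    substate_mean_durations=(8.0, 12.0, 8.0), seed=3))
res = classify_trace(rec.lfp, seed=0)

print(res.hmm.summary())
print("events:", res.intervals.n_sles)
roc = roc_from_mpd(res.mpd, rec.sle_intervals())
print("AUC vs planted truth: %.3f" % roc.auc)
for name, fit in substate_gamma_fits(res.intervals).items():
    print(f"{name}: shape={fit.shape:.2f} CI=({fit.ci95[0]:.2f}, "
          f"{fit.ci95[1]:.2f}) -> {fit.label}")
```

Output (seeds as above):

```
Two-state Gaussian-mixture HMM
==================================
observations:      450
features:          32
mixture components 2
log likelihood:    18111.952
EM iterations:     51 (converged)

state labels: S1 = inter-SLE, S2 = SLE (higher mean coupling)
initial Pr:        S1=1.000 S2=0.000
transition matrix (S1,S2 order):
    0.9242  0.0758
    0.1080  0.8920
state mean emission level: S1=0.3167  S2=0.4004
events: 15
AUC vs planted truth: 0.927
r_o: shape=92.64 CI=(26.46, 158.82) -> deterministic
r_s: shape=3.49 CI=(1.10, 5.87) -> deterministic
r_e: shape=22.96 CI=(6.65, 39.27) -> deterministic
```

The summary reports the fitted state model (S2 is the coupling-rich SLE
state); the AUC scores the posterior against the planted event intervals;
the γ shapes above 1 say the classified sub-state durations are on the
statistically deterministic side, as planted. (At this scaled-down event
duration the classified transition durations sit near the extraction's
time resolution, which inflates their shape estimates; see
`docs/methods.md`.)

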