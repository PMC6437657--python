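# Methods

## The model

The pipeline treats an extracellular field-potential recording as an
alternation between two regimes — an inter-event state S1 and a
seizure-like-event (SLE) state S2 — observed only through windowed
phase–amplitude coupling features.

**Coupling features.** For phase frequencies 1–12 Hz (1-Hz steps) and
amplitude frequencies 30–250 Hz (5-Hz steps), a complex Morlet wavelet
(bandwidth f_b = 3, centre frequency f_c = 1, dilated across scales; 5-s
reflect-padded flanks, removed after the transform) yields instantaneous
phase and amplitude. In each 2-s window the phase axis is cut into
eighteen 20° bins; the mean amplitude per bin, normalised to a
distribution, is compared with the uniform distribution by
Kullback–Leibler distance and scaled by 1/log 18, so the modulation index
is 0 for phase-independent amplitude and 1 when all amplitude mass falls
in one bin. log N is the unique normaliser that puts the delta
distribution exactly at 1. Empty phase bins (possible at 1 Hz in a 2-s
window) receive machine-epsilon mass before the KL distance, which keeps
the index finite without measurably biasing occupied bins.

The 12 × 45 index grid per window is averaged into 4 phase bands
(linear split at 1, 3.75, 6.5, 9.25, 12 Hz) × 4 amplitude bands
(log-even split at 30, 51, 87, 147, 250 Hz), unwrapped row-major over
(amplitude band, phase band) into 16 features, and augmented with time
derivatives. Derivatives are central differences over a fixed 2-s time
gap regardless of the window stride: training features use
non-overlapping windows, testing features 95% overlap, and a fixed
differencing gap is what keeps the derivative features identically
distributed across the two grids. Each row is min–max normalised; one
recording gets one set of bounds (the union over its training and testing
grids), and a model transferred to a different recording maps that
recording's features with the training bounds, because the emission
densities live in the training feature space.

**State model.** Emissions per state are mixtures of m ∈ {1, 2} full-
covariance Gaussians over the 32 features. Initialisation clusters the
training windows into 2m k-means clusters, ranks them by mean coupling
level, and assigns the lower half to S1 — windows of intermediate
coupling (the transitions) then seed the boundary between states instead
of forming a spurious S1 mode. Baum–Welch EM refines {s, A, B} until the
log-likelihood gain drops below 1e-5 or 100 iterations. Covariances carry
a ridge (1e-6 × mean variance) plus a relative eigenvalue floor at 0.5 ×
the mean variance: the band features are strongly correlated, and without
the floor the near-null covariance directions make the Mahalanobis
distance — and hence the state posterior — hypersensitive to the small
distribution shifts that come with testing on a different recording.

Posteriors use per-window-scaled forward–backward recursions (stable for
arbitrarily long sequences; a log-space implementation exists as a
numerical cross-check). When the posterior is evaluated on windows
overlapping by a fraction v, each step carries only (1 − v) of a window
of new data, so the log emission term is tempered by (1 − v) and the
transition matrix raised to the (1 − v) fractional matrix power.
Without this correction the 95%-overlap testing grid counts every sample
twenty times as independent evidence and the posterior saturates.

**Sub-states.** The classified S2 support of each event is split into an
onset transition r_o, mid state r_s and termination transition r_e by the
posterior's 0→1 and 1→0 fluctuations. The raw rule (module defaults)
finds threshold crossings at 0.05/0.95 with linear interpolation between
window times, so a step posterior yields one-window transitions and a
ramp's interior becomes the transition. The trace pipeline uses the
fluctuation-region form of the same rule: the posterior is averaged over
4 s (its local S2 occupancy), thresholds 0.1/0.85 are applied to the
occupancy — an occupancy scale, where sustained values above ~0.85
already mean a committed state — and excursions shorter than a 2-s dwell
are treated as fluctuation, i.e. transition material. Events truncated by
the recording edges are dropped: censored durations bias the γ fits.

**Duration dynamics.** Sub-state durations pooled over events are fitted
by maximum-likelihood γ; the shape CI is the asymptotic normal interval
from the observed Fisher information, Var(α̂) = α/(n(α ψ₁(α) − 1)). The
dynamics label uses the CI: upper bound below 1 → stochastic, lower bound
above 1 → deterministic, otherwise Poisson-compatible.

**Evaluation.** A conventional power-based event definition (1-s-smoothed
squared signal ≥ 3 × the median power of a pre-event baseline window;
bursts separated by < 10 s of quiet merged) provides reference intervals.
Sweeping 101 thresholds over the S2 posterior gives per-window confusion
counts (reference-event windows → Tp/Fn, inter windows → Fp/Tn), the
trapezoidal AUC, and a one-parameter summary fit
sensitivity = 1 − exp(−(1 − specificity)/ξ), with the optimal operating
point the fitted-curve point nearest (0, 1). ξ is fitted by bounded
scalar minimisation over log ξ, with the corner anchors included so a
degenerate (perfect) sweep still pins ξ → 0.

**Controls.** (i) Envelope reconstruction: the lower envelope —
interpolated linearly or cubically through prominent troughs at least a
12-Hz half-period apart — plus white noise variance-matched to a 10-s
quiet window. This strips ≥ 10× of the 30–250 Hz power while keeping the
slow outline, so a classifier relying on genuine phase–amplitude coupling
collapses on it. (ii) Spike melting: rectified peaks above a threshold ×
rolling RMS (and an absolute amplitude floor) are shrunk toward the local
linear baseline by the cleaning fraction, with cosine ramps at the window
margins; the routine is idempotent and the identity on spike-free input.
It is a reimplementation from the printed parameter roles (window,
threshold, amplitude floor, smoothing width, cleaning fraction, margin),
not a port of the unpublished original. The mean absolute S2 difference
×100 quantifies the effect on classification. (iii) Band ablation:
omitted phase ranges are removed from the 1-Hz CFC grid before rebinning
(bands left empty are dropped), the model is re-trained and re-tested and
the γ fits recomputed; a whole-row ablation mode also exists.

**Synaptic currents.** PSC events are rectified peaks ≥ k × SD of a
pre-event baseline (k = 3 by default) separated by ≥ 50 ms — the
refractory cap means measurable event rates top out near 20 Hz. Charge
transfer per sub-state is the trapezoidal integral of the baseline-
subtracted rectified current in ten equal-duration (amortized-time) bins,
compared against the 10% pre-onset bin (Wilcoxon signed-rank, Bonferroni;
at least nine events are needed for any bin to survive the ten-fold
correction). Phase locking is the mean resultant length (PLV) of unit
phasors at event-time phases with the Rayleigh test for uniformity; the
recursive search raises the detection threshold over twenty log-spaced
multipliers (3–30 × SD) and returns the first threshold whose best
frequency reaches PLV > 0.3 with p < 0.05, or the maximum-PLV result
flagged non-significant. Surrogate testing of the coupling grid
block-shuffles the phase series (10-sample blocks), recomputes the grid
200 times and z-scores the real values; cells with z ≥ 3 are flagged.
The three-standard-error reading of this criterion would flag ~40% of
null cells and is not usable as a screen; z is therefore taken against
the surrogate standard deviation. Even so the scheme is mildly
anti-conservative on null data (~16% of cells at z ≥ 3 in white noise),
because shuffling alters the smoothness of the phase series; it is a
boundary-finding device for strongly coupled windows, not a calibrated
test.

## The synthetic data

No recordings are deposited with the study this package reimplements, so
all claims are exercised on generated data. The generator's defaults are
the study conditions: events recur at 0.61/min with exponential
inter-event gaps; sub-state durations are γ with shapes (1.8, 1.6, 1.7)
and means (29.6, 25.2, 25.9) s; PSC amplitude classes average 16 pA
(baseline) and 48 pA (phase-coherent). Scales the study does not print
were chosen once as realistic for slice LFP: slow-rhythm amplitude
0.4 mV, fast carrier 0.1 mV SD, background noise 0.05 mV.

Within an event, a mid-state rhythm (2.5 Hz; below the 3–6 Hz ablation
band) amplitude-modulates a band-limited 30–250 Hz noise carrier at depth
0.9, waxing and waning slowly (multiplier 0.6–1). Transitions are trains
of discharge bursts (1.2–2.5 s, capped-exponential gaps, mean ≈ 4.5 s)
coupled to a 4-Hz rhythm at depth 0.9 and to the mid rhythm at a 0.45
fraction; at the termination the mid rhythm dies at a random early point
(U² law) followed by sparse weak re-ignition blips, leaving the 4-Hz
afterdischarges to structure the rest. The carrier stays on throughout
the event, so power-based detection sees the whole event. This is a
descriptive stand-in, not a biophysical simulation: it reproduces the
statistical structure the analysis targets (alternating regimes,
γ-distributed sub-state durations, transition-specific 4-Hz coupling,
erratic terminations once the 3–6 Hz features are removed), and nothing
about channel or network mechanisms. Passing tests therefore show the
pipeline recovers planted structure of this kind; they cannot certify
behaviour on every waveform real tissue produces.

## Problem sizes and numerical choices

Tests run the pipeline at scaled-down conditions — sub-state means of
5–14 s in 600–1600-s traces — chosen so a full train/test cycle takes
tens of seconds. Two consequences are documented rather than hidden:
classified transition durations carry a resolution floor of roughly the
posterior-smoothing width (~3–4 s), which inflates γ shape estimates when
true durations approach it; and the ablation-direction check pools
durations over three generator seeds (as the study pools events over
slices) because a single scaled-down recording yields only ~20 events.
Degenerate inputs are handled explicitly: all-zero amplitude and
zero-variance baselines raise; empty phase bins are ε-smoothed; identical
feature windows fall back to ridge-regularised covariances with a
warning; fractional matrix powers of the transition matrix are
re-projected onto the stochastic simplex.

## Known limitations

* The two-state model cannot represent more than one coupled regime per
  state beyond what the emission mixture absorbs; >2 states are out of
  scope.
* γ fits assume uncensored, pooled durations; survival-style censoring
  corrections are not implemented (edge events are dropped instead).
* The surrogate significance scheme is anti-conservative under the null
  (see above).
* The specificity-factor curve is one fixed exponential family; raw ROC
  points are always persisted so any other summary can be fitted later.
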