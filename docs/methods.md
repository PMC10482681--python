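# Methods

This note documents the models, conventions and numerical choices behind
`coldstate`, and what the synthetic-data generators do and do not emulate.

## Behavioural-state HMM

**Model.** A categorical hidden Markov model with K = 3 hidden states over a
V = 15 action vocabulary, observed at 1-s bins. The vocabulary order is
fixed (sitting, shivering, head grooming, turning, lower body grooming,
moving out, eating, moving back, pushing bedding, standing up, bedding
retrieval, drinking, digging, grooming tail, walking) so that integer codes
are stable across runs. One label per bin: files with overlapping
annotations are rejected rather than resolved, because the annotation scheme
assigns a single behaviour per second.

**Initialisation.** The initial distribution and transition matrix start
uniform (no a-priori transition information). The emission matrix starts
from an informative template — state 1 concentrated on sitting/shivering,
state 2 on feeding-related actions, state 3 on locomotor/grooming actions,
with a 0.01 floor elsewhere — optionally perturbed by multiplicative
log-normal jitter (seeded) to break symmetry between restarts. Recovery on
synthetic data is robust to the template: an uninformative template plus
jitter converges to the same solution up to state permutation, which the
semantic labelling resolves.

**Fitting.** Multi-sequence Baum–Welch EM with Rabiner per-step scaling of
the forward/backward recursions (numerically equivalent to log-space
recursion; a 10,800-step sequence underflows in unscaled linear space).
Expected counts are pooled across sequences — one shared model for all
animals, each sequence restarting from pi — and pi is re-estimated as the
average of the first-step posteriors. Convergence: relative log-likelihood
change below `tol` (default 1e-6), `max_iter` 500. After each M-step,
emission entries below 1e-8 are floored and rows renormalised so behaviours
unseen in a state cannot freeze at exactly zero. Per-animal fitting is
available by passing a single-sequence list.

**Decoding and labelling.** Viterbi in log space; every tie (transitions and
final state) breaks toward the lowest state index, making the decoded path
deterministic. Because EM state indices are arbitrary, fitted states are
mapped to semantic labels from their emission rows: highest eating
probability → state 2 (exploration with feeding); of the remaining two,
larger sitting+shivering mass → state 1 (energy conservation); remainder →
state 3. Ties break to the lower raw index.

**Verification.** The forward likelihood and Viterbi score are checked
against brute-force enumeration of all K^T paths on a grid of random models
(K ≤ 3, V ≤ 4, T ≤ 8), one EM iteration is checked against an
enumeration-based E/M step, and the forward pass is cross-checked against an
independent categorical-HMM library. At full session scale (3 animals ×
10,800 bins, well-separated emissions) the fitted transition matrix lands
within 0.05 max-abs error of the generating chain with ≥ 90% decoding
accuracy.

## State metrics

Transition events are stamped at the start of the first bin of the NEW
state, so photometry windows centre on state entry; the annotation itself
does not fix this convention, and it is configurable by shifting event times
by one bin. Transitions are counted on raw 1-s changes with no minimum-bout
smoothing (an optional filter exists but defaults off), since any smoothing
constant would be arbitrary.

RTPP side assignment compares x against a configured divider; samples
exactly on the divider count toward the non-stimulated side so the two side
fractions always sum to 100%. Dwell weighting uses forward time differences,
with the final sample carrying the session's median dwell. The open-field
centre zone is the concentric square holding the configured fraction
(default 0.4) of the arena AREA — side length L·√0.4 ≈ 0.632 L — because the
defining quantity is an area fraction, not a side fraction; the rule is
defined for square arenas only. In-zone distance sums segments whose both
endpoints lie in the zone.

## Fibre photometry

The baseline F is the least-squares prediction of the 470-nm channel from
the 410-nm reference over the whole recording: bleaching is a
recording-scale trend, and the reference is a motion/bleach control rather
than a local baseline. A mean-ratio fallback (`method="ratio"`) exists for
recordings whose reference has no variance. A sliding-percentile baseline is
deliberately not the default; the regression convention is flagged in the
API so sensitivity checks can switch it.

Peri-event extraction aligns to the nearest sample (no interpolation; the
1-s event resolution is far coarser than the sample period) and retains only
events whose full window fits inside the recording, logging the dropped
count. AUC is the trapezoidal integral over the window, reported in
dF/F·s; the peak is the signed maximum within the window, reported in
percent. Default windows: (−20, +10) s for feeding onsets, (−10, +10) s for
state transitions.

## Indirect calorimetry

Energy expenditure uses the abbreviated Weir equation with 3.941 kcal/l O2
and 1.106 kcal/l CO2 (config-overridable). Hour h covers [h, h+1) relative
to the start of the cold transition; only fully recorded hours are kept.
Hourly intake converts cumulative grams (step-interpolated at hour
boundaries) by the diet energy density, default 3.56 kcal/g; the
pellet-count dialect uses 20-mg pellets.

The coupling statistic is a **convention, not a reproduction**: the
correlation between hourly EE and intake is computed as Pearson r over all
(animal, hour) pairs inside a sliding window of ±1 h around each hour, with
windows holding fewer than 3 pairs or zero variance flagged undefined. The
onset is the earliest window centre with r ≥ threshold (default 0.5) such
that every later defined window also satisfies the threshold ("remaining
elevated"); raising the threshold can only delay the onset. The choice of
pooled pairs, window width and correlation type is validated only by
recovery of a programmed onset on synthetic data.

## Synthetic-data generators

All generators are pure functions of (config, seed); identical seeds give
bit-identical output.

* **Ethograms** — 3 animals × 10,800 s by default (three-hour sessions at
  1-s bins). The generating chain has 0.95 self-transitions (multi-second
  bouts) and emission rows concentrated on disjoint action groups
  (total-variation separation ≥ 0.5), i.e. the "well-separated" regime in
  which state recovery is expected to succeed.
* **Photometry** — both channels share an exponential bleach (τ = 3600 s)
  and a slow multiplicative sinusoidal motion artifact (default 2%,
  period 37 s); only the signal channel carries transients, modelled as
  double exponentials a·(e^(−t/τ_d) − e^(−t/τ_r)) with a = 0.05 dF/F,
  τ_r = 0.5 s, τ_d = 2 s at 20 Hz, plus white sensor noise. By default,
  state 1→2 events carry transients and 1→3 events do not, mirroring the
  contrast the peri-event analysis is meant to detect.
* **Calorimetry** — 24 animals, 2 h at baseline then 12 h of cold; VO2 steps
  up 1.8× over a linear 3-h ramp (the temperature transition), modulated by
  a slow Ornstein–Uhlenbeck fluctuation (15%, τ = 60 min) and 10%
  between-animal spread; VCO2 = 0.8·VO2. Pellets are Poisson at 4/h before
  the programmed coupling onset (5 h post cold onset) and thereafter at
  k·(EE − basal)⁺ with k = 60 pellets per kcal/h, chosen from the variance
  relation r² ≈ Var(kΔEE)/(Var(kΔEE)+E[λ]) so that post-onset pooled hourly
  correlation sits near 0.8. The detected onset typically lands at 6 h — one
  hour late — because the ±1-h window only fills with coupled hours after
  the onset has passed; the recovery tolerance is ±1 h.
* **RTPP** — chamber occupancy follows a two-state Markov chain whose
  stationary distribution equals the target preference, with ~10-s mean
  dwells and a clipped random walk inside each chamber. A single 30-min
  session has a sampling s.d. of several percentage points around the
  target; accuracy claims therefore average over seeds.

**What the generators do not emulate:** annotation errors and ambiguous
behaviours, non-stationary or context-dependent transition structure,
calcium-indicator nonlinearity and event-rate-dependent baselines,
respiratory-exchange-ratio dynamics, circadian structure, or thermal
physiology. Passing tests demonstrate that the analysis recovers known
structure under the stated statistical assumptions — not that those
assumptions hold in any particular experiment.

## Degenerate inputs and tie-breaks

Empty ethograms are invalid; impossible observation sequences yield −inf
likelihood (forward) or an error naming the first impossible step (Viterbi);
all-identical sequences are legal EM input and converge to point-mass
emissions. All argmax ties anywhere in the package break toward the lowest
index, and all stochastic-matrix rows are renormalised after every update,
keeping every reported quantity deterministic given the seed.

## Problem sizes

Default test and acceptance runs use 3 × 10,800-bin sessions for fitting,
10^5-step chains for stationarity checks, 15-min photometry recordings, and
8–24 simulated calorimetry animals over 14 h; these sizes match the study
design the generators emulate while keeping a full verification run in the
tens of seconds on one CPU.
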