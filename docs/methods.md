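# Methods

This note documents the models and numerical choices behind `gaitclass`,
what the synthetic-data generator does and does not emulate, and the
known limitations.

## Signal model and preprocessing

The input is one uniformly sampled acceleration channel (m/s², default
100 samples/s): the proximal-to-distal axis of a shank-mounted sensor,
the axis that carries the sharpest stride/step transients.  A 2–20 Hz
4th-order Butterworth band-pass removes the gravity component and
high-frequency noise while keeping stride-rate harmonics.  Causal
filtering (`scipy.signal.sosfilt`) is the default because the method is
designed for on-line, on-board use; zero-phase filtering
(`sosfiltfilt`) is available for offline analysis where group delay
matters (e.g. onset-timing studies).  Whether the original study
filtered causally or zero-phase is not documented; both are supported
and tested.

## Epoch segmentation

Detection thresholds the absolute value of the 100 ms trailing
trapezoidal integral of the filtered signal (units m/s).  The adaptive
constants are the published operating point: threshold first guess
0.35 m/s, then 0.75× the previous epoch's peak integral; refractory
first guess 600 ms, then 0.5× the previous epoch's duration, measured
from epoch onset.  Choices the published description leaves open were
made as follows:

* **Offset rule.**  The moving integral of a signed oscillation dips
  toward zero twice per cycle, so an epoch must not close at the first
  sub-threshold lull.  An epoch closes when the integral stays below
  `offset_frac` = 0.5 of the current threshold (hysteresis) for
  `offset_hold` = 200 ms, with the offset placed at the start of that
  quiet run; a `max_epoch` = 2.5 s cap bounds pathological cases.  The
  hold bridges inter-lobe lulls of any passband component while staying
  far below realistic inter-epoch gaps (≳ 300 ms).
* **Onset timing.**  A trailing integral reports activity up to a
  window late, and the threshold crossing adds the build-up time.  The
  detector therefore keeps a 250 ms lookback and, at epoch close,
  refines the onset to the first sample whose rectified amplitude
  reaches 35% of the epoch peak.  The 35% fraction sits above
  zero-phase pre-ringing (measured ≈ 27% of peak for impact-like
  bursts) so the refinement never reaches into filtfilt artifacts.
  With this rule detected onsets land within ±10 ms (zero-phase) /
  ±40 ms (causal) of ground truth on noise-free synthetic sessions.
* **Threshold floor** 0.05 m/s prevents collapse after a near-silent
  epoch; epochs shorter than `min_epoch` = 100 ms are discarded without
  adapting the state.
* The detector is a streaming state machine (`EpochDetector`):
  processing a record in chunks of any size yields identical epochs to
  a single call, which is asserted by test.

## Features

The 16 per-epoch features: (a) timing of the maximum, (b) maximum
value, (c) timing of the minimum, (d) minimum value, (e) |timing
difference| of max and min, (f) zero-crossing count (strict sign
changes; exact zeros inherit the preceding sign), (g) spacing of the
two most prominent local maxima (prominence-ranked via
`scipy.signal.find_peaks`, then time-ordered; epoch duration as the
sentinel when fewer than two exist, same for (h) valleys), extrema of
the central-difference derivative, extrema of the 100 ms moving
integral, and extrema of the instantaneous mean frequency in linear and
natural-log scale (floored at 0.1 Hz before the log).

The mean-frequency track is the power-weighted first spectral moment
over 2–20 Hz of a Hann-windowed short-time spectrum, 0.3 s window, 50%
hop; frames without band power carry the neighbouring value.  The
original estimator reference and log base are not reproducible from the
text, so windowing and log base are configuration, and the defaults are
labelled interpretations.

## Sammon mapping

Features are z-scored before distance computation (the 16 features have
heterogeneous units), then embedded in 2-D by minimizing the Sammon
stress with the classic diagonal-Newton update, magic factor 0.35 and
step-halving whenever a step would increase the stress, so the accepted
stress sequence is non-increasing by construction.  Initialization is
the first two principal components (deterministic); seeded random
initialization is available.  Input pairs at exactly zero distance are
excluded from the stress sum.  Iteration stops at relative stress
change < 1e-9 or 500 iterations; the returned stress equals a
brute-force recomputation from the returned coordinates to 1e-10.

## Surrogate network

Because the mapping is iterative with no out-of-sample extension, a
16-40-2 MLP (tanh hidden layer, linear output, z-scored inputs) is
trained to mimic it from a seeded random 15% subset of the mapped
points.  Training is full Levenberg–Marquardt on the 762-dimensional
weight vector (analytic Jacobian, λ adaptation ×5/÷5), stopping when
MSE / var(targets) < 0.1%.  The "0.1%" criterion is interpreted as
*normalized* MSE — a raw-unit threshold would be scale-dependent, and
coordinate scale is explicitly immaterial downstream.  At that error
the per-dimension Pearson correlation with the true coordinates exceeds
0.98, making the two published fidelity criteria mutually consistent;
both are asserted in the acceptance suite.  Downstream classifiers
consume surrogate predictions (not raw Sammon coordinates), matching
the deployment story in which the network is the only mapping available
on-line; this is switchable.

## MAP classifier

Class-conditionals are bivariate Gaussians with sample moments from the
training set (sample covariance, ddof = 1; ridge 1e-6·trace when
near-singular).  Posteriors are computed in log space and normalized
with logsumexp.  Priors start uniform and adapt from a 240-slot buffer
of the last predicted labels: each prediction evicts the globally
oldest entry (plain FIFO), and priors are the buffer class frequencies.
The published update-rule sentence admits a per-class reading
(refresh the oldest slot *of the predicted class*), but that reading
leaves the class counts — hence the priors — fixed forever,
contradicting the stated purpose of the rule; it is available behind
`buffer_mode="per_class"` for comparison, with global FIFO as the
default.  A prior floor ε = 1/480 (renormalized so floored classes hold
exactly ε) prevents the absorbing state in which a class whose prior
decays to zero can never be predicted again.  The buffer receives
predicted labels, not ground truth: deployment has no truth available.

## SVM

Linear soft-margin machines (no kernel — the surrogate network is the
nonlinear map), C = 5, solved in the dual by maximal-violating-pair
two-coordinate transfer: each iteration picks the pair that most
violates the KKT conditions and moves mass between the two coefficients
with the closed-form step clipped to the box, the update the
Mitchell–Demyanov–Malozemov method applies to its hull coefficients.
Restricting pair selection to within one label group, as a literal MDM
nearest-point implementation would, cannot leave the all-zero start
(within-class transfers conserve per-class mass), so cross-class pairs
are included; when the selected pair shares a label the step *is* the
within-group MDM transfer.  Iteration starts deterministically at
α = 0 and stops when the duality gap (hinge-loss primal minus dual
objective) reaches 1e-6, far below any decision-relevant scale in 2-D.
The bias is the mean over unbounded support vectors, falling back to
the midpoint of the KKT-feasible interval.  The solver is verified
against a generic QP solver on random instances (dual objectives within
1e-6, identical decision signs).  Multiclass is one-vs-one with
max-wins voting; vote ties go to the tied label with the largest summed
|decision value|, then to sorted label order.

## Evaluation

Confusion matrices are row-normalized (rows = actual class); NMI is
mutual information over the joint label distribution divided by the
geometric mean of the marginal entropies, natural logs, 0 by convention
when a marginal entropy vanishes.  This normalization, applied to the
published row-percentage tables with actual-class marginals
proportional to the per-activity totals (5448/3404/3300), reproduces
both published NMI values to ±0.002 — which is what pins the convention
down, since the original text does not name one.  The train/test split
helper is stratified 15/85 with a seed; the original split beyond the
surrogate's 15% is undocumented, so this default is an assumption.

## Synthetic data

No recordings were published, so the generator emulates the *structure*
of the data: trains of burst-like epochs (damped 4–12 Hz sinusoid
sums, impact-like 20 ms attack) of three classes at three speeds with
class-specific amplitude/frequency/duration templates, quiet gaps, and
additive white noise (default SD 0.05 m/s²).  Class and speed
composition defaults to the published dataset proportions.  Template
constants were calibrated once, at design time, so that every
class/speed peak 100 ms integral sits near 0.55 m/s: the published
constants (0.35 m/s first guess, 0.75× adaptation) leave little
headroom — a weak burst following a strong one is missed if class peak
integrals differ by more than ~25% — and the study's own recordings
were evidently detectable by this very segmenter.  A `separation`
scalar interpolates all class templates toward their common mean
(0 = identical classes); end-to-end accuracy is monotone in it.

For classifier and mapping tests, a second generator draws 16-D
Gaussian clusters (default centers 6–8.5 apart at unit covariance,
composition again dataset-proportional).

**What passing tests show, and what they do not.**  The synthetic
sessions establish that the implementation is correct and
self-consistent: segmentation recovers known epochs, features separate
classes that differ as the templates do, the surrogate reaches its
stopping criteria, both classifiers recover well-separated clusters at
≥95%.  They do not establish the published real-data accuracy levels
(≈84% MAP vs ≈76% SVM on held-out recordings): real gait epochs have
within-subject correlation, transition strides, far messier
class-conditional feature distributions, and a Bayes error the
synthetic clusters deliberately lack.  The published accuracies are
therefore not acceptance targets; the two NMI values recomputable from
the printed tables are.

## Problem sizes

The acceptance computation uses 2000 feature vectors (dataset
proportions), the surrogate's 15% training subset (300 points), 50
random SVM instances of n ≤ 50, and multi-seed segmentation sessions of
30–120 epochs — sizes at which every stochastic criterion is stable
across seeds while the full suite stays fast.

## Known limitations

* Single axis only; no gravity-component estimation, no 3-axis fusion.
* The segmenter assumes quiet gaps between epochs; continuous
  activities with no inter-stride lull below threshold merge until
  `max_epoch` splits them.
* Levenberg–Marquardt as implemented is batch-only and assumes the
  15% subset fits in memory (it does, at any realistic session size).
* The per-class prior-buffer mode is provided for completeness but
  freezes the priors (see above); quantitative claims about the
  adaptive priors refer to the FIFO default.
* The Sammon optimizer finds a local stress minimum; different seeds
  (random init) can give reflected/rotated embeddings.  All downstream
  results are invariant to rigid motions of the embedding.
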