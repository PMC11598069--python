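# Methods

## Problem and model

`accelsym` quantifies left/right asymmetry of repetition-based
rehabilitation exercises from paired smartphone-accelerometer recordings
(one phone per body side, nominally 100 Hz, 3 axes).  The analysis treats
each side's recording as a single series, cuts it into M consecutive
subwindows of N samples (one per repetition by default), and describes each
subwindow by

* time-domain features: mean and sample (n−1) standard deviation, and
* frequency-domain features: relative band power — the fraction of the
  subwindow's mean-removed DFT energy over bins 1..⌊N/2⌋ that falls inside
  a frequency band ⟨fc1, fc2⟩.

For a non-negative feature F evaluated on the left and right subwindow of
repetition q, the symmetry index is

    c_q(r) = (1/2) · |F_L − F_R| / (F_L + F_R) · 100     ∈ [0, 50] %

and the global criterion of one recording pair averages over the M
repetition pairs and a feature subset Ψ:

    C = (1/|Ψ|) Σ_{r∈Ψ} (1/M) Σ_{q=1}^{M} c_q(r).

C = 0 means perfect symmetry; larger C means a larger systematic
left/right discrepancy.  Per-cohort results are arranged in an
individuals × exercises table with row means, column means and column
sample standard deviations.

Separately, the 2M subwindows are classified as left vs right (SVM,
Gaussian naive Bayes, two-layer neural network) under leave-one-out
cross-validation: if a classifier separates the sides well above chance,
their feature distributions genuinely differ, corroborating a high C.

## Design choices

**Channel reduction.** The analysis consumes one series per side; the
default is the Euclidean magnitude √(ax²+ay²+az²), which is robust to how
the phone is oriented on the limb.  A single axis can be selected instead
(`channel: x|y|z`).  Magnitude is a nonlinear (rectifying) map, so spectral
content appears at harmonics of the motion frequency; band edges were
chosen wide enough that this does not move energy across the default
bands.

**Index absolute value and degenerate segments.** The index uses
|F_L − F_R|, making all values non-negative; a signed variant (sign of
F_L − F_R, range [−50, 50]) is available behind `signed=True` for
directionality analysis.  If both features are zero the segment is
degenerate (no motion on either side) and c is defined as 0 — a symmetric
absence of motion — and logged.  The ratio is computed as
`50·(diff/denom)` and clipped so the ±50 bound is exact in floating point.

**Criterion normalizer.** c_q is defined per left/right *pair*, so the
inner average is over the M pairs actually summed, not over the 2M
columns; normalizing by 2M would silently halve every C.

**Ψ presets.** `frequency` = band powers only; `mixed` = standard
deviation + band powers.  Both are exposed because either convention is
defensible for a study-level table; the mean feature is excluded from both
(after mean-removal-based band powers, the magnitude-channel mean mostly
reflects static posture, not motion).

**Segmentation and spectra.** Default M = 10, one subwindow per
repetition of a ten-repetition exercise block; N follows by floor division
and the trailing remainder is discarded.  The DFT is taken per column
after removing the column mean (DC bin exactly 0); frequency resolution is
fs/N.  Band-power denominators run over bins 1..⌊N/2⌋ (the Nyquist bin is
included for even N); band intervals are half-open [fc1, fc2) so adjacent
bands partition the spectrum, except that a band ending exactly at fs/2
keeps the Nyquist bin.  Default bands: [0.5, 3) Hz (repetition
fundamental and first harmonics) and [3, 10) Hz (fast components and
tremor-like content).

**Trimming and resampling.** 1.0 s is cut from each end of a recording by
default (handling artefacts); both amounts are configurable.  Recordings
whose timestamp jitter exceeds 1 % of the sample period are linearly
interpolated onto a uniform 1/fs grid, since the DFT assumes uniform
sampling.

**Classifiers.** The two-feature default pattern matrix is {power in the
first band, standard deviation}, z-scored per feature using training-fold
statistics only (the test column never influences the scaling).

* SVM: RBF kernel, C = 1, kernel width γ = 1/(R · feature variance)
  (scikit-learn's `gamma="scale"`).
* Bayes: Gaussian naive Bayes with equal class priors — per-class,
  per-feature Gaussian likelihoods.  "Bayesian classification" admits many
  models; this is the documented interpretation.
* Neural network: two layers, S1 = 10 sigmoid hidden units and a 2-unit
  softmax output, trained by full-batch gradient descent on mean
  cross-entropy (learning rate 0.1, max 2000 epochs, stopping tolerance
  1e−6, Glorot-style uniform initialization from the seed, zero biases).
  A backtracking step keeps the accepted-loss trace non-increasing; the
  analytic gradients are verified against central finite differences in
  the test suite.  Chosen over quasi-Newton training for bit-level
  reproducibility from a single seed.

Metrics use class L as positive: TPR = TP/(TP+FN), TNR = TN/(TN+FP),
AC = (TP+TN)/n.  The cross-validation error CV is defined as the held-out
misclassification fraction; since leave-one-out tests every segment
exactly once, CV = 1 − AC here.

## Synthetic data: what it emulates and what it does not

Each synthetic side is a periodic waveform — fundamental at the repetition
frequency plus one harmonic at twice the frequency and half the amplitude,
enveloped by sin²(π·f·t) so each repetition is a distinct smooth burst —
plus a 0.05 Hz baseline-drift sinusoid and i.i.d. Gaussian sensor noise
per sample and axis.  Defaults (chosen once as plausible for slow
repetition exercises on a phone accelerometer): fs = 100 Hz, 10
repetitions at 0.5 Hz (20 s records), base amplitude 1 m/s² with per-axis
weights (1.0, 0.6, 0.3) and fixed phase offsets, noise SD 0.05 m/s²,
drift amplitude 0.1 m/s².  Per-exercise nominal frequencies span
0.40–0.75 Hz.  Asymmetry is injected by scaling the right side's entire
deterministic component by (1 + δ_a) and its repetition frequency by
(1 + δ_f); with δ_f = 0 this makes RMS(R)/RMS(L) = 1 + δ_a exactly, and
with the mixed feature set and no noise the criterion has the closed form
C = (1/3)·50·δ_a/(2 + δ_a), both of which the tests exploit.  Cohort
generation derives one RNG stream per (individual, exercise) cell from the
master seed, so a cohort is reproducible sample-for-sample.

The generator does **not** model exercise-specific kinematics, fatigue or
within-block variability, sensor saturation, or gravity offsets
(recordings are zero-mean apart from drift).  Passing tests therefore
demonstrate that the pipeline recovers *injected* asymmetry under
controlled periodic-plus-noise conditions — not that the default bands or
windows are optimal for any particular real exercise.

One structural property is worth knowing: with the default *shared* drift,
the left and right subwindows of the same repetition are near-twins with
opposite labels.  On perfectly symmetric data (δ = 0) leave-one-out
classification is then systematically *below* chance — the held-out
segment's closest neighbour carries the opposite label (a known LOOCV
pathology with paired data).  The chance-level test band [0.35, 0.65],
derived from binomial quantiles, assumes independent chance-level
predictions and is therefore checked on drift-free pairs; the anti-learning
regime is real behaviour, not a bug, and disappears as soon as genuine
asymmetry dominates the shared component.

## Numerical and degenerate-input conventions

* Constant columns have zero spectral energy; their relative band power is
  defined as 0 with a warning.
* A recording-length mismatch beyond one segment truncates both sides to
  the shorter length with a warning; less than that is absorbed by the
  discarded remainder.
* LOOCV requires ≥ 4 segments; a fold whose training set degenerates to a
  single class predicts the training majority class with a warning.
* Stored results are never rounded; rendering rounds symmetry values and
  accuracies to one decimal and CV to two, matching the tables' printed
  precision.

## Problem sizes used in the checks

The verification suite and the acceptance script use synthetic problems
sized to exercise every code path at full fidelity: 16-individual ×
8-exercise cohorts (1280 repetition tests) for the design count,
20-repetition pairs (Q = 20 segments) for criterion and classifier
checks, 200-segment pairs for the chance-level band, and 20 seeds (10 in
the acceptance script) per Monte-Carlo average.  Inside the heavy LOOCV
sweeps the network trains with a reduced epoch cap (150–500); accuracy
there is insensitive to the cap because the two-feature problems converge
quickly.

## Known limitations

* The symmetry criterion conflates systematic asymmetry with noise-driven
  feature scatter: C grows with the noise level even at δ = 0 (the tests
  quantify this).  Comparisons across recordings are only meaningful at
  comparable noise levels and segment counts.
* Band edges, M and the trim amount are conventions, not estimates; no
  attempt is made to learn them from data.
* No clinical threshold on C is proposed: the package reports the
  criterion, not a diagnosis.
* The deposited-dataset directory adapter assumes a
  `<individual>_<exercise>_<side>.csv` naming scheme and must be checked
  against any real deposit before use; it is isolated in a single function
  for that reason.
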