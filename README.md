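# accelsym

Left/right motion-symmetry analysis of wearable-accelerometer recordings
from rehabilitation exercises.

Physiotherapists preparing patients for abdominal surgery (prehabilitation)
or guiding their recovery need an objective measure of whether a
repetition-based exercise — spinal motions, leg lifts, squats — is
performed symmetrically by the two sides of the body.  `accelsym` takes
paired recordings from a phone strapped to each side (3-axis acceleration
at ~100 Hz), segments them into per-repetition subwindows, extracts
time-domain (mean, standard deviation) and frequency-domain (relative DFT
band-power) features, and reports:

* a **symmetry index** per repetition and feature,

      c_q(r) = ½ · |F_L(r) − F_R(r)| / (F_L(r) + F_R(r)) · 100   ∈ [0, 50] %,

* a **global symmetry criterion** per recording pair,

      C = (1/|Ψ|) Σ_{r∈Ψ} (1/M) Σ_{q=1}^{M} c_q(r),

  with Ψ a chosen feature subset and M the number of repetition pairs
  (C = 0 ⇒ perfect symmetry), aggregated into an individuals × exercises
  table, and

* a **left-vs-right separability check**: SVM, Gaussian naive Bayes and a
  two-layer sigmoid/softmax neural network classify the 2M subwindows
  under leave-one-out cross-validation, reporting TPR, TNR, accuracy and
  the CV error — high accuracy corroborates high measured asymmetry.

A synthetic-data generator produces paired recordings with a controllable,
known asymmetry (amplitude and frequency shifts on one side) so the entire
pipeline is verifiable without any real recordings.  See
[docs/methods.md](docs/methods.md) for the model details and conventions.

## Worked example

```python
from accelsym import SyntheticConfig, generate_pair, loocv
from accelsym.pipeline import PipelineConfig, process_pair

# one simulated exercise block: 10 repetitions at 0.5 Hz, the right side
# 30 % stronger than the left, realistic sensor noise
cfg = SyntheticConfig(asym_amp=0.3, noise_sd=0.05, seed=1)
left, right = generate_pair(cfg)

pc = PipelineConfig(classifiers=(), psi="mixed")
features, result = process_pair(left, right, pc)
print(result.summary())

pair = features.select(["bandpower[0.5,3)", "std"])
for method in ("svm", "bayes", "nn"):
    print(loocv(method, pair, seed=1).summary())
```

prints

```
Symmetry criterion C = 6.110 %  (individual=-, exercise=-, 10 segment pairs)
Per-feature mean index:
  std                    6.512
  bandpower[0.5,3)       0.851
  bandpower[3,10)       10.967
svm: AC 70.0 %  CV 0.30  TPR 0.900  TNR 0.500  (TP=9 TN=5 FP=5 FN=1)
bayes: AC 65.0 %  CV 0.35  TPR 0.500  TNR 0.800  (TP=5 TN=8 FP=2 FN=5)
nn: AC 70.0 %  CV 0.30  TPR 0.700  TNR 0.700  (TP=7 TN=7 FP=3 FN=3)
```

C = 6.1 % says the sides differ systematically (a perfectly symmetric,
noise-free pair gives C = 0; one side at rest gives 50).  The standard
deviation index (6.5) picks up the injected 30 % amplitude difference,
while the first-band power (0.9) barely moves — band powers are scale
invariant, so they respond to *spectral* asymmetry, not amplitude.  All
three classifiers separate left from right segments above the 50 % chance
level, consistent with the nonzero criterion.

## Command line

```sh
accelsym simulate --out data/ --n-individuals 2 --asym-amp 0.0,0.3 --seed 7
accelsym run --manifest data/manifest.csv --out results/ --preset mixed --seed 7
accelsym report --results results/
accelsym symmetry --left data/S01_E1_L.csv --right data/S01_E1_R.csv --preset mixed
```

`run` writes `symmetry_table.csv/.json` (individuals × E1..E8 with mean
rows/columns) and `classification.csv/.json`; every JSON embeds the full
configuration and its hash, and a rerun with the same seed reproduces the
outputs byte for byte.  Recording files are plain delimited text
(`time_s,ax,ay,az`, comma or tab, gzip accepted) plus a cohort manifest
CSV (`individual_id,exercise_id,side,path`).

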