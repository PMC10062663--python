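# Methods

## Problem and model

Dynamic contrast CT of the brain records a Hounsfield-unit (HU) time curve
per voxel during the passage of an iodine bolus.  Indicator-dilution theory
models the baseline-subtracted tissue curve as

C(t) = CBF · (C_a ⊛ R)(t),

with C_a the arterial input concentration and R the residue function
(fraction of tracer still in the voxel at lag t).  Deconvolving C by C_a
yields the flow-scaled residue k(t) = CBF·R(t), from which the clinical
maps follow: CBF = max k, Tmax = argmax k, CBV = ∫C/∫C_a, MTT = CBV/CBF.
Hypoperfusion is Tmax > 6 s; the core is rCBF < 0.38 inside it, where rCBF
normalizes CBF by the mean over control tissue (Tmax < 6 s).  All CBF/CBV
values are relative (no density/hematocrit calibration): only the rCBF
ratio enters any decision, so absolute calibration is irrelevant.

A finite acquisition records only the first N·dt seconds of C(t).  If the
scan ends before wash-out, the convolution tail is lost and the recovered
k — hence Tmax and the lesion volumes — degrades.  That *truncation
artifact* is the object of study: the package labels which truncated
durations still give reliable volumes and trains classifiers to predict
that label from vascular-curve features alone.

## Deconvolution

The AIF concentration curve is embedded in a circulant matrix
D[i,j] = dt·a[(i−j) mod L] with L = 2N (zero padding prevents wrap-around),
making the estimate invariant to the arterial-to-tissue arrival delay up to
the padded horizon.  The system is inverted by truncated SVD: singular
values below `lambda_rel`·σ_max are discarded.

* `lambda_rel` (default **0.15**) controls the bias/variance trade-off.
  Hard-threshold truncation is biased: at 0.15 the noise-free worst-case
  CBF underestimation over CBF ∈ [0.2, 1] × delay ∈ [0, 10] s ×
  MTT ∈ [2, 12] s is ≈ 45 % and the residue peak shifts ~2 s late.  With
  noisy voxel curves this is the setting that maximizes lesion-segmentation
  Dice on the phantom (≈ 0.85–0.97); oracle tests on noise-free curves use
  `lambda_rel = 1e-3`, where recovery is exact to < 1 %, because the
  regularization strength should match the noise level of the input.
* Baseline estimation: bolus arrival is the first sample exceeding the
  expanding pre-window mean + 3 sd; the baseline is the pre-arrival mean.
  If no arrival is detected (flat curve, or a scan with no pre-contrast
  acquisition that rises from its first sample) the first sample is the
  baseline.  For map computation, tissue baselines use the window detected
  on the AIF — tissue contrast cannot arrive before the arterial bolus —
  which is both faster and more robust than per-voxel detection at low SNR.
* Tie-breaks and degenerate voxels: argmax k takes the first index
  attaining the maximum; non-finite or flat curves get CBF = CBV = 0,
  Tmax = 0 and missing MTT; CBF is clipped at 0.

## Synthetic cohort

The generator emulates the acquisition characteristics of public
multi-center stroke CTP data resampled to 1 volume/s:

| parameter | default | rationale |
| --- | --- | --- |
| scan duration | trunc-normal N(46.6, 5.3) s on [31, 64] s | published acquisition statistics |
| bolus arrival | trunc-normal N(11.1, 4.5) s, min 0.5 s | arterial peak = arrival + α·β ⇒ 15.6 ± 4.5 s, min ≥ 5 s |
| AIF | gamma-variate, α = 3, β = 1.5 s, peak 200 HU | typical first-pass width; amplitude directly in HU (peak-normalized parameterization) |
| VOF | AIF delayed 6 s, exponentially dispersed 2 s, peak 300 HU | venous curves lag and exceed arterial ones; delay/dispersion are judgment calls (no published venous peak statistics) |
| grid | 64×64×4 voxels at 0.125 ml | desk-scale runtime; volumetry depends only on voxel counts |
| healthy tissue | CBF_rel 0.012 /s, MTT 4 s, no delay | CBV ≈ 5 %, tissue peak ≈ 8 HU above baseline |
| lesion | ellipsoid, 5 % of brain voxels; CBF_rel 0.004 /s, MTT 10 s, delay 8 ± 1 s, dispersion 3 s | Tmax truth > 6 s, rCBF truth 0.33 < 0.38 |
| per-voxel jitter | ±15 % flow, ±1 s lesion delay | mild heterogeneity without breaking shared-curve vectorization |
| noise | i.i.d. Gaussian, sd **1 HU** | *effective* residual noise of preprocessed clinical data.  The pipeline segments on single voxels and models no spatial smoothing (a deliberate non-goal), so the noise level stands in for noise-after-smoothing; at 2 HU nearly every phantom scan fails the 2.5 ml stability rule, which clinical data do not. |
| baseline | 40 HU | brain parenchyma |

The forward tissue model truncates the convolution tail at the scan end —
deliberately and silently, because that tail loss *is* the artifact under
study.  Delays are rounded to the 1 s sample grid.  All randomness flows
from one seed through `numpy` `SeedSequence` spawning; identical configs
reproduce cohorts bitwise.

What the phantom does **not** emulate: anatomy, motion, beam hardening,
partial-volume vascular signals, multi-lesion or graded-severity perfusion
patterns, scanner-dependent noise spectra.  Passing tests therefore
demonstrate the correctness and internal consistency of the procedure, not
clinical performance.

## Labeling protocol

Truncated versions are produced by dropping 1 s from the end until 10 s
remain; each version is re-analyzed independently (deconvolution, control
tissue, normalization and volumetry are all recomputed; the vascular sites
never move).  Rules, with literal boundary semantics:

* **stability**: a scan is stable iff truncating each of the final 6 frames
  changes *both* the hypoperfused and core volume by ≤ 2.5 ml (exactly
  2.5 ml is stable).  Unstable scans are excluded.  Checking both lesion
  types (rather than one) is configurable.
* **reliability**: duration d is raw-reliable iff, for each lesion type,
  |V(d) − V(T)| < 5 ml OR (V(T) > 0 and the relative deviation < 10 %) —
  OR semantics, both lesion types must pass; when V(T) = 0 only the
  absolute criterion applies.  Final labels propagate downward: every
  duration at or below a raw-unreliable duration is unreliable, making the
  reliable set an up-set.  OSD = shortest reliable duration.
* **exclusions**: unstable scans; stable scans with hypoperfused volume
  0 ml (no lesion) or < 5 ml (too small to trust relative deviations); a
  sweep failure within the final 6 frames (stability unassessable).

## Features and augmentation

Features are computed on raw HU vascular curves (no baseline subtraction).
Sample i occupies time (i+1)·dt, so an N-sample 1 Hz scan has duration N s
and its last sample sits exactly at the scan duration; peak times use the
first-occurrence tie-break.  The coverage identity
coverage = duration − argmax holds exactly by construction and is asserted
after every transformation.

Augmentation emulates protocol variability: one shift δ ~ U(−5, +10) s is
added jointly to scan duration and both peak times (coverages unchanged —
a different pre-contrast duration does not change whether the scan is
truncated), and one gain s ~ U(0.7, 1.3) multiplies the four UCI/DCI
amplitudes (deconvolution is amplitude-independent).  Two copies per
training record; the uniform bounds are package defaults (no published
values exist).  Augmentation touches training folds only.

## Classifiers and evaluation

* Baseline g: reliable iff scan duration ≥ θ (boundary inclusive).
  Reported both at its own operating point and on the fixed grid
  θ ∈ {27, 30, 40, 50, 60} s.
* Single-feature g′: same rule on any feature, with the orientation
  (higher ⇒ reliable, or the reverse) chosen by training ROC-AUC.
* ML families and search spaces: random forest (50–300 trees, depth 2–8,
  leaf 1–20), logistic regression (C 1e-2–1e3, log), linear SVM (C), RBF
  SVM (C, γ 1e-4–1), AdaBoost (50–300, lr 0.01–1), gradient boosting
  (50–300, lr 0.01–0.3, depth 2–6).  Hyperparameters are tuned by a
  sequential model-based optimizer (random initial design, Matern-5/2 GP
  surrogate, expected improvement; default budget 16 evaluations) that
  maximizes mean PR-AUC over an inner scan-grouped 3-fold CV; augmented
  rows take part in the inner search (grouped with their source scan).
  SVM/LR are standardized on the training fold; tree models are not.
* Outer evaluation: scan-grouped 5-fold CV (~80/20), identical splits for
  all models.  The operating point θ* = argmin{(precision−1)² +
  (recall−1)²} (ties → higher recall) is selected on the (augmented)
  training fold only.  Unreliable is the positive class.  Metrics are
  reported per fold and pooled over concatenated test predictions; PR-AUC
  uses the step-wise (average-precision) estimator, ROC-AUC the trapezoid.
* Feature importance: gradient boosting refitted on 100 (50 in the
  acceptance script) bootstrap resamples of the *scans*; impurity-based
  importances, normalized per fit, reported as mean ± sd.
* Error-vs-OSD-gap: per-record gap = duration − OSD, 1 s bins, error rate
  computed over records with |gap| > 2.30 s (the published inter-rater OSD
  variability band, used here as a fixed window).

On the default phantom the impurity importance concentrates on VOF_DCI
rather than AIF_coverage: the simulated venous curve is a deterministic
transform of the arterial one, so the downward venous contrast increase
encodes truncation with less per-scan variability than in clinical data,
and collinear features let the tree ensemble pick one representative.  The
classifier *ordering* (duration baseline < AIF-coverage rule ≈ gradient
boosting) matches expectation and is asserted in the acceptance tests.

## Problem sizes and determinism

Default study size: 30 scans on the 64×64×4 grid (~13 k brain voxels,
~37 truncated versions each, ~1 000 labelled records), chosen as the
smallest cohort on which the classifier comparison is stable; the full
pipeline runs in a few minutes on one CPU.  The 256×256 matrix is
supported via `SimConfig.tissue_grid`.  Every stage is deterministic given
the configured seed; reruns produce byte-identical CSV/JSON artifacts.

## Known limitations

* Truncated SVD with a fixed relative threshold is the only regularization
  offered; oscillation-index and Tikhonov variants are not implemented.
* Numerical agreement with any proprietary clinical package is neither
  expected nor testable; thresholds (6 s, 0.38, 2.5 ml, 5 ml/10 %) are
  configurable but default to the published clinical values.
* The phantom's lesion is homogeneous apart from mild jitter; core and
  hypoperfusion truth coincide spatially, so core-specific reliability
  failures are less diverse than in patients.
* Automatic AIF/VOF detection is out of scope; the simulator's ground-truth
  sites stand in for expert annotations.
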