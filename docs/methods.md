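# Methods

This document records the models, estimators, numerical choices and
limitations of `ppgaug`. Notation: frames are row vectors `x ∈ R^D`
(default `D = 500`, i.e. 5 s at 100 Hz), class labels `c ∈ {1, …, C}`,
latents `z ∈ R^50`.

## 1. Data model

A recording is one patient session of single-channel PPG with a sampling
rate and a 1-based severity class. Sessions are cut into frames of
`L = round(fs · t)` samples (default `t = 5 s`) with 50 % overlap;
trailing partial windows are discarded. Classifiers never see raw frames:
each frame is split into non-overlapping 1-second sub-segments whose
untapered periodograms are averaged (Welch, boxcar window, no overlap);
the DC bin is dropped, leaving `fs // 2` log-power bins at 1 Hz resolution
(50 bins at 100 Hz). Cross-validation is always grouped by patient —
frames from one patient never appear in both splits of a fold.

## 2. Synthetic cohort generator

No clinical data ships with the package; `ppgaug.simulate` produces
class-conditional cohorts. A patient draws a personal heart rate from
`N(hr_mean, hr_sd²)` (clipped to `[0.5, 1.5] · hr_mean`). The waveform is
a pulse train of two-bump beat templates — a systolic Gaussian bump plus a
delayed, scaled dicrotic bump — with 2 % between-beat onset jitter (a
pathological line spectrum would otherwise make the classification task
trivial), amplitude-modulated by `1 + resp_depth · sin(2π resp_rate t)`
(emulating respiratory sinus arrhythmia) and corrupted by white noise.
Classes differ in mean heart rate and respiratory depth, which separates
them in log-power-spectrum space. Assumptions: stationary heart rate per
session, sinusoidal respiration, additive Gaussian noise; none of these is
physiologically exact, but the generator's only job is to give the GAN and
the evaluation stack a realistic low-data classification problem.

## 3. Conditional GAN variants

All three variants share one architecture (NumPy implementation, explicit
backpropagation — verified against central finite differences in the test
suite):

* generator: fully connected tanh layers `(50 + C) → 100 → 200 → 400 → 500`,
  followed by a trainable length-preserving 1-D convolution (15 taps,
  boxcar-initialised: a genuine low-pass filter that removes stair-step
  artefacts from the dense output);
* discriminator: `p` packed frames (consecutive same-class frames
  concatenated along time, default packing `p = 3`, exposing within-batch
  mode collapse) through tanh layers `500p → 400 → 200 → 100 → 50`, then
  two heads: a scalar realness score and class logits.

At the defaults (`C = 3`, `p = 3`) the generator has 306,516 and the
discriminator 705,954 parameters (frozen in tests).

**`cgan_ds`** conditions the generator on a one-hot class code appended to
a standard-Gaussian latent. The generator loss is

```
L_G = −E[log σ(D(x̂))] − E[log softmax(logits)_c] + λ_div · L_DS
```

with the class-specific diversity-sensitivity reward

```
L_DS = −E_c E_{z1,z2} [ ‖G(z2|c) − G(z1|c)‖₂ / ‖z2 − z1‖₂ ]
```

(per-class means first, then the mean over classes; coincident latent
pairs are skipped with a warning; a collapsed generator that ignores its
latent earns the *null reward* 0, so `L_DS ≤ 0` always). Default
`λ_div = 1e-6`. The discriminator loss combines a Wasserstein term on the
raw realness scores, a **zero-centred** gradient penalty
`gp_weight · E[‖∇_x̄ D(x̄)‖²]` at uniform interpolates
`x̄ = αx + (1−α)x̂`, `α ~ U(0,1)` (default `gp_weight = 10`), and the
auxiliary class cross-entropy on real data. The penalty's parameter
gradient is computed by analytic double backprop through the
input-gradient recursion.

**`deligan_ds`** replaces the latent prior with a learnable Gaussian
mixture, one component per class: `z ~ N(μ_c, σ² I)` with `μ_c` trained
jointly (initialised uniformly on `[−1, 1]`) and isotropic `σ = 0.3`
fixed. Everything else matches `cgan_ds`.

**`madgan`** trains one generator per class and a single discriminator
whose class head is `(C+1)`-way: it identifies the *source* of a packed
sample (0 = real, `1…C` = generators). The discriminator minimises the
`(C+1)`-way cross-entropy; each generator minimises
`−E[log p(source = real)]` on its own samples.

Optimisation: Adam (`β₁ = 0.5`, `β₂ = 0.999`), learning rate `2e-4` for
both networks, batch size 64, 200 epochs by default. By default only a
class-stratified 20 % of the frames (then class-balanced by subsampling)
forms the GAN training pool, reflecting the low-data regime the method
targets; `train_frac = 1.0` disables this.

## 4. Kernel two-sample evaluation

The kernel is the exponentiated quadratic `K(x, y) = exp(−‖x − y‖²)`
(`K(x,x) = 1`). Frames are standardised per frame (zero mean, unit
variance) and then scaled by `1/√(2D)` before kernel evaluation: two
*independent* standardised frames then sit at expected squared distance 1,
`‖x − y‖²/(2D) = 1 − ρ` for correlation `ρ`. Without this scaling the unit
bandwidth saturates for `D = 500` (squared distances of order `10³`, every
off-diagonal kernel entry numerically 0, and the MMD carries no signal —
observed empirically both at initialisation and after training). The raw
kernel remains available (`standardize_frames(..., kernel_scale=False)`).

The conditional MMD between class-matched samples uses the unbiased
pair-normalised estimator

```
cMMD = Σ_{i≠i'} K(x̂_i, x̂_i') / [m(m−1)]
     − 2 Σ_{i,j} K(x̂_i, x_j) / (mn)
     + Σ_{j≠j'} K(x_j, x_j') / [n(n−1)]
```

which is comparable across sample sizes and may be slightly negative on
identical distributions. The reporting protocol draws 30 synthetic and 30
real frames per class for each of 10 seeds and reports mean ± sd per class
plus a pooled (class-merged) MMD; classes with fewer than 30 real frames
are flagged and computed on what is available.

Intraclass diversity is the mean off-diagonal entry of the
sample-vs-itself kernel matrix: 1 means total mode collapse, values near 0
mean diverse samples.

## 5. Augmentation policies and baselines

A policy is a triple (target class, imbalance degree `d`, synthetic-ratio
`r`). Applying it to a training split of `n` real frames adds
`S = round(r · n)` synthetic frames whose per-class counts are
proportional to `1 + d · 1[c = target]`, rounded by the largest-remainder
method with ties broken toward the lower class index (counts sum exactly
to `S`). Real frames are always conserved; synthetic frames are additive
only, labelled with their conditioning class and flagged in provenance.
The default grid enumerates 3 classes × degrees {0, 0.5, 1} × ratios
{0.1, 0.2, 0.4, 0.6, 0.8, 1.0} = 54 policies.

Baseline augmenters share the `sample(n, cls, rng)` interface:

* **SpecAugment**: random time/frequency band masking of a real frame's
  complex STFT (Hann window of ~0.5 s trimmed to a multiple of 4 samples,
  75 % overlap so the NOLA inversion is exact), inverse STFT back to the
  waveform. With zero masks the round trip is exact to numerical
  precision.
* **Oracle** (positive control): replays genuine held-back real frames.
* **Label-shuffled** (negative control): serves frames of a uniformly
  random class under the requested label.

## 6. TRTR / TSRTR harness

Folds leave `patients_per_class` patients per class out for testing. Per
fold, three schemes are trained and all evaluated on the same untouched
real test fold: `TRTR_imbalanced` (raw training split), `TRTR_balanced`
(classes subsampled to the minority count — the headline baseline), and
`TSRTR` (the balanced split augmented by a policy). The metric is macro
one-vs-rest AUROC over a fixed 10-classifier zoo (naive Bayes, LDA, QDA,
kNN, logistic regression, SVM, decision tree, random forest, AdaBoost,
MLP; LDA/QDA use shrinkage solvers because per-fold training splits can be
smaller than the 50-dimensional feature space). The headline quantity is
`%ΔAUROC = (X_TSRTR − X_TRTR)/X_TRTR · 100` per classifier,
fold-averaged before the ratio. `best_percent_change` reports both
aggregations (best-policy-per-classifier then mean, and mean-per-policy
then best). `factor_tests` applies t-test + Wilcoxon rank-sum (2-level
factors) or ANOVA + Kruskal–Wallis (multi-level), with per-level Shapiro
normality checks.

## 7. SG curve and AUSGC

For a policy and a metric, the synthetic-generalization curve is

```
SG(ε) = (1/M) Σ_m 1[ X_TSRTR,m ≥ (1 − ε) · X_TRTR,m ]
```

over the `M` zoo members, swept over a grid of 101 points on
`[−0.5, 0.5]` (`ε = 1` is excluded; baselines must be positive). The
curve is non-decreasing in ε with values in `[0, 1]`. AUSGC is the
trapezoidal area normalised by the grid span. A no-effect augmentation
(TSRTR ≡ TRTR) produces a 0→1 step at ε = 0 whose trapezoidal area on the
default grid is 0.505 — i.e. 0.5 up to half a grid cell at the jump; tests
assert `|AUSGC − 0.5| ≤` half a cell.

## 8. Numerical choices

* All randomness flows through `numpy.random.Generator`; `fit(seed)`
  spawns independent streams for pool selection, initialisation and
  training via `SeedSequence`.
* Log arguments are floored at `1e-12`; the sigmoid is evaluated in its
  numerically stable split form.
* Gradients (dense layers, convolution, both discriminator heads, and the
  gradient-penalty double backprop) are verified against central finite
  differences to ~1e-6 absolute (the analytic error is at machine
  precision; the tolerance covers the finite-difference truncation).
* Checkpoints are `.npz` containers with a JSON descriptor; no pickling.

## 9. Limitations

* The networks run on a single CPU in NumPy; training wall-time limits
  realistic epochs/dataset sizes to desk scale. Default epochs (200) on
  the 300-frame test fixture take on the order of a minute.
* The synthetic cohort is a caricature of pathological PPG; absolute
  AUROC/MMD values on it do not transfer to clinical data. Only relative
  statements (training reduces MMD, oracle augmentation helps, shuffled
  labels hurt) are validated.
* One kernel bandwidth (unit, after `1/√(2D)` scaling) is used throughout;
  no median-heuristic adaptation.
* `madgan` does not use the diversity-sensitivity reward (its per-class
  generators address collapse structurally), and packing drops up to
  `p − 1` frames per class per batch.
* Only the macro one-vs-rest AUROC metric is implemented in the harness.
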