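# Methods

This note documents the models, algorithms and design choices behind
`sersnet`, and what the synthetic validation study does and does not
demonstrate.

## The data model

A measurement is a 1D SERS spectrum: intensities (arbitrary units) on a
strictly increasing Raman-shift axis in cm⁻¹, nominally 400–1800 cm⁻¹.
Each serum sample is measured five times at different locations of the dried
serum/silver-colloid droplet and the five replicates are averaged pointwise
into the sample's final spectrum. Four diagnostic groups are used in fixed
canonical order: `healthy`, `BC` (bladder cancer), `AC` (adrenal cancer),
`AML` (acute myeloid leukemia); the default cohort layout is 30/30/30/20
samples (110 total). The 17 prominent serum SERS peaks (494–1654 cm⁻¹) and
their literature biochemical assignments ship as a static lookup table
(`sersnet/data/table1.csv`); the package never infers assignments.

## Synthetic spectrum generator

The generator exists so every downstream stage is testable without measured
sera. Each group is a `GroupProfile`:

* **Peaks** — Lorentzian lines (FWHM 14 cm⁻¹ by default; Gaussian
  available) at the 17 prominent positions, with base amplitudes loosely
  following serum practice (strong phenylalanine 1004 and adenine 725
  bands). Raman lines are naturally Lorentzian, hence the default.
* **Group differences** — relative to healthy controls, BC raises
  494/589/639/1135 and lowers 1443; AC raises 531/589/1135 and lowers
  959/1443; AML raises 531/1206/1443 and lowers 1073/1654. The default
  effect size is ±25% of the base amplitude. No effect sizes are published
  for sera, so this is a free simulation parameter, exposed in the config —
  the signs, not the sizes, are the modelled claim.
* **Nuisance structure** — per-sample amplitude jitter (CV 8%), a shared
  degree-5 polynomial fluorescence baseline, a per-replicate log-normal
  multiplicative gain (σ = 0.15) emulating sample-to-sample SERS intensity
  variability, and additive white noise (σ = 0.01); intensities are clipped
  at zero. The baseline is degree 5 *on purpose*: the fifth-order
  baseline-removal stage can remove it exactly, which turns
  baseline-recovery into a clean test.

What the generator does **not** emulate: electromagnetic/chemical SERS
enhancement physics, instrument response, wavenumber miscalibration,
cosmic-ray spikes, and correlated biochemical co-variation between peaks.
Passing tests therefore demonstrate the pipeline's correctness and its
ability to recover localized amplitude differences under realistic nuisance
variability — not clinical performance on sera.

## Preprocessing

Two tracks, matching their downstream consumers:

* **Classical track** (mean-spectra comparison, PCA-LDA/PCA-SVM):
  Savitzky–Golay smoothing (window 11, polyorder 3), then iterative
  fifth-order polynomial baseline removal, then per-spectrum min–max
  normalisation. The baseline algorithm is the modified-polynomial
  peak-clipping scheme: fit a degree-5 polynomial, clip the spectrum to the
  fit, refit, and stop when the largest baseline change falls below 1e-4 of
  the intensity range (max 100 iterations; non-convergence warns and
  returns the last iterate). The smoothing/fit parameters are common
  practice and fully configurable — no published values exist for them.
* **Deep track** (CNN): linear resampling to the model input length, then
  per-spectrum min–max. Normalisation is per spectrum, matching its stated
  purpose of removing per-sample intensity variability; augmentation happens
  separately at the split stage.

Min–max on a (numerically) constant spectrum raises a degenerate-input
error rather than emitting NaNs; "numerically constant" means a range below
1e-10 of the intensity magnitude.

## Split-then-augment cross-validation

Samples (not spectra) are randomly assigned to 5 folds — stratified by
group by default, so the 30/30/30/20 balance gives 6/6/6/4 per fold — and
each of the 5 rotations takes one fold as test, the next as validation and
the remaining three as training. Augmentation happens *after* the split,
independently per subset: each original spectrum contributes `factor = 10`
synthetic spectra, each a convex combination of itself and two other
same-group spectra of the same subset, with weights from the uniform
Dirichlet on the 3-simplex. Convexity keeps every augmented spectrum inside
the hull of its sources, preserves the group mean, and cannot produce
negative intensities — this is what "random linear combination within class"
is taken to mean here. The anchor is always the first source so that
`factor = 1` with degenerate weights reproduces the unaugmented split
exactly. With 110 samples this yields the canonical 660/220/220
train/validation/test sizes per rotation, and no augmented test spectrum
shares source samples with training data by construction.

## The 1D-CNN

Architecture (input length L, default 2046):

| stage | operation | output |
|---|---|---|
| block 1–4 | conv(k=21/11/5/3, 16/32/64/128 ch, stride 1, same pad) → BN → ReLU → maxpool(2,2) | L/2, L/4, L/8, L/16 |
| flatten | — | (L/16)·128 |
| FC1, FC2 | linear → ReLU → BN → dropout(0.7) | 256, 64 |
| FC3 | linear (+ log-sigmoid or softmax reporting) | 4 |

Convolution padding is *reflective*: spectra are smooth curves, and zero
padding introduces artificial step edges whose feature activations were
observed to contaminate gradient-based attribution at the axis ends. The
FC widths 256/64 are package defaults (configurable); no published values
exist for them. Pooling a length-1 map is rejected at build time.

Training: RAdam (β = 0.9/0.999), learning rate 1e-4, batch size 128, up to
300 epochs, class-weighted softmax cross-entropy normalised by the summed
weights. Class weights default to inverse frequency renormalised to mean 1,
which up-weights the minority AML class; the literal `n_c/N` convention
(which does the opposite) and unweighted loss are available as modes, and a
per-class log-sigmoid Bernoulli likelihood is available for parity with the
log-sigmoid output head. The retained parameter state is the one with the
best validation accuracy; ties go to the *later* epoch, because among
equal-validation states the most-trained one has larger margins and
markedly more stable gradient attribution. Everything is float32, lowered
to BLAS matrix multiplications via im2col; training is deterministic given
the seed on a fixed BLAS configuration.

The engine (`sersnet.nn`) implements forward and reverse passes by hand so
that gradients of any intermediate quantity are available exactly — the
property the Grad-CAM stage and its finite-difference tests rely on. The
estimator (`SersCNNClassifier`) follows the scikit-learn contract
(`fit`/`predict`/`predict_proba`, `get_params`, fitted attributes with
trailing underscores) and composes with sklearn tooling.

## Evaluation

Per-class accuracy, precision, recall and F1 come from the one-vs-rest
collapse of the pooled 4×4 confusion matrix; overall accuracy is
trace/total; averaged metrics are support-weighted (macro also reported);
zero-denominator cases return 0 and are flagged. ROC/AUC is computed for
four binary collapses — healthy vs cancer and each cancer vs the rest —
scoring with the positive group's class score; AUC is trapezoidal
(Mann–Whitney-equivalent under ties). Cross-validation pools test
predictions over the 5 rotations into a single confusion matrix (per-fold
accuracies are reported alongside). Welch's unequal-variance t-test is used
for per-peak group comparisons at the grid point nearest each lexicon
position. The chemometric baselines fit PCA (20 components) on training
spectra only, then LDA or an RBF SVM on the scores.

## Grad-CAM and contribution degrees

For a spectrum and a target class, the gradient of the class logit is taken
with respect to the last conv block's post-activation feature maps
(length L/16, 128 channels); the per-channel global average of that
gradient gives channel weights wᵢ; the heatmap is ReLU(Σᵢ wᵢ·Aᵢ), linearly
upsampled to the input grid and min–max normalised (an identically zero map
stays zero and is flagged). Group heatmaps average the maps of a group's
correctly classified spectra (misclassified spectra answer a different
class's "why"; configurable).

For each prominent peak, Sᵢ is the trapezoidal integral of the heatmap over
the peak's FWHM window and Cᵢ = Sᵢ/ΣSᵢ, so contributions sum to 1 exactly.
The FWHM window is located by finding the local maximum within half the
minimum lexicon inter-peak distance of the nominal position and walking
outward to the half-maximum crossings (linearly interpolated; clamped and
flagged if no crossing occurs inside the search window). By default the
window is measured on the heatmap itself; `spectrum_window` mode measures
it on a reference spectrum (the group mean) instead — both satisfy the
normalisation and scale-invariance identities, and they agreed closely in
our studies. Group tables can aggregate as Eq-on-the-mean-heatmap (default)
or as per-spectrum contributions averaged afterwards.

### What attribution can and cannot recover

Two structural limits of this (standard) Grad-CAM formulation matter for
interpreting the tables, and both are visible in the test suite:

* **Absence evidence is invisible.** Evidence *for* a class that consists
  of a peak being lower or missing produces negative gradients, which the
  ReLU removes; a class recognised mainly by absences can have a near-zero
  or unstable heatmap. With only two classes the softmax logits are
  complementary, so one class's map can collapse entirely; class-level
  attribution tests therefore use ≥ 4 classes.
* **Global channel weights smear attribution.** wᵢ averages the gradient
  over the whole length, so strong activations at non-discriminative
  positions (e.g. the dominant 1004 cm⁻¹ band present in every group) can
  receive substantial heatmap area. On synthetic data where each group
  differs at a handful of designated peaks, per-spectrum heatmap maxima
  localise to the discriminative peak reliably for classes whose evidence
  is a raised peak, and group contribution tables usually rank raised
  peaks highly — but not every raised peak of every group lands in the top
  ranks in every run. The acceptance suite asserts the strict ranking
  property and documents its failures rather than weakening it.

## The built-in validation study

`scripts/acceptance.py` (and `tests/test_acceptance.py`) run the study at
sizes chosen for a single CPU core: the 5-fold cross-validation study uses
the full 110-sample cohort with ×10 augmentation on a **512-point** axis and
model input with 30 epochs per rotation (≈4 min; the CNN reaches perfect
validation accuracy well before epoch 30 at this size), and the
interpretation study trains one rotation at a **1024-point** input (finer
attribution resolution — the heatmap's native resolution is input/16, which
must be finer than the lexicon's inter-peak spacing). Metric oracles use
1000 random confusion matrices and 300 exhaustive Mann–Whitney AUC
instances; gradient checks difference all 128 channels of a small network.

## Known limitations

* Synthetic effect sizes (±25%) are arbitrary; results say nothing about
  discriminability of real sera.
* Reported paper-style metrics (e.g. pooled accuracy) are on synthetic
  data; they validate the machinery, not the clinical claim.
* The attribution stage inherits Grad-CAM's structural biases (above).
* Training determinism holds for a fixed BLAS/thread configuration;
  different BLAS builds may yield slightly different trajectories.
* Vendor binary spectrum formats (SPC/WDF/JCAMP-DX) are out of scope; I/O
  is CSV/TSV and JSON only.
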