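# Methods

## Problem and model

The package classifies volumetric scans from scan-level binary labels only.
Each scan is treated as a multiple-instance bag of ordered axial slices; the
scan label obeys the standard MIL rule (negative iff every slice is
negative). The classifier is the composition Ŷ = g(P f(X)):

- **Instance representation f.** A frozen per-slice feature extractor
  followed by a trainable tail of two fully connected layers
  (D_raw → 512 → 512) with ReLU and dropout 0.5. The extractor is never
  fine-tuned: with cohorts of a few hundred scans, training a deep extractor
  end-to-end would be badly underdetermined, while a frozen extractor plus a
  ~1M-parameter head keeps the trainable surface small.
- **Pooling P.** Attention pooling a_n = softmax(wᵀ tanh(V x_nᵀ)),
  z = Σ a_n x_n, with embedding dimension 512 and attention hidden dimension
  128; element-wise mean and max pooling as baselines. All three are
  permutation-invariant across slices.
- **Classifier g.** Affine 512 → 1 with sigmoid.

Two scan-level baselines ignore the MIL structure: a noisy 2D slice
classifier trained with the scan label broadcast to every slice (scan score
= mean slice probability; max available), and a fully 3D CNN on volumes
axially interpolated to a fixed 128 slices (four valid-3×3×3-conv + ReLU +
2×2×2 average-pool blocks, global average pooling, sigmoid).

All trainable models are plain numpy with hand-derived backpropagation;
tests validate every gradient against central finite differences at 1e-5
relative tolerance. A deliberate consequence: the package has no
deep-learning framework dependency, and the pretrained (VGG19) extractor
path — per-block spatial average pooling of the five max-pool block
outputs, per-block L2 normalization, concatenation to D_raw = 1472 —
raises an explicit error directing users to the lightweight extractor when
no runtime with ImageNet weights is available.

## Feature extractors

**Lightweight (default, `light`).** Each slice is partitioned into an 8×8
grid and summarized by block means, block standard deviations, and block
minima of a Gaussian-smoothed (σ = 2 px) copy of the slice — the smoothed
minimum is a classic blob response, chosen because the lesions of interest
are blob-like hypoattenuated regions and smoothing keeps noise pixels from
setting the minimum. The 192 statistics are expressed as deviations from
the scan's per-bag median statistics (bag-context normalization), mapped
through a fixed, seeded Gaussian projection to 512 dimensions with a ReLU,
and L2-normalized to norm √D so downstream activations sit at unit scale.

Bag-context normalization is the load-bearing choice. With absolute slice
summaries, attention-MIL has two loss-equivalent optima: attend to lesion
slices, or attend to clean slices and let the classifier read the
complementary signal — and which one training finds is decided by early
gradient noise, so attention "localization" flips polarity run to run.
Representing each slice by its deviation from the scan's own typical slice
makes the typical (clean) slices of every scan nearly identical, so a
pooled representation built from clean slices cannot separate scans; only
the atypical, lesion-like slices carry bag-discriminative signal, and the
anti-localized optimum disappears structurally. On the default synthetic
cohort this took held-out lesion-slice attention localization from ~0.6–0.75
(polarity-unstable) to 1.0 across all repeats. Extraction remains a pure,
deterministic function of the bag's pixels and the extractor seed; an
all-zero bag yields the (normalized) bias-only response on every slice.

**Transfer (`vgg19`).** The Antropova-style multi-block pooled feature
scheme described above. Grayscale slices are replicated to three channels.
Unavailable offline; the architecture metadata (block widths, D_raw) is
implemented and testable without weights.

## Training protocol

Bag-level binary cross entropy; Adam with β₁ = 0.9, β₂ = 0.99, initial
learning rate 1e-4; one bag per optimization step (bags vary in length, and
one-bag steps are standard attention-MIL practice). Scans are split
70/10/20 into train/validation/test, stratified by label (validation sets
of ~10% of a few hundred scans are otherwise unstable at low prevalence);
global role sizes are the rounded fractions (half-to-even), allocated
across classes by largest remainder so totals are exact. The protocol is
repeated 5 times with independently drawn splits; all repeats derive their
split/init/shuffling seeds from one master seed, so two models run with the
same master seed see identical splits and their per-repeat DeLong
comparisons are paired on identical test cases.

Early stopping: training halts when the validation loss fails to drop below
the best so far by at least 1e-6 for 7 consecutive epochs, and the
best-validation-epoch parameters are restored. The epoch cap is 30;
with patience 7 the stop typically fires near epoch 15, and the cap only
bounds rare slow-plateau runs whose extra epochs were observed to add
nothing to held-out AUC.

**Initialization.** All parameters are drawn from normal distributions. By
default weight tensors use std = 1/√fan_in and biases std = 0.01; a fixed
small std (e.g. 0.01) for 512-wide weight matrices shrinks activations by
~0.01·√512 ≈ 0.23 per layer and stalls learning at the 1e-4 learning rate.
The std is configurable per layer class (weights vs biases).

## Evaluation

AUC is the midrank Mann–Whitney statistic; its variance and the paired
model comparison come from the DeLong structural components (per-positive
and per-negative placement values, with the cross-model covariance
included). Comparisons across the 5 repeats are aggregated by the median
p-value; the family of model pairs is Bonferroni-corrected (the most
conservative standard choice). A comparison with zero variance of the AUC
difference (e.g. identical scores) raises a typed error at the statistics
layer and is mapped to p = 1 ("no evidence of difference") at the report
layer. The test suite checks the DeLong test's type-I error on 1000
paired-null replicates (rejection rate within [0.035, 0.065] at α = 0.05).

## Attention interpretability

Per scan, attention weights are min–max scaled to [0, 1] (a constant vector
maps to 0.5 — an uninformative midpoint that avoids division by zero) and
paired with normalized depths: slice j of N sits at (j−1)/(N−1), 0 = lung
top, 1 = lung bottom; a single-slice scan sits at 0. A degree-4 polynomial
(configurable) is least-squares fitted to the pooled (depth, scaled weight)
points of a scan group; degree 4 represents the smooth unimodal-to-bimodal
shapes these profiles take while keeping the fit closed-form. Three
influence metrics, in percent of lung depth:

1. argmax of the fitted curve on [0, 1] (grid-evaluated at 2001 points);
2. attention-weighted mean slice depth, pooled over scans using raw
   per-scan weights (each scan's weights sum to 1, so scans contribute
   equally; the alternative — reading the average off the fitted curve —
   is a switchable choice, but the weight-based form is exact and does not
   inherit fit error);
3. max − min of the fitted curve on [0, 1].

Top-k analysis: for each scan the k highest-attention slices (ties broken
toward the lower slice index, for determinism) are checked for each
annotated imaging feature; prevalence is the fraction of scans whose top-k
slices contain the feature, compared against whole-scan prevalence. With
k = N this equals whole-scan prevalence exactly. k > N is clipped to N with
a logged warning.

## Synthetic phantom generator

The generator emulates the *structure* of a screening cohort, not its
radiology: bags of 20–60 slices of 64×64 pixels; a fixed two-ellipse lung
mask inside a body ellipse; abstract intensities in [0, 1] (no Hounsfield
calibration — the method never uses HU thresholds). Positive scans receive
lesions on max(1, round(lesion_fraction · N)) slices; lesions are
hypoattenuated discs whose contrast is signal_effect × the slice noise SD
(0.05), so signal_effect = 0 makes lesion and clean slices statistically
indistinguishable. Lesion slice depths are drawn from a truncated normal on
[0, 1] with configurable mode (default 0.2 — upper-lung predominance) and
spread (0.1) for the "centrilobular-like" and "paraseptal-like" phenotypes;
"panlobular-like" scans draw uniformly across depth. Phenotype proportions
default to 0.80/0.11/0.09, the approximate ratio seen in screening cohorts.
Four nuisance features (nodule-like bright discs, bronchial-like rings,
distortion-like streaks, ground-glass-like haze) are rendered per slice
with label-independent Bernoulli rates, so attended-feature prevalence
analyses can be checked against known rates. Defaults: 300 scans, 50%
positive, signal_effect 3.

What the phantoms do *not* model: anatomy, dose/noise physics, slice
thickness variation, inter-slice correlation of disease, or
label-correlated nuisance findings. Passing the end-to-end tests therefore
shows that the pipeline recovers planted weak-label signal and localizes
it in depth — not that it would quantify real emphysema.

## Problem sizes and numerical choices

- End-to-end experiments (tests and the acceptance script) use the default
  300-scan cohort, 5 repeats; the script additionally runs a shuffled-label
  control (5 repeats). The mean/max pooling and non-MIL baselines are
  exercised in the test suite and available through the library and CLI.
- Softmax uses max-subtraction; BCE clips probabilities at 1e-12; tanh
  saturation is accepted as-is.
- MIL heads compute in float32 by default (float64 available via `dtype`,
  used by the gradient-check tests); Adam keeps flat float32 moment
  buffers.
- Axial interpolation to 128 slices is linear with endpoints pinned, the
  identity when N = 128, and replication when N = 1.
- Volume orientation is resolved from the NIfTI affine (canonical
  reorientation, then superior→inferior slice order) or DICOM
  ImagePositionPatient z (descending); a volume stored with either axial
  direction loads identically.

## Known limitations

- The attention polarity argument above is an initialization-scale
  heuristic, not a guarantee; pathological feature geometries could still
  converge to anti-localized attention.
- The DeLong test is asymptotic; at very small test sets (tens of scans)
  its per-repeat p-values are approximate, which is one reason the median
  across repeats is used for decisions.
- The noisy-2D and 3D baselines are faithful in structure but modest in
  capacity; they are baselines, not tuned competitors.
- Single-slice scans get normalized depth 0 by convention; depth analyses
  on such degenerate bags are not meaningful.
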