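# Methods

## Overview

`lesionfuse` classifies pigmented skin lesions from two modalities — a
dermatoscopic image and the patient's clinical record (age, sex, lesion
site, diagnosis-confirmation method) — by encoding each modality into a
fixed-width embedding and combining the embeddings with one of eight fusion
operators before a small feed-forward classifier. The package also provides
post-hoc explanations: Grad-CAM localization for the image branch and
Integrated-Gradients attributions for the clinical branch.

The implementation runs on a compact reverse-mode automatic-differentiation
engine written on NumPy (`lesionfuse._tensor`, `lesionfuse.nn`). This keeps
the dependency surface to the scientific Python stack and makes every
gradient path — including those used by Grad-CAM and Integrated Gradients —
inspectable; the engine is validated against central finite differences in
the test-suite.

## Preprocessing pipeline

Order of operations, with statistics strictly fitted on training data:

1. **Split** — stratified 70/30 by diagnosis (per-class train count =
   `round(count × fraction)`), seeded. Stratification guarantees all seven
   classes appear in the test split, without which per-class metrics would
   be undefined; a plain random split would not guarantee this for the rare
   classes.
2. **Class balancing (training split only)** — classes above the target are
   randomly undersampled; classes below it are filled with replicated and
   augmented copies (pixel jitter, horizontal/vertical flips, rotations,
   rescaling). Every synthetic record stores the source image id and the
   augmentation (operation, parameters, seed), so balanced manifests are
   reproducible and persistable. Balancing a 70 % training split of the
   emulated archive to 6,000 per class yields 42,000 records.
3. **Image preprocessing** — resize to a square (256 px by default; smaller
   for desk-scale runs) and scale to [0, 1] by dividing by 255.
4. **Metadata preprocessing** — median imputation for age, mode imputation
   for categoricals, then one-hot encoding over *fixed* vocabularies
   (so encoded widths never depend on which levels a cohort happens to
   contain), then standardization of age to zero mean / unit variance.
   Imputation precedes encoding; the diagnosis is emitted only as the
   label, never as a feature. `dx_type` (how the diagnosis was confirmed)
   is included as a feature by default — it is part of the schema and the
   attribution tables rank it — but a switch excludes it, since it can leak
   label information in real cohorts.
5. **Alignment** — all arrays are joined on `image_id`; row *i* of the
   encoded metadata, label *i* and image *i* always refer to the same
   lesion.

Augmentation magnitudes (defaults, all configurable): jitter amplitude 0.02
of full scale, rotations uniform in ±30°, rescale factor uniform in
[0.9, 1.1]. Axis-aligned rotations are implemented exactly (array rotation,
no interpolation). Standardization statistics are computed on the balanced
training set — what the model actually sees — not the pre-balance split.

## Encoders

**Clinical MLP.** `affine(d_c → 128) → ReLU → affine(128 → 256)`. The
input width `d_c` is 1 numeric + the one-hot widths (23 with all three
categoricals at full vocabulary).

**Weighted-residual image encoder.** Each residual unit computes

    y = F(x) + α · skip(x),    F = [conv3×3 → BN → LeakyReLU] × 2

with `α` a learnable scalar per block, initialized to 1.0 (recovering a
plain residual block at the start) and unconstrained afterwards. When the
block downsamples or changes width, `skip` is a learned 1×1 strided
projection, also scaled by `α` so the skip weighting remains meaningful
across shape changes. The network is: a stem (7×7 stride-2 conv, BN,
LeakyReLU slope 0.01, 3×3 stride-2 max-pool), four stages of
[stride-2 unit, stride-1 unit] with channel widths `w, 2w, 4w, 8w`
(`w = 64` by default, giving 64 → 128 → 256 → 512), dropout (p = 0.3
default) inside the residual branches of stages 3–4 only, global average
pooling, and a two-layer head (`8w → 512`, LeakyReLU, `512 → 512`) emitting
the 512-d embedding. A linear 7-way head on the same backbone serves the
image-only ablation.

One deliberate deviation: a softmax on the *feature* head would destroy the
embedding's scale information, so the default head omits it; a
`literal_softmax_head` flag restores the literal reading for comparison.

Batch-norm running statistics are seeded from the first training batch and
then tracked with momentum 0.1. Starting the running estimates at (0, 1)
instead biases evaluation-mode normalization badly for short training runs
(tens of update steps), which the desk-scale experiments rely on.

## Fusion operators

With `x ∈ ℝ⁵¹²` (image) and `y ∈ ℝ²⁵⁶` (clinical):

* **concat** `z = [x; y] ∈ ℝ⁷⁶⁸`.
* **wconcat** `z = [w₁x; w₂y]`, scalars initialized at 1 so the operator
  starts exactly equal to plain concatenation.
* **hadamard** `z = (Px) ⊙ y ∈ ℝ²⁵⁶`, `P` an affine 512 → 256 map.
* **tensor** `Z = x ⊗ y ∈ ℝ⁵¹²ˣ²⁵⁶`; for the classifier the matrix is
  flattened and affinely projected to 512 to keep parameter counts
  tractable. The raw outer-product matrix remains accessible.
* **bilinear** `zᵢ = xᵀWᵢy` for `i = 1..256`, `W ∈ ℝ²⁵⁶ˣ⁵¹²ˣ²⁵⁶`
  initialized uniform with scale `1/√(512·256)`. Evaluated with one matrix
  product; the test-suite checks it against a literal triple loop.
* **gated** `g = σ(W_x x′ + W_y y + b)`, `z = g ⊙ x′ + (1−g) ⊙ y` with
  `x′ = Px`. The gate includes a bias term (zero-initialized); with all
  gate parameters at zero the operator returns the exact midpoint
  `0.5(x′+y)`.
* **selfattn / crossattn** — single-head scaled dot-product attention over
  token grids. A 1×512 "sequence" would make softmax attention degenerate
  (one key ⇒ weight 1), so embeddings are reshaped into tokens (defaults:
  image 8 × 64, clinical 8 × 32) and projected per token to a model width
  `d_m = 64`. Self-attention runs within each modality, mean-pools the
  attended tokens and concatenates the two pooled vectors (`2·d_m`).
  Cross-attention derives queries from image tokens and keys/values from
  clinical tokens, `z = softmax(Q_x K_yᵀ/√d_m)V_y`, and **concatenates the
  per-query attended outputs** (`T_x·d_m`) rather than averaging them.
  Averaging over queries collapses exactly the information this operator
  adds — which clinical values each image-derived query selected — leaving
  the classifier little more than a metadata summary; the flattened form
  preserves the per-query mixtures. With one query and
  one clinical token the operator still reduces exactly to `y W^V`. The
  literal single-token configuration remains available for contract tests.

No normalization layers are used inside fusion blocks. All fusion
parameters are registered learnables; a one-step optimization probe in the
test-suite asserts every one of them moves.

## Training and evaluation

Adam (β = 0.9/0.999, ε = 1e-8) on cross-entropy over unnormalized class
scores; defaults: batch size 64, 100 epochs, learning rate 0.001. No
schedule, weight decay or early stopping. Data order is a seeded shuffle
per epoch, so runs are bit-reproducible given the seed. A non-finite loss
aborts with the offending epoch/batch index.

Evaluation on the untouched test split reports: overall accuracy; per-class
and macro precision, recall (sensitivity), specificity and F1; per-class
one-vs-rest ROC-AUC (rank statistic, ties counted ½ — cross-checked against
exhaustive Mann-Whitney pair counting); and the confusion matrix (rows =
true class). Macro averaging is used for the headline numbers, treating
the seven classes symmetrically as the balanced training regime intends.
A class absent from the test split is reported as undefined (NaN, listed in
`undefined_classes`), never silently zero.

The public surface is a statsmodels-style pair: `LesionFusionModel(images,
metadata, labels, config).fit()` returns a `LesionFusionResults` with the
trained network, the loss history, `evaluate()`, `summary()` and
checkpointing.

## Explainability

**Grad-CAM** — for a target class *c* and a convolutional stage activation
`A^k`: channel weights `α_k = (1/Z)Σᵢⱼ ∂y^c/∂A^k_{ij}`, heatmap
`L^c = ReLU(Σ_k α_k A^k)`, bilinearly upsampled and min-max normalized for
overlay rendering. The metadata input is held fixed during the backward
pass. The default target layer is the deepest stage (stage 4); all-negative
combinations yield a valid all-zero map, flagged rather than rescaled. The
test-suite checks the closed form for a pool-then-linear toy model and the
invariance of the map to constant shifts of all class scores.

**Integrated Gradients** — right-endpoint Riemann approximation with
S = 50 steps (default) on the straight-line path from a zero baseline to
the encoded clinical row, the image held fixed at its observed value.
Note the baseline caveat: in encoded space, "zero" for a standardized
numeric feature means *the training mean*, and for a one-hot block it means
*no level active*. Absolute attributions are normalized so the top feature
scores 1.00; ranking ties break deterministically by feature name.
One-hot columns are reported individually by default (mirroring the
instance-relevance table format), with an optional aggregation summing
member columns' absolute attributions per original feature. The linear
closed form `IGᵢ = wᵢxᵢ` holds exactly for any S; completeness
(`ΣIG = f(x) − f(x′)`) is verified to 1 % at S = 300 on a smooth toy model.

The three distinct quantities that share the symbol α in the literature —
the residual skip weight, the Grad-CAM channel weights, and the IG path
scalar — are named `alpha`, `channel_weights` and `alphas` (path fractions)
respectively in code and never interact.

## Synthetic cohort generator

The generator emulates the structure of the public HAM10000-style archive:
seven diagnoses with its class imbalance (proportions of 1113/6705/514/327/
1099/115/142 over 10,015), ages 0–85 in 5-year steps, sex ≈ 54/45/1 %,
a 15-site lesion-location vocabulary, and four confirmation methods.
Images are procedural: skin-tone background with Gaussian texture, one
elliptical lesion with class-conditional colour, border irregularity
(random-harmonic radial perturbation) and internal texture, plus optional
dark hair-strand arcs at a configurable rate. Class counts use a
deterministic largest-remainder allocation so count-based tests are exact;
identical configuration + seed reproduces byte-identical metadata and
pixels. A configurable fraction of ages (5 % default) is blanked to
exercise imputation.

Signal placement is configurable: `image_only`, `metadata_only`, `both`, or
`xor`. In metadata-signal modes the shifts are chosen to be clinically
plausible (older ages for keratinocytic cancers, histopathology
confirmation for malignant classes, site preferences per diagnosis). The
calibration is tested: in `image_only` mode a cross-validated logistic
model on the metadata is statistically indistinguishable from the majority
rate (binomial test at n = 1000).

**The XOR probe.** `xor` mode is a two-class cohort (NV vs MEL labels)
whose label is the exclusive-or of a binary image cue (very dark vs very
light lesion) and a binary metadata cue (lesion-site group). Design
choices that matter:

* The image cue is carried by lesion *luminance*, not hue: hue contrasts
  attenuate rapidly through a randomly initialized deep network, whereas a
  luminance cue shifts the mean activation of every channel and survives
  global average pooling, so joint training can discover it.
* Labels are allocated exactly 50/50. Given the label, the cue pair is
  drawn under a fair image-cue prior and a metadata-cue prior of 0.65,
  then each rendered cue is flipped with probability 0.02 (observation
  noise). The bias makes each cue *near*-uninformative rather than exactly
  uninformative: an image-only classifier's Bayes ceiling is 0.644 and a
  metadata-only classifier's exactly 0.5, while the fused ceiling is 0.96.
  `xor_bayes_accuracy` computes all three by exact enumeration of the
  joint distribution, and a Monte-Carlo test confirms the enumeration.
  The residual marginal signal is what lets a jointly trained image branch
  bootstrap; a pure 50/50 XOR leaves the deep branch with no gradient at
  all and nothing trains.

The fusion-gain experiment (`lesionfuse.experiments`) trains the two
unimodal ablations plus concatenation and cross-attention fusion on three
seeded XOR cohorts and reports median test accuracies. The package's desk
scale for this probe is n = 2000 cohorts at 32 × 32 px with a width-4
backbone (32-d image / 32-d clinical embeddings; cross-attention uses
8 tokens with model width 16), 30 epochs, batch 32 — chosen so the whole
experiment runs in minutes on a single CPU core while leaving the
published optimizer recipe (Adam, lr 0.001, cross-entropy) untouched. The
narrow backbone matters beyond runtime: at a few thousand samples a wider
image branch has the capacity to memorize spurious per-image rules instead
of generalizing the planted interaction. A companion ordering experiment
on a `both`-signal cohort (n = 600, 15 epochs, a width-8 backbone for the
seven-class task, all eight fusion operators) checks that no fusion method
falls materially below the better unimodal baseline.

**What passing these tests does and does not show.** The synthetic images
are geometric caricatures: no dermoscopic structures (networks, globules,
blue-white veil), no calibrated colour, no acquisition variation beyond
Gaussian noise and hair artifacts. The XOR result demonstrates that the
fusion operators can extract a cross-modal interaction that neither branch
carries alone — a property claim about the architecture and training code,
not a performance claim about real dermatoscopy. Accuracies on the real
archive would additionally depend on photographic invariances and
fine-grained texture that this generator deliberately does not model.

## Numerical choices

* float32 throughout; parameters initialized uniform with fan-in scaling
  `±1/√fan_in`.
* Convolution via im2col + BLAS matrix product; max-pool backward scatters
  through stored argmax indices; softmax and cross-entropy use max-shifted
  stable forms.
* Largest-remainder ties break by class order (stable sort); ranking ties
  break by feature name; stratified-split per-class train counts are
  clamped to leave at least one member on each side.
* Degenerate inputs: an all-zero Grad-CAM map and an all-zero attribution
  vector are returned flagged (`all_zero=True`), not renormalized; AUC for
  a class without positives or negatives is NaN and flagged; a zero
  variance in age standardization falls back to 1.
* Checkpoints store every parameter and batch-norm running statistic in a
  single `.npz` with the run configuration embedded; loading into a
  mismatched architecture raises a checkpoint-incompatibility error naming
  the offending keys.

## Known limitations

* No GPU path and no multi-head attention; the engine is intended for
  desk-scale cohorts, not the full archive at 256 px.
* No hair removal, colour constancy, focal loss or generative
  oversampling; the balancing pipeline is replication + classical
  augmentation only.
* The IG zero baseline inherits the encoded-space caveat above; users
  comparing attributions across preprocessing configurations should hold
  the baseline convention fixed.
* The unimodal-vs-fusion ordering is only asserted at desk scale and for
  median-of-three-seeds aggregates; single runs of the weaker operators
  (tensor, self-attention) can fall below the unimodal baselines.
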