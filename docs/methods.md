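# Methods

## The model

`ocufusion` implements an attention-guided multi-color-space fusion
classifier for six-category ocular-surface disease screening from single
eye photographs.  One input image `I` is decomposed into three aligned
8-bit planes — RGB, HSV (hue scaled onto 0–255) and BT.601 full-range
YCbCr — and each plane is encoded by its **own** MobileNetV3-Small
backbone `f(·)` (no weight sharing), ending in a 576→1024 linear so each
branch emits a d = 1,024 embedding:

    F_RGB = f(I_RGB),  F_HSV = f(I_HSV),  F_YCbCr = f(I_YCbCr)

The embeddings are concatenated, `F = [F_RGB; F_HSV; F_YCbCr] ∈ R^3072`,
and refined by single-head scaled dot-product self-attention

    Attention(Q, K, V) = softmax(QKᵀ / √d_k) V,   Q = FW_q + b_q, …

with 3072×3072 projections and d_k = 3072.  A head
3072 → 1024 → 512 → 6 (batch-norm, ReLU and dropout 0.3 on the hidden
layers) produces logits; softmax is applied explicitly only at inference.

### The single-token reading of the attention block

The description above leaves the token structure open.  The default
treats the fused vector as a **single token**.  With one token the
softmax is over a 1×1 score matrix and equals 1 identically, so

    output ≡ F W_v + b_v        (exactly, to the last bit)

and no gradient reaches `W_q`/`W_k`.  We implement the general tokenized
path and assert this identity rather than hiding it: it is an analytic
property of the architecture as described, and the parameter total only
matches the published figure under this reading.  A documented
alternative (`attention_mode: three-token`) treats each color-space
embedding as one of three 1,024-wide tokens with 1024×1024 projections
and d_k = 1024, giving a non-degenerate attention pattern at the cost of
no longer matching the printed parameter count.

### Parameter accounting

The calibration that reproduces the published totals:

| component | parameters |
|---|---|
| one branch (MobileNetV3-Small, 1000-way linear removed, 576→1024 linear kept) | 1,517,856 (1.52 M) |
| attention projections, weights **and biases**, 3 × (3072² + 3072) | 28,320,768 |
| head 3072→1024→512→6 with two batch-norms | 3,677,702 |
| **total** (3 branches + attention + head) | **36,552,038 (36.55 M)** |

The projection biases are required by the arithmetic: bias-free
projections give 28,311,552 and a 36.54 M total.  With one token the
biases only shift the value projection, so this choice does not change
the model class in the single-token mode.

### Variants

`build_variant` exposes the ablation registry: `rgb-only` (one branch +
head), `fusion-no-attention` (concatenation straight into the head),
`fusion-se` / `fusion-cbam-channel` / `fusion-eca` / `fusion-nam`
(channel-recalibration gates applied to the 3,072-d fused vector in
place of self-attention; SE and CBAM use reduction 16, ECA an adaptive
1-D kernel, NAM batch-norm-scale gating), and single-backbone reference
baselines (`baseline-resnet50`, `baseline-efficientnet` (B0),
`baseline-vit` (B/16)) on RGB.  With a 1×1 "spatial" extent the CBAM
channel gate's average- and max-pooled descriptors coincide, so it
degenerates to `sigmoid(2·MLP(x))`; this is the faithful application of
the block to a vector and is documented rather than patched.

## Training protocol

Stratified k-fold cross-validation (default k = 5) at the image level;
per-class shuffle under a fixed seed followed by round-robin assignment
guarantees per-class fold counts within one of N_c/k.  Per fold the
model is re-initialized from scratch and optimized with Adam
(lr 1e-4, β = (0.9, 0.999), ε = 1e-8, no weight decay, no schedule),
batch 16, at most 50 epochs, early stopping after 10 epochs without a
strictly lower validation loss (min_delta 0), checkpointing the weights
with the best validation macro-F1 and discarding previous checkpoints.

The loss is weighted cross-entropy

    L = −(1/N) Σ_n w_{y_n} · log softmax(z_n)_{y_n},   w_c = N / (N_c · C)

with division by the batch size N exactly (not by Σw), so unit weights
recover the ordinary mean cross-entropy, balanced classes give w_c = 1,
and Σ_c w_c N_c = N always.

Augmentation (training split only, applied to RGB before decomposition
so the three planes stay geometrically aligned): horizontal flip
p = 0.5, rotation uniform in ±15° (bilinear, black fill), then
brightness/contrast/saturation factors uniform in [0.8, 1.2] in that
fixed order.  Validation preprocessing is resize + normalize only.
Channel-wise normalization statistics (9 channels, 0–255 units) are
computed from the fold's training split only and applied to both splits;
resizing (bilinear, default 224, tests use 64) precedes conversion.
Hue is treated as an ordinary channel during normalization; the
wrap-around at red is not handled specially.

Pretrained initialization of the RGB branch (with HSV/YCbCr random) is
the documented transfer-learning configuration; it requires a local
weights file (`pretrained_weights`) and is off by default, so all
experiments here train from random initialization.

## Evaluation

Accuracy is trace/N of the confusion matrix; precision, recall and F1
are computed per class one-vs-rest from the confusion counts and
macro-averaged without class weights.  Multi-class AUC uses the
one-vs-one strategy: for each unordered class pair, samples of the two
classes are ranked by each class's own probability, the two directed
AUCs are averaged, and pair scores are macro-averaged; ties count ½
(Mann–Whitney convention).  Cells with zero denominators are defined as
0 and flagged so fold aggregation stays total.  Folds aggregate as
mean ± sample standard deviation (ddof 1, 4 decimals); variants are
compared by paired two-sided t-tests on fold-wise differences with
significance at p < 0.05 (zero-variance differences flagged, not
tested).

## Grad-CAM

For each branch the last convolutional block's map A is captured;
channel weights are the spatially averaged gradients of the target-class
logit w.r.t. A; the map is the rectified weighted channel sum,
max-normalized (an all-zero map stays zero and is flagged degenerate)
and upsampled bilinearly.  Because the network pools globally before the
classifier, the gradient is spatially uniform and the procedure reduces
to classic CAM; localization information comes entirely from the
activation patterns.  Two implementation details matter at small image
sizes:

* **Grid alignment.**  With stride-2 pad-1 convolutions, feature cell
  (i, j) is centred on input pixel (s·i, s·j) for total stride s.  The
  upsampler samples at `x_in = x_out / s` to preserve that alignment; a
  naive image resize shifts every map by s/2 pixels — half a lesion
  radius at 64 px — and systematically displaces the argmax.
* **Cross-branch gradient coupling.**  Branch activations depend only on
  their own color plane, but the gradient weights flow through the
  shared head, whose ReLU gating depends on all three branches.  Branch
  maps are therefore not strictly independent across planes; the
  activation part is, and the test suite asserts exactly that.

The combined map is the unweighted mean of the three branch maps.  The
visualized class defaults to the predicted one and can be overridden.
Overlays blend a jet colormap at fixed α = 0.4.

## Synthetic data

Real screening data cannot ship with the package, so a procedural
generator emulates the study's signal structure on a shared eye template
(sclera, amber iris annulus with mild radial texture, dark vertical slit
pupil), 64×64 by default:

* *Regular*: no perturbation.
* *Conjunctivitis*: peripheral hue shift toward red on the sclera
  (chromatic-plane signal).
* *Blepharitis*: red, noise-textured rim at the image border.
* *Corneal Sequestrum*: a dark **brown** plaque (74, 42, 18) of radius
  ≈ 0.15 (normalized units) placed on the iris annulus, deliberately
  clear of the pupil slit — a dark plaque overlapping the equally dark
  pupil would carry no visible signal, making the ground-truth mask
  wrong — and chromatically distinct from the near-black pupil, as real
  necrotic sequestra are.
* *Corneal Ulcer*: a bright star-convex blob with local contrast loss.
* *Non-Ulcerative Keratitis*: global haze (luminance contrast shrunk
  toward the mean in YCbCr, chroma preserved).

Nuisance illumination (all classes): brightness/contrast jitter and an
optional glare ellipse with magnitude proportional to
`nuisance_strength`.  Masks stored as `<image_id>.mask.png` cover the
full support of the planted perturbation (smooth blend rim included);
"Regular" and the global-haze class get empty masks.  One RNG stream per
image keyed by (seed, class, index) makes any subset byte-reproducible.

What the generator does *not* emulate: anatomical variability between
animals, device/viewpoint variation, co-occurring conditions, specular
texture of real corneas.  Passing tests therefore demonstrate that the
pipeline's machinery is correct and that the architecture can exploit
chromatic and luminance signal under illumination nuisance — not
clinical performance.

## Desk-scale experiments

The published headline numbers require the external 16,480-image
clinical dataset and multi-hour GPU training; they are out of desk
scope.  The package instead fixes two synthetic experiments, sized to
run on one CPU core:

* **Attention ablation** (`ocufusion.benchmark`): 100 images/class,
  64 px, nuisance 0.5, generator seed 7; per training seed (0, 1, 2) a
  stratified k = 2 split defines a 50/50 partition and one fold is
  trained (three seeds give three independent splits — the package's
  compute-budget choice); batch 16, Adam 1e-4, 12 epochs (the benchmark
  caps the budget at 15), no pretrained weights, best-validation-F1
  weights restored before evaluation.  The check is direction-only —
  mean validation accuracy of the attention model at least that of
  plain concatenation, both above chance — not the full-scale margin.
* **Saliency localization**: 70 images/class at nuisance 0.3 (generator
  seed 11), 50/class for training a tiny-backbone fusion model
  (four-block CNN, d = 64, 15 epochs); on 20 held-out sequestrum images
  the combined Grad-CAM argmax must fall inside the planted mask in the
  majority of cases.  Strong nuisance matters here: with weak
  illumination jitter the classifier can lean on class-conditional
  global color statistics and needs no localized evidence.

The tiny backbone (stride-8 final map, ≈ half-image receptive field) is
used for these experiments because a three-block variant proved purely
edge-driven: its class-activation maps peaked on lesion rims and pupil
edges rather than lesion bodies.

## Numerical choices and implementation notes

* All network arithmetic is float32, channels-last; pointwise
  convolutions and linear layers run as BLAS matmuls, depthwise
  convolutions as k² shift-accumulate passes, general convolutions via
  im2col.  Backward passes are hand-derived per layer and verified
  against finite differences and float64 reference implementations.
* Adam uses the standard `p −= α·m̂/(√v̂+ε)` reformulation with a fused
  update kernel; gradient buffers are reused as scratch during the step.
* Batch-norm: eps 1e-3 / momentum 0.01 in the backbones (matching the
  published architecture), eps 1e-5 / momentum 0.1 in the head;
  eval-mode backward differentiates the running-statistics affine map.
* Early-stopping "improvement" is strictly lower validation loss by any
  margin; checkpoint selection is strictly higher macro-F1.
* Degenerate inputs: empty manifests, classes smaller than k,
  zero-variance normalization channels, non-finite losses, and
  single-class AUC pairs all raise or flag rather than silently
  continuing.
* Determinism: all stochastic steps (splits, init, shuffling,
  augmentation, dropout) draw from generators seeded from the run seed,
  so a repeated run reproduces its metric tables byte-for-byte on the
  same platform (floating-point kernel differences across BLAS builds
  can change low-order bits across machines).

## Known limitations

* Single-token self-attention is analytically a linear value projection;
  claims about "attention weighting" reduce, in this reading, to the
  extra learned linear map.  The three-token mode exists precisely to
  probe the non-degenerate alternative.
* On the desk-scale ablation benchmark this has a concrete consequence,
  which the test suite measures and reports honestly: once both
  variants are trained long enough to beat chance, plain concatenation
  *outperforms* the attention variant (the extra randomly initialized
  3072×3072 projection slows convergence at lr 1e-4 within the ≤ 15
  epoch budget, and the gap widens with more training).  The
  attention-advantage direction seen at full scale is not reproduced at
  this scale, and the corresponding acceptance-style test fails by
  design rather than being weakened.
* Image-level (not subject-level) cross-validation mirrors the study
  design and inherits its leakage caveat.
* The synthetic benchmark's effect direction is stable but its
  magnitude is not informative about clinical data.
* ImageNet-pretrained branch initialization is supported only through a
  user-supplied weights file; no download mechanism exists.
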