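# Methods

## The model

`lesionrefine` implements interactive skin-lesion segmentation as a two-stage,
deliberately decoupled pipeline.

**Stage 1 — box-guided coarse segmentation.** The user draws a *surrounding
box*: a loose rectangle around the lesion, not a tight bounding box. The crop
under the box is resized to the network resolution (`crop_size`, default
96 px, divisible by 16) and passed through a fully convolutional network: a
shared encoder emitting features at stride 4 (shallow) and stride 16 (deep), a
global-context extractor on the deep features, and a decoder that reduces the
shallow channels by 1×1 convolution, bilinearly upsamples the context features
×4, concatenates, refines with a 3×3 convolution, projects to one channel and
upsamples ×4 again. The output `B` is a per-pixel logit map of
lesion-vs-background.

**Stage 2 — click-guided residual refinement.** When the coarse result is
unsatisfactory, the user supplies *positive* clicks (pixels wrongly excluded)
and *negative* clicks (pixels wrongly included). Clicks of each polarity are
encoded as a Gaussian distance channel

    G(m, n) = max over clicks (i, j) of exp(-4 ((m-i)^2 + (n-j)^2) / R^2),

so each channel is 1 at its clicks and decays to e^-1 at distance R/2. The
refinement head consumes the *cached* context features of stage 1 (the encoder
runs exactly once per session) together with the two guidance channels
downsampled to the deep grid, and produces a correction logit map `C`. A
polarity-blind *weight map*

    W(m, n) = sum over all clicks of exp(-4 d^2 / R_w^2),  R_w >> R,

localizes where the correction may act, and the final result is the residual
fusion

    F = W * C + B   (elementwise).

Where no click exerts weight, `F` equals `B` bit-for-bit, so an empty click
set is a strict no-op; each click opens a soft window of radius ~`R_w` in
which the refinement head may override the coarse decision.

### Domain and numerical choices

* `B`, `C`, `F` live in the **logit domain** and are binarized at 0.
  Logits make `W * C` a true additive residual, keep the fusion closed under
  addition, and make the no-click identity exact. Probabilities, when needed,
  are `sigmoid(F)`.
* The click Gaussians are untruncated and evaluated with exact squared
  Euclidean distances in pixels. `W` is not clamped or normalized — repeated
  clicks legitimately raise the local weight, and click-stage training absorbs
  the scale.
* Default radii are `R = 40` and `R_w = 3R = 120` at a 256 px crop, scaled
  linearly with `crop_size` (15 / 45 at 96 px). `R` is sized so that one click
  plausibly covers one mistake region; `R_w` is deliberately much larger so a
  click can adjust the weight of a broad area. Both are exposed under
  `guidance.radius` / `guidance.weight_radius`.
* Coordinates are `(row, col)`, 0-based; boxes are half-open. Clicks are
  stored in crop coordinates and mapped to the network grid with half-pixel
  centring, so sub-stride positions survive the resize.

## Networks

The three learnable parts are written against a two-level feature contract
(strides 4 and 16) behind which any encoder could sit. The packaged encoder
is a compact five-convolution CNN (He-initialized, ReLU, widths 8/16/24/32 by
default) chosen so the whole model stays under 100 k parameters and trains in
minutes on one CPU; the contract is the seam for swapping in a large
pretrained segmentation backbone.

Three interchangeable global-context extractors are provided for the
ablation harness:

* **aspp** — parallel 1×1 and dilated 3×3 convolutions (rates 1, 2) plus a
  global-average-pooled branch, concatenated and 1×1-projected;
* **psp** — average pooling to pyramid grids {1, 2, 3, 6}, per-level 1×1
  projection, bilinear upsampling back, concatenation with the input, 1×1
  projection;
* **naive** — a single 3×3 convolution (the no-global-context baseline).

All forward/backward passes are hand-written NumPy: convolutions via shifted
views and matrix products, and every spatially linear operator (bilinear
resize, adaptive pooling) as a sparse matrix whose transpose is its backward
pass. The backward implementation is validated against central finite
differences in the test suite (float64, biases randomized off the ReLU
kinks, relative tolerance 1e-3).

## Interaction simulation

* **Boxes.** Training boxes are the ground-truth tight box with each edge
  independently shifted by a uniform integer in ±`max_jitter` pixels
  (default 30, the loose-box behaviour of a human annotator at dermoscopy
  scale), clamped to the frame; degenerate draws are resampled so the
  uniform-offset model is preserved. For 96 px synthetic frames the jitter is
  scaled with image size to 6 px. Evaluation uses jitter 0 for deterministic
  reports (a flag restores training-style jitter).
* **Clicks.** Positive clicks are drawn uniformly without replacement from
  the false-negative set of the current prediction, negative clicks from the
  false-positive set — the two mistake classes a user would poke at. A
  training round's budget (default 3) is split between the polarities
  proportionally to the error-set areas (largest remainder, ties to
  positive). Clicks are resampled every pass by default; a flag fixes them
  per object.

## Training

Both stages use momentum SGD (momentum 0.9, weight decay 5e-4, batch 8)
under the poly schedule `lr = base_lr * (1 - iter/max_iter)^0.9` with
`max_iter = epochs × batches-per-epoch`. Stage 1 trains everything with
pixel-wise binary cross-entropy on `sigmoid(B)` at base LR 0.01 (50 epochs by
default; 20 in the desk-scale study). The loss is the conventional choice for
binary segmentation heads. Stage 2 freezes stage 1 bit-exactly, mines the
*hard subset* (objects with coarse IoU < 0.9 under the tight box), and trains
only the click head at base LR 0.1 on the cross-entropy of `sigmoid(F)`;
gradients reach the head through `W * C`, which concentrates learning where
clicks grant weight. Every run is deterministic given `(seed, config, data)`
on a fixed platform.

## Synthetic data

The generator emulates the aspects of dermoscopy that matter to this
pipeline: a skin-toned background (jittered base colour ≈ RGB(205,160,140),
smooth directional gradient, Gaussian noise σ=7), a single darker star-convex
lesion `r(θ) = r0 (1 + Σ a_k sin(kθ + φ_k))` (r0 ∈ [14, 26] px at 96 px, four
harmonics of amplitude ≤ 0.14) whose pigment *fades radially* over a rim of
1–9 px, and — with probability `artifact_prob` — a distractor: a
lesion-coloured blot placed near (never touching) the lesion, or a hair-like
streak occluded outside the annotation. The mask is the exact analytic blob
interior before any blurring, so ground truth is crisp while the image has
soft edges, the way human annotations relate to the photographs.

The design is deliberately adversarial in the two ways the refinement stage
exists to fix: faded rims produce false negatives (positive clicks), nearby
dark blots produce false positives (negative clicks). Star-convexity
guarantees a single connected, hole-free component, and distractors never
darken annotated pixels, so every distractor-induced error is a false
positive by construction.

What the generator does **not** emulate: real pigment network texture,
multi-lesion scenes, specular highlights, rulers/gel artifacts, colour
calibration differences between clinics. Passing the synthetic study shows
the pipeline's mechanics work end to end — it does not certify clinical
accuracy on real dermoscopy, which requires the real datasets this package
can also consume (PNG images + 0/255 masks).

## Evaluation

Metrics are pixel-wise accuracy, sensitivity, specificity, Dice and IoU from
the confusion counts of the binarized prediction against ground truth,
computed over the cropped region at its native resolution — the region both
stages actually operate on. Ratios with zero denominators are reported as
undefined (NaN, empty CSV cells), never coerced to 0, so dataset means are
not corrupted. `dic = 2·iou/(1+iou)` holds as an exact identity.

Protocols:

* **fixed-budget evaluation** — per sample: coarse pass, then one fused
  refinement with the click budget sampled from the current errors (default
  2 clicks, the single-pass reading of a fixed-budget comparison);
* **clicks-to-target** — the surrounding box is accounted as 2 clicks, then
  one click per refinement step (polarity of the larger error set) until the
  target IoU or the click cap; capped samples are *censored*: counted at
  `2 + max_clicks` and flagged separately rather than silently averaged;
* **ablation harness** — identical data and seeds across the three context
  variants, reporting coarse and optionally refined IoU per variant.

## Desk-scale study sizes

The packaged experiment (also what `scripts/acceptance.py` runs) uses 300
synthetic 96 px samples (artifact probability 0.5), a 200/100 train/test
split, 20 coarse epochs, click training for 10 epochs on the mined hard
subset, and an 8-epoch ablation on 100 training samples — sizes chosen so the
whole study runs in about a minute on one CPU while leaving a non-trivial
hard subset (~25 % of samples) for the refinement stage to improve.
Improvement is reported on the hard samples of the *held-out* split.

## Known limitations

* The packaged encoder is small by design; absolute IoUs on real dermoscopy
  would require a pretrained backbone behind the stride-4/16 contract.
* The refinement head decodes from the stride-16 grid, so a single click
  cannot sharpen details much finer than the deep-feature stride; the weight
  map, computed at full crop resolution, restores most but not all locality.
* Censored clicks-to-target samples make the reported mean an underestimate
  of the true interaction cost at high targets.
* Whether a fixed 2-click budget should be spent in one fused pass or one
  click at a time is ambiguous in interactive practice; both are implemented
  (single-pass default for the fixed-budget report, per-click for sessions
  and clicks-to-target).
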