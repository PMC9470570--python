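# Methods

`endoattn` implements an end-to-end pipeline for classifying benign versus
malignant gastric-ulcer lesions on digestive-endoscopy frames: classical
image cleaning, an Xception convolutional backbone augmented with residual
attention modules ("Xception-RA"), imbalance-aware training, and a
five-metric evaluation harness. Because clinical endoscopy datasets of this
kind are access-restricted, the package ships a synthetic-frame generator
that emulates the structure of such images with exact ground truth, so every
stage is testable end to end.

## Frame preprocessing

An endoscopy frame divides into an irrelevant annotation area — near-black
strips added by the device, carrying timestamps and device info — and the
tissue region of interest (ROI). Inside the ROI, two kinds of pixels carry
no diagnostic information: *dark regions* (poorly illuminated tissue) and
*reflective regions* (specular glare from digestive-tract liquid).

**ROI detection.** The luminance image is filtered with the 3×3 Sobel
operator (replicate-padded borders); pixels whose gradient magnitude
exceeds half the frame maximum vote in a Hough transform restricted to
near-vertical and near-horizontal lines (±2° by default). The strongest
line on each side of the frame centre that clears the vote threshold
(default: half the relevant frame dimension, since device borders span the
frame) becomes that side's ROI boundary; a side with no qualifying line
falls back to the frame edge, so border-free images pass through uncropped.
The half-maximum edge threshold matters: the annotation-border step is by a
wide margin the strongest gradient when present, while in-tissue texture
can otherwise accumulate enough aligned weak edges to fabricate a boundary.

**Interference masking.** Masks are computed in HSV with S and V scaled to
0–255. A pixel is *dark* iff V < 80 and *reflective* iff S < 90 **and**
V ≥ 200. The value floor is our addition: low saturation alone would flag
pale but diagnostically fine tissue, and because the floor exceeds the dark
threshold the two masks are disjoint by construction. All three thresholds
are configurable.

**Cleanup and fill.** Both masks undergo iterated morphological opening
(disc element, radius 2, 3 cycles by default) followed by removal of
8-connected components below 64 px. Opening can only shrink a mask, so
cleanup never invents interference. Flagged pixels are then replaced by the
per-channel median of the clean ROI pixels (`median_of_roi`); a `zero` fill
mode exists but re-creates artificial dark regions, hence is not the
default. The full pass is idempotent in practice: re-running it on its own
output changes well under 1 % of pixels.

## The Xception-RA network

### Backbone

The backbone organises 36 convolutional layers into 14 modules across
entry, middle and exit flows of 4, 8 and 2 blocks:

| blocks | flow   | structure |
|--------|--------|-----------|
| 1      | entry  | two unpadded stride-2 3×3 convolutions (stem) |
| 2–4    | entry  | 2 separable convs + ceil-mode 3×3/2 max-pool; stride-2 1×1-conv shortcut |
| 5–12   | middle | 3 separable convs, identity shortcut, size-preserving |
| 13     | exit   | downsampling block as in the entry flow |
| 14     | exit   | 2 separable convs, no residual |

Every module except the first and last carries a residual connection. Each
separable convolution is a depthwise 3×3 followed by a pointwise 1×1, with
batch normalisation and ReLU as in Xception; the classifier head is global
average pooling into a single linear layer. Default channel widths are the
public Xception plan (64/128/256/728 entry, 728 middle, 1024/2048 exit);
`ChannelPlan.small()` provides a desk-scale variant for tests.

At the default input side of 441 px the per-block spatial sides are

```
109, 55, 28, 14, 14 ×8, 7, 7
```

The stem convention (two *unpadded stride-2* convolutions, ceil-mode
pooling) is the one simple convention that reproduces these sizes; it is
applied uniformly at every input side. `forward_shapes` computes the chain
analytically and the test suite confirms it against an actual forward pass.

### Residual attention

An attention module splits its input x into a **trunk branch** T(x) — one
middle-flow block — and a **soft mask branch** M(x): n stages of max-pool
downsampling interleaved with middle-flow blocks, mirrored by
nearest-neighbour upsampling stages with skip connections between matching
scales, then two 1×1 convolutions and a sigmoid. The combination is

```
H(x) = (1 + M(x)) · T(x),        M(x) ∈ (0, 1)
```

so the mask can amplify informative features but never erase the trunk
signal (M = 0 is an exact identity on T). Because M is computed from x and
not from T's parameters φ, the mask also filters gradient updates:
∂(M·T)/∂φ = M · ∂T/∂φ, which the test suite verifies by finite differences.

Modules embed after blocks 2, 3 and 12 by default (local map sides 55, 28
and 14). Each module's downsampling depth is derived so its coarsest
internal map matches the smallest feature map in the network (7 px at the
default input): 3, 2 and 1 stages respectively. All four placement variants
(2&3&12, 4&12&13, 6&8&10, 4&8&12) are constructible; when a local side
already equals the network minimum, one downsampling stage is used, since a
bottom-up/top-down branch needs at least one. The mask-branch
micro-structure (one middle block per scale, two 1×1 convolutions, sigmoid)
follows the original residual-attention design; only the trunk replacement
and the downsample counts are constrained by the architecture itself.

### Numerical engine

The network runs on a compact float64 reverse-mode autograd engine written
on numpy (`endoattn.nn`): convolution and pooling are expressed as nine
slice extractions feeding batched matrix products, batch normalisation and
the softmax cross-entropy carry hand-derived backward passes, and the
sigmoid is evaluated in its numerically stable split form (so extreme
logits saturate cleanly to 0.0/1.0 instead of overflowing). Every operator
is finite-difference-tested to ~1e-9 relative error. Parameters use
He-normal initialisation drawn in registration order from a seeded
generator, which makes structurally identical networks with equal seeds
share weights exactly — the property the trunk-equivalence tests rely on.

## Imbalance-aware training

**Weighted cross-entropy.** Per sample, `loss = W_class · (−x_class +
log Σ_j e^{x_j})`, reduced by a plain mean over the batch. Printed
statements of this weighted loss sometimes carry an extra leading minus,
which would make it negative and untrainable; the standard non-negative
convention is implemented. Default weights are inverse class
frequencies, mean-normalised: `W_c = total / (K · n_c)` — for a 109 / 69
cohort this gives (0.8165, 1.2899). Weights are overridable.

**Label shuffling.** With N the largest class size, each class's shuffled
record list is indexed by `i mod n` for i = 0..N−1; the per-class lists are
concatenated and reshuffled. Every epoch therefore reads K·N samples with
exact class balance, each record appearing ⌊N/n⌋ or ⌈N/n⌉ times. The order
is re-drawn each epoch from `seed + epoch`, so runs are reproducible and
the single-list behaviour is recoverable by fixing the epoch.

**Optimisation.** Adam with learning rate 0.02, β₁ = 0.89 (the stated
"momentum"), β₂ = 0.999, coupled L2 weight decay 5e-4, batch size 8.
Splits are patient-level (default 70/15/15 by patient count, seeded):
patients contribute 2–6 images each, so image-level splitting would leak.

**Batch-norm recalibration.** After each epoch the running statistics of
every normalisation layer are recomputed as the arithmetic mean of batch
statistics over the training set. With only tens of optimizer steps the
exponential moving averages still carry their initialisation, and in a
50-layer normalised stack that mismatch compounds until eval-mode
inference is useless even though the training loss has converged; the
refresh pass makes eval-mode behaviour consistent at any training length.

## Evaluation

Malignant (class 1) is the positive class. From TP/FP/TN/FN: accuracy,
precision TP/(TP+FP), sensitivity TP/(TP+FN), specificity TN/(FP+TN), and
F1 as the standard harmonic mean 2PS/(P+S) — printed variants of the F1
formula occasionally show a product where the harmonic mean requires a sum
in the denominator; the standard form is implemented.
Zero-denominator metrics are returned as an explicit undefined marker with
a warning — never silently 0 — with a strict mode mapping them to 0.
Inference is deterministic (eval mode, argmax); metrics are image-level by
default with a patient-level majority-vote option (ties break toward the
malignant call). The learning-curve harness retrains from scratch at
increasing patient counts — subsampled with class stratification, since a
patient carries a single diagnosis — and evaluates each run on one fixed
held-out partition.

## Synthetic frames

The generator paints, per frame: near-black annotation strips (value ≈ 18)
with 2 % bright glyph speckle; a tissue ROI as a multiplicative texture
over a fixed reddish base colour; hard-edged dark discs whose maximum
channel equals the requested value level (< 80); and specular discs with
V ∈ [218, 246] and S ≈ 15. Multiplicative texture preserves HSV saturation,
so clean tissue (S ≈ 113) can never trip the reflective rule, and the
modulation is clipped so clean tissue stays above the dark threshold.
Class 0 is a smooth low-frequency mottling; class 1 is high-frequency
granular texture plus an irregular bright annulus (a crude ulcer-rim
analogue) — separable by a threshold on mean local roughness (> 90 %
accuracy on 100 frames) yet not by mean intensity alone. Dark and specular
discs are placed disjointly, so ground-truth masks never overlap. All
output is a pure function of (spec, seed).

What the generator does *not* model: vignetting and uneven illumination
gradients, soft specular halos, motion blur, mucus strands, pathology
subtypes, or any realistic lesion morphology. Passing tests therefore
demonstrate that the pipeline recovers planted structure under controlled
conditions and that the architecture trains and evaluates correctly — not
clinical performance. The study's headline clinical numbers require the
restricted hospital dataset and are out of scope here.

## Problem sizes used in the checks

Structural checks run at the default 441-px configuration (shape chain,
downsample counts, module counts). Behavioural checks run at desk scale:
128-px inputs with reduced channel widths, 256-px generated frames with
28-px borders, 50 frames for the preprocessing-recovery rates, 16 frames /
15 epochs for the overfit smoke test, and 1000 random logit vectors for
the loss oracle. These sizes exercise every code path while keeping the
full suite under a minute of compute.

## Known limitations

- The engine is CPU/numpy; it is meant for correctness and desk-scale
  experiments, not for training full-width 441-px models.
- Nearest-neighbour upsampling in the mask branch is blocky; the original
  residual-attention design used bilinear interpolation.
- No augmentation, learning-rate schedule, or early stopping — none are
  part of the described procedure.
- The Hough detector assumes axis-aligned device borders; rotated or
  curved vignettes fall back to the full frame.
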