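# Methods

## Data model and partition protocol

Every image is a manifest record `(id, path, class, split, provenance,
source_id)` with provenance one of `original | augmented | gan |
filtered`. Counts are always recomputed from records, never cached.

The partition protocol is asymmetric on purpose:

1. **Hold-out first.** Per class, `round_half_away(n · test_fraction)`
   original images are marked `test` (seeded shuffle over a
   lexicographically sorted file list, so the draw is identical across
   platforms). At the default geometry (8 × 500, fraction 0.2) every
   quota is an exact integer: 100 test per class, 800 total.
2. **Augment the pool only.** The 21-transform policy applied to the
   3,200-image pool yields 67,200 augmented images; the corpus available
   for training is pool + derived = 70,400. The reported "total after
   augmentation" (and the per-class 8,800) deliberately *excludes* the
   test hold-out; `split_summary` also reports the all-inclusive total
   (71,200 at full scale) to avoid ambiguity.
3. **Split after augmentation.** Stratified 80/20 over pool ∪ augmented
   (∪ gan): 56,320 train / 14,080 val; 7,040/1,760 per class.

`verify_isolation` is a report-only audit: duplicate ids, derived
records sourced from test images, and label drift between a derived
record and its source all fail it. Filtered renderings inherit their
source's split (a CKPF rendering of a test image is still test data);
only `augmented`/`gan` provenance in the test split counts as leakage.

## Augmentation policy

Three transform families — horizontal flip (column reversal), vertical
flip (row reversal), rotation about the image center (positive =
counter-clockwise, 0-based row-major coordinates). The canonical policy
is the 7 angles {45°, 90°, …, 315°} in three flavours (plain,
hflip-then-rotate, vflip-then-rotate): 3 × 7 = 21 non-identity transform
specifications, giving exactly 21 variants per pool image.

Two numerical regimes: multiples of 90° with nearest interpolation are
exact pixel permutations (histogram-preserving, used for the permutation
oracles); other angles use bilinear resampling with reflect padding,
output cropped to the source size so tensor shapes stay uniform.

A caveat worth knowing: as *geometric maps*, vflip-then-rotate(θ) equals
hflip-then-rotate(θ−180°), so 6 of the 21 entries duplicate others
pixel-wise. The policy is defined at the transform-specification level
(21 distinct entries, the count the protocol fixes), not as a claim of
21 pixel-distinct outputs.

## Filter bank

- **Grayscale.** Default mode applies the literal two-stage weighting
  (each 8-bit channel scaled by the classic luminance weights
  (0.2989, 0.5870, 0.1140)/255, the results recombined with weights
  (0.3, 0.59, 0.11)). This maps white to 0.44854 rather than 1.0 — an
  unusual choice preserved deliberately as the default, with
  single-stage ITU-601 luminance available as `standard`. Modes are
  never mixed within a run.
- **Sobel.** 3×3 cross-correlation kernels, reflect borders, magnitude
  `sqrt(Gx² + Gy²)` rescaled to [0,1] by a recorded scale factor.
- **Canny.** scikit-image's implementation (Gaussian σ=1, non-max
  suppression, hysteresis); the low/high thresholds are supplied as
  fractions (defaults 0.1/0.3) of the maximum smoothed-gradient
  magnitude, so they are relative to image contrast.
- **Harris corners.** Structure tensor from Sobel gradients, Gaussian
  window σ=1, response `det(M) − k·trace(M)²` with k=0.04; keypoints are
  positive responses ≥ 0.01 × max response after 3×3 non-maximum
  suppression. Tests hold the detector equal to a fully loop-based
  brute-force implementation on all toy matrices. Note the scale limit:
  on a ≤9×9 toy the σ=1 window merges nearby corners (a 3×3 block reads
  as one blob); the four-corners-of-a-square and six-corners-of-an-L
  behaviours are exercised at 64×64 where the geometry resolves.
- **CKPF rendering.** `α·gray` everywhere (α=0.3), with disks of radius
  3 px around each keypoint restored to full intensity and multiplied by
  `1 + boost·ρ` (boost=0.5, ρ = response normalized to the image
  maximum), clamped to [0,1]. α=1, boost=0 is the identity. This is the
  classifier's default single input channel.
- **Kernel isolation.** 3×3 Laplacian high-boost (center 9, neighbours
  −1; kernel sums to 1 so constants pass through), reflect borders,
  clamped to [0,1]; a milder `sharpen` kernel is available.

## DCGAN

One unconditional GAN per class, so samples carry their class label by
construction. Generator: latent z ~ N(0, I), D=100 → dense to a 4×4 map
→ stride-2 4×4 transposed convolutions (batch norm + ReLU per stage,
channels halving from `base_channels · 2^(stages−1)`) → tanh.
Discriminator: stride-2 4×4 convolutions (LeakyReLU 0.2, batch norm
after the first stage) down to a 4×4 penultimate feature map → dense →
sigmoid. `stages = log2(image_size) − 2`.

Losses: `loss_D = BCE(real→1) + BCE(fake→0)`;
`loss_G = BCE(fake→1) + λ‖mean(real_feats) − mean(fake_feats)‖²` with
λ=1 on the penultimate discriminator features (real features treated as
constants). Training: alternating one D-step and one G-step per batch,
AdamW (lr 1e-4 generator / 5e-4 discriminator, betas (0.5, 0.999)),
cosine annealing over the scheduled steps, He-normal init, batch size
64, default 300 epochs at full scale. Checkpoints are `.npz` weights
with a JSON sidecar (spec, seed, epoch) and reload to bit-identical
samples.

Defaults chosen where the protocol is silent: latent 100, base channels
64, LeakyReLU slope 0.2, GAN resolution 64×64 (configurable; 256 is
impractical on one CPU core). Batch norm lives in the GAN, instance
norm in the classifier stem (the "hybrid" normalization split). How
many GAN images enter classifier training is a free parameter
(`gan_per_class`, default 0 — the 21× geometric augmentation alone
reproduces the documented counts).

## Atrous-context classifier

Input (default): one CKPF channel at 64×64 (32×32 in the desk-scale
demos). Architecture: 3×3 stride-2 stem conv to 32 channels + instance
norm + ReLU → optional **pre-context block** → dilated stack → optional
**post-context block** → global average pool → dropout 0.3 → dense →
softmax (rows sum to 1 within 1e-6).

A context block is: global average pool (per channel, 1/(H·W) Σ fm) →
1×1 convolution **without nonlinearity** (on a pooled 1×1 map this is a
dense C→C map, which is how it is stored) → broadcast-add onto the
input. With the kernel pinned to identity and zero bias, a constant
input c yields 2c — the hand-check used in tests. The 1×1 kernels are
trainable (a frozen all-ones kernel would make the block dead weight).

The dilated stack is *sequential*: three 3×3 convolutions at rates 2, 4,
6, same-padding equal to the rate, Swish activations, 32→64 then 64→64
channels; the three stage outputs are fused by element-wise addition and
projected by a 1×1 convolution. Receptive field 1 + (2+4+6)·2 = 25 px. A
parallel-branch fusion mode exists for comparison. Toggling the context
blocks changes the parameter count by exactly C²+C each — the ablation
arithmetic tests rely on this closed form.

Training: softmax cross-entropy, AdamW (betas (0.9, 0.999), weight decay
1e-5 on conv/dense weights only), cosine annealing over the full run,
seeded end-to-end (two runs with equal seeds give identical loss
curves). With a validation set the best-val checkpoint is kept.

## Evaluation harness

Confusion matrix rows are true classes. Per class: precision TP/(TP+FP),
recall = sensitivity TP/(TP+FN) (both names reported because the
reporting convention prints them as separate columns), specificity
TN/(TN+FP), F1 as the harmonic mean, IoU TP/(TP+FP+FN) — the standard
multi-class Jaccard reading for a classifier. Macro values are
unweighted class means; zero-denominator cells are reported as 0 with a
flag. All proportions are percentages.

The failure table's totals row averages the *per-class* error rates
(unweighted); this is the convention the reference tables use, and it
differs from aggregate misclassified/total (1.38 vs 3.125 on the
documented 25/800 case) — both numbers are emitted, the aggregate as a
table attribute.

`FoldStats` reports per-fold values, mean, sample SD (ddof=1) and two
95% CIs: Student-t (df=k−1) and normal multiplier, labeled. The printed
reference interval [99.78, 99.82] arises from the *rounded* mean/SD
(99.80 ± 1.96·0.02/√5); the exact-value intervals round to [99.79,
99.82] (normal) and [99.78, 99.83] (t). Similarly, the reference
t-statistics (≈55) are not recoverable from the printed fold accuracies
— the standard paired-t formula on those values gives a much larger t —
so `paired_ttest` follows the standard formula (cross-checked against
scipy and a closed form to 1e-9) and the discrepancy is simply noted.
Zero-variance differences are flagged degenerate rather than infinite;
p-values below 1e-4 format as "< 0.0001".

`kfold_cv` folds only the non-test pool (how k-fold interacts with a
fixed hold-out is otherwise underdetermined; refolding the pool keeps
the hold-out pristine). Classes with fewer than k members are an error.

## Synthetic fixtures: what they do and do not show

The fixture generator emulates the *structure* of the real task — eight
balanced classes, RGB images, distinct shape/texture per class, nuisance
jitter in position, scale (±20%) and brightness (±0.1) — with fixed
per-class families so fold experiments are comparable, and full
determinism (equal spec ⇒ byte-identical PNGs; per-image RNG seeded by
(seed, class, index)). It does **not** emulate photographic nuisance:
lighting fields, backgrounds, occlusion, intra-class morphology. Passing
the suite therefore demonstrates that the pipeline's bookkeeping, losses,
gradients and end-to-end mechanics are correct and that the architecture
can learn separable visual classes — not that the headline real-data
accuracy transfers.

## Problem sizes and numerical choices

Chosen as the package's desk-scale defaults: fixtures 64×64 (demos
32×32); the partition-arithmetic checks run records-only at the full
8×500 geometry; the end-to-end demo trains on 8×50 fixtures (5,632 train
images after augmentation) for 8 epochs with lr 3e-3, batch 64 and
32-channel dilated stack, reaching ≳90% held-out fixture accuracy; the
overfit smoke uses 8×16 images, lr 1e-2, batch 16, ≤50 epochs; the GAN
smoke uses base 16 channels at 32×32 for 200 alternating steps. All
arrays are float32; BCE clips probabilities to [1e-7, 1−1e-7]; softmax
subtracts the row max; AdamW uses eps 1e-8; dropout is inverted-scaled
and seeded. Ties in Harris non-max suppression resolve to all co-maximal
pixels (then threshold); keypoints sort by descending response.

## Known limitations

- CPU-only engine: full-scale (8×500, 64×64, 300-epoch GAN) training is
  out of desk reach; the defaults reproduce the protocol, not the
  reference accuracy numbers.
- The CKPF construction (attenuate-and-boost) and the "kernel isolated"
  filter are concrete instantiations of loosely specified renderings;
  both are parameterized so alternatives can be swapped in.
- `ingest_directory` assumes one subdirectory per class and does not
  deduplicate across datasets.
- The per-class GAN never conditions on label; class purity of synthetic
  images is by construction, not by a classifier check.
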