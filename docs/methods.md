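# Methods

## The problem

High-dimensional tabular data — bulk or single-cell expression matrices,
proteomics panels, any observations × features table — is usually attacked
with aggressive feature selection and dimension reduction before modelling.
That preprocessing throws away small perturbations that may be exactly the
signal of interest. `deepmapper` takes the opposite route: keep every
feature, fold each observation's feature vector into a small image in which
**one pixel encodes one feature**, train a 2-D convolutional network on those
pseudo-images, and then ask the trained network which pixels (hence which
features) its correct decisions depended on.

Because the pixel ↔ feature map is an explicit bijection, attribution scores
translate back to named features with single-feature resolution — there is no
"this image region corresponds to several genes" ambiguity.

## Folding and normalisation

Given `F` features, the fold geometry is the smallest square: side
`m = ceil(sqrt(F))`, with the trailing `m² − F` pixels fixed at zero
(e.g. 19,319 features → 139 × 139 with 2 padding pixels; 18,225 → 135 × 135
exactly). Filling is row-major in the table's column order, or in the order
given by an optional two-column index file (`feature_name, rank`). The
inverse map (`pixel_to_feature`) is exact, and padding pixels are excluded
from every ranking.

Before folding, each feature is log-normalised independently:

1. shift by `−min` if the column minimum is negative;
2. `x ↦ ln(1 + x)` (keeps 0 at 0, compresses the right tail typical of
   count-derived data);
3. min–max rescale to [0, 1]; constant columns map to all zeros.

The transform is monotone per feature, so within-feature ranks survive.
Normalisation statistics are computed on the full dataset before the
train/test split. That is a deliberate, documented trade-off: the pipeline
normalises → folds → splits, and the per-feature min/max leak only marginal
distributional information. Users who need strict separation can split
upstream.

The only filtering is removal of observations or features that are entirely
zero (empty cells are read as 0). No variance filter, no imputation, no
dimension reduction — preserving "noise" is the point.

## The synthetic benchmarks

**Needle-in-a-haystack (NIHS).** The generator emulates the benchmark used
to validate the approach: by default 10,000 observations × 18,225 features,
all cells i.i.d. Uniform[0, 1) except two planted features whose values are
drawn from class-conditional sub-ranges:

| feature  | class-0 range | class-1 range |
|----------|---------------|---------------|
| 20       | [0.00, 0.20)  | [0.20, 0.40)  |
| 17,998   | [0.10, 0.20)  | [0.25, 0.35)  |

Intervals are half-open so adjacent class supports stay disjoint at the
shared endpoint. Class labels are balanced (the class split is configurable);
everything is reproducible from one seed. Because both planted features have
disjoint class-conditional supports, a single threshold on either is a
perfect classifier — an exact oracle for every downstream recovery test.
What NIHS does **not** emulate: feature correlations, batch structure,
heavy-tailed marginals, label noise — all ubiquitous in real omics data. A
passing recovery test therefore shows the machinery works end-to-end under
ideal noise, not that real datasets will be as clean.

**Toy patterns.** Class-specific bright rectangles plus Gaussian noise,
clipped to [0, 1]. They exist to exercise the trainer and the pixel-shuffle
property quickly; they are not a stand-in for natural images.

**Pixel shuffles.** One seeded flat-position permutation applied identically
to every image, with the permutation returned for exact inversion. A CNN's
accuracy should survive such a shuffle almost unchanged — spatial structure
in pseudo-images is arbitrary anyway, which is the core reason direct folding
works at all.

## The network

A compact residual CNN implemented directly on numpy arrays (im2col
convolutions, explicit backward passes, verified against central finite
differences in the test suite; Adam optimizer; float32 working precision).
Two registered configurations:

- `resnet18` — the classic 18-layer stack (widths 64/128/256/512, two blocks
  per stage, stride-2 stem); the default for full-size runs.
- `small` — an 8-layer variant (16/32/64, one block per stage, stride-1
  stem) for desk-scale images up to ~40 px.

Design points that matter:

- **Adaptive global average pooling** before the linear head makes one
  weight set valid for any side ≥ 16, so 135 × 135 and 139 × 139 inputs run
  through the same code path.
- **Coordinate channels.** Two fixed channels (row and column position,
  scaled to [−1, 1]) are concatenated to the input. Pseudo-images have no
  translation invariance to exploit — each feature lives at one fixed
  pixel — and a purely convolutional stack can sense absolute position only
  through boundary padding. The coordinate channels hand position to the
  first convolution directly, which is what lets the network single out
  individual informative pixels efficiently.
- **Batch normalisation** with running statistics; inference and attribution
  run in eval mode (frozen statistics), so attribution maps are
  deterministic functions of the trained weights.
- Downsampling is by strided convolution (classic); a 2 × 2 average-pool
  alternative (`downsample="pool"`) exists for experimentation but trained
  measurably worse on the needle benchmark and is not a default.

## Training protocol

One *iteration* = stratified seeded split (held-out fraction 0.375 by
default, reproducing a 3,750-sample held-out set from 10,000) → fresh
initialisation → up to `epochs` epochs of Adam (lr 1e-3, batch 32,
cross-entropy), stopping early once held-out accuracy reaches
`accuracy_target` (default 0.95; training past a good fit mostly buys
overfitting) → attribution of the correctly classified held-out samples.

Iterations repeat with different derived seeds until the best held-out
accuracy changes by less than `convergence_tol` (default 0.005) between two
successive iterations *and* the accuracy target has been met, or
`max_iterations` is hit. A tolerance ≥ 1 is treated as "convergence checking
disabled": the run stops after two iterations regardless. Every stochastic
stage draws its seed as `sha256(seed/iteration/stage)`, so one user-facing
seed fixes the whole run, and split membership differs across iterations by
construction.

## Attribution

Two methods, both gradient-based, both computed in eval mode on held-out
samples the model classified correctly (a wrong prediction's gradients
explain the mistake, not the class):

- `saliency` — the input gradient of the true-class **logit contrast**
  (logit minus the mean of the other logits).
- `integrated-gradients` (default) — the path integral of that gradient from
  an all-zero baseline, approximated with a 16-point midpoint Riemann sum,
  times the input.

The contrast target, rather than the raw logit, is deliberate: under softmax
only logit *differences* drive the decision, and raw-logit gradients carry
evidence shared by every class that cancels in the decision but would
pollute the maps. Only the image channel's gradient is used; coordinate
channels receive attribution but are not features.

Per class, the element-wise mean of **absolute** attributions is accumulated
(absolute values prevent sign cancellation across samples), pooled across
iterations with equal weight per sample. Classes with no correct sample
yield an all-zero matrix and are flagged. Rankings sort features by mean
score descending, ties broken by ascending feature index (deterministic).

Besides the per-class rankings, an **overall** ranking (class code −1) uses
the per-pixel maximum of the per-class means. The max, not the mean, is the
right aggregate here: integrated gradients from a zero baseline scale with
input intensity, so a marker whose in-class values sit near the baseline
(e.g. a feature confined to [0.0, 0.2) in one class) is visible almost
exclusively through the *other* class's maps; count-weighted averaging would
dilute exactly the class-specific markers the method exists to find.

Known limitation: convolutional weight sharing leaks a small amount of
attribution onto pixels that share downsampling phase or receptive fields
with a truly informative pixel ("gradient clutter"). The contrast target and
correct-samples-only rule reduce it; it does not vanish. At desk scale the
planted features clear the clutter by a wide margin, but on real data the
tail of a ranking should be read with this in mind.

## Problem sizes used by the test suite

The suite exercises the full-size NIHS generator (10,000 × 18,225) but
trains at desk scale, chosen so the whole pipeline remains a few minutes of
CPU: needle recovery on 2,000 × 1,024 (32 × 32 images, planted features 20
and 998, five epochs, two iterations, `small` backbone) and shuffle
invariance on 1,000 toy images at 28 × 28 (four epochs each arm, early
stopping disabled so both arms train identically). The full 18,225-feature
recovery is the same code path and runs unattended in a few hours.

## Numerical and degenerate-input choices

- Conv/BN/linear backward passes are finite-difference-verified; training is
  float32, attribution accumulates in float64.
- Non-finite inputs are rejected with the offending cell named; a loss that
  becomes non-finite aborts with epoch and learning rate.
- Vacuous datasets (all-zero after filtering), single-class label sets,
  degenerate split fractions, unknown architectures and unknown attribution
  methods raise immediately with the supported options listed.
- Model checkpoints are numpy `.npz` archives saved under a content-addressed
  filename; reports carry a SHA-256 manifest of every artifact.
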