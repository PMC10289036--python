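# Methods

## Problem and model

The task is multi-class fruit detection in cluttered scenes: locate every
blueberry in an RGB image and classify its ripeness (ripe / semi-ripe /
unripe), under occlusion between berries, varying light and defocus blur.
The detector is a single-stage anchor-based network. An image is divided
into grids at four strides (4, 8, 16, 32; grids 152/76/38/19 at the native
608×608 input); each grid cell carries three anchor priors per level and
predicts, per anchor, box offsets `(tx, ty, tw, th)`, an objectness logit
and three class logits. Decoding follows the YOLOv5 convention:
centre `= (2σ(txy) − 0.5 + cell) · stride`, size `= (2σ(twh))² · anchor`.
The extra stride-4 level exists because the median berry is small relative
to the frame; at stride 8 and coarser, neighbouring berries collapse into
the same cell.

Architecture choices the reconstruction had to make where the upstream
description is silent:

- **Channel schedule.** No channel table is published for the lightweight
  detector; we use base widths (32, 64, 128, 256, 512) for stem/P2–P5 with
  CSP-MobileNet blocks of depth (2, 3, 3, 2), an SPPF tail, and symmetric
  PAN neck blocks of depth 2. All widths scale with `width_multiple`.
  This lands at 11.07 M parameters against the published 13.1 M — the
  comparison point is a ±20 % band, since any schedule consistent with the
  block diagram is plausible.
- **MSSENet internals.** Only the multi-scale sum and the dual-pooling gate
  are specified. We implement the 3/5/7 convolutions dense and
  channel-preserving (the literal reading) and cap head inputs at 128
  channels with a 1×1 reduction before the block: dense 3/5/7 convolutions
  at 512 channels would alone cost ~22 M weights, irreconcilable with the
  published total. The FC reduction ratio defaults to 16 (squeeze-excitation
  convention), lowered automatically for narrow toy widths.
- **Little-CBAM.** Channel stage: shared 1-D convolution (kernel 3,
  ECA-style) over the channel axis applied to both the average- and
  max-pooled descriptors, summed, sigmoid. Spatial stage: 3×3 convolution
  with dilation 2 and padding 2 on the concatenated channel-mean/max maps.
  A single 3×3 dilation-2 kernel spans a 5×5 window, not 7×7; we implement
  the stated construction as-is and note the discrepancy rather than
  "fixing" it. Insertion point is immediately after the bottleneck's channel
  expansion, where the feature space is widest.
- **Baseline.** The reference YOLOv5x is built in the v6-generation layout
  (6×6 stem, C3, SPPF) because its published profile (86.7 M params,
  205.7 GFLOPs at 640; 7.2 M/16.5 G for the s-variant) belongs to that
  generation. Our reconstruction measures 86.75 M / 205.4 G; FLOPs count
  2 per conv/linear multiply-accumulate and zero for BN, activations,
  pooling and upsampling, the convention behind such tables.

## Losses and assignment

Box term: EIoU, `(1 − IoU) + ρ²/c² + Δw²/c_w² + Δh²/c_h²`, with ε = 1e-9 in
every denominator; CIoU (`(1 − IoU) + ρ²/c² + αv`, α treated as a constant
in the gradient) is retained as the ablation baseline. On equal-sized boxes
both reduce to DIoU (asserted in tests). Targets are assigned by the
shape-ratio rule (anchor/box side ratios all < 4) to the centre cell and its
two nearest neighbour cells; objectness targets are the detached IoU of the
decoded box (zero elsewhere), class targets one-hot with binary
cross-entropy. Components are weighted (box 0.05, obj 1.0, cls 0.5 by
default; the toy recipe raises box to 0.1) and objectness is balanced per
level (4, 1, 0.4, 0.1) finest-first.

## Anchor clustering

k-means++ under IoU distance: distance `A(x) = 1 − IoU(x, c)` on size-only
boxes co-anchored at the origin; seeding probability `O(x) = A(x)²/ΣA(x)²`
(roulette wheel); Lloyd iterations with arithmetic-mean centre updates until
the assignment stabilises (cap 300); empty clusters are re-seeded from the
farthest sample. Because the mean update is a heuristic for the IoU
objective (the partition-optimal solution need not be one of its fixed
points — we verified instances where it is not), `cluster_anchors` runs
`restarts` independent seedings (default 10) and keeps the lowest total IoU
distance. The default anchor table ships one 12-anchor group per ripeness
class; a standard single head consumes one shared set, so the per-class
groups are exposed as data and via `bby anchors --per-class` reporting only.

## Synthetic scenes: what they emulate and what they do not

Scenes place clusters of shaded ellipses (radial gradient + specular
highlight, mild per-berry colour jitter) on a low-frequency green-mottled
background. Class-conditional appearance follows the field description:
ripe = dark purple and dim, semi-ripe = red/lavender and bright, unripe =
green and very bright. The three interference factors map to controlled
degradations:

- fruit density → maximum allowed pairwise box IoU during placement:
  very_sparse 0.0, normal 0.30, tightly_arranged 0.70 (the source strata are
  qualitative; these caps are a declared convention);
- light intensity → luminance scaling (backlighting ×0.55·level down,
  strong light brightening/washout up);
- shot clarity → Gaussian blur (σ = 3·level px; levels 0/0.45/0.9).

Ground-truth boxes are amodal (full berry extent, including occluded parts),
matching how clustered fruit is usually hand-labelled. Generation is
bit-deterministic given the config seed.

What passing tests on these scenes shows: the pipeline (data → anchors →
detector → loss → training → evaluation) is wired correctly, the task is
learnable from colour/shape cues, and accuracy degrades monotonically with
occlusion density. What it does not show: performance on real orchard
images — real berries have waxy bloom, leaves and stems as distractors,
perspective scale variation and labelling noise, none of which are modelled.

## Training recipe and problem sizes

Full-scale defaults follow the reference protocol: SGD with momentum 0.9,
initial learning rate 0.001, weight decay 0.0005 (applied to conv/linear
weights only), cosine decay. Verification runs use the package's toy
configuration (`bbyolo.toy`): 64-px scenes with 4–16 berries of 10–18 px,
the detector at width 1/8 and depth 1/3 (~0.17 M parameters), batch size 8,
learning rate 0.1 with cosine decay to 0.01 and box weight 0.1 — a small
model trained for tens of epochs needs a proportionally larger step size.
The learnability checks train on 200 scenes for 40 epochs (~2 CPU-minutes
per seed); the EIoU/CIoU direction comparison uses 60 scenes for 25 epochs
per run, three seeds each. Anchors for toy runs are clustered from the
training boxes (k = 12 over grids 16/8/4/2), exercising the clustering path
end-to-end.

## Numerical and engineering choices

- `bbyolo.nn` is a compact CPU tensor library: numpy arrays with
  reverse-mode autodiff, im2col convolution (grouped/dilated/strided),
  max/global pooling, batch normalisation (momentum 0.1), nearest
  upsampling, and a numerically stable fused binary cross-entropy. All
  gradients are validated against central finite differences in the test
  suite.
- Profiling runs the model's own `forward` on a shape-only `Shadow` tensor
  that accumulates multiply-accumulates, so parameter/FLOP figures can never
  diverge from the executed graph.
- Sigmoids are computed in the numerically stable split form; EIoU/CIoU are
  written once over generic operands and serve both the scalar API and the
  training graph.
- VOC XML uses 1-based inclusive integer corners on disk, converted to
  continuous 0-based half-open intervals in memory; integer boxes round-trip
  exactly. Strata tags ride in a custom `<strata>` element other VOC
  consumers ignore.
- Dataset splits floor the train and validation sizes and give the remainder
  to the test split, reproducing the reference counts
  18,498/2,642/5,286 for n = 26,426 at 70/10/20.
- Rotation augmentation re-boxes via the axis-aligned hull of the rotated
  corners and is therefore deliberately not inverse-exact (the hull grows);
  clipped boxes are dropped below 25 % of their transformed area.
- mAP is computed at IoU 0.5 (configurable) with all-point interpolation of
  the precision-recall curve; P and R are micro-averaged over classes at the
  operating confidence threshold. FPS is reported from mean per-image wall
  time but is hardware-bound and carries no correctness claim.

## Known limitations

- The synthetic scenes are far easier than orchard imagery; absolute mAP
  values here say nothing about field accuracy.
- The channel schedule and MSSENet head-width cap are reconstructions; other
  schedules within the same block structure would land at somewhat different
  parameter/FLOP totals.
- The numpy engine is single-threaded-friendly but orders of magnitude
  slower than a GPU framework; full-scale (608-px, 26k-image) training is
  out of its intended scope.
- Greedy NMS and greedy confidence-ordered matching are the standard but not
  the only conventions; both are oracle-tested against exhaustive references
  at small n.
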