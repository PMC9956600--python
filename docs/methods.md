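# Methods

This note records the model, the procedure choices that were genuinely
open, the numerical conventions the tests' oracles rely on, and what the
synthetic data does and does not establish.

## Problem and model

The task is single-class object detection: axis-aligned boxes around
standing dead tree (SDT) crowns in RGB tiles (nominally 512×512 px)
cropped from UAV orthomosaics.  Dead crowns are defoliated, gray-brown,
sparse structures on a green canopy; they span small (< 32×32 px box
area) to large (> 96×96 px) scales, and the main confusers are discolored
live crowns and bare soil.

The detector is a two-stage architecture.  A shifted-window transformer
backbone produces a four-level hierarchy U1..U4 (strides 4–32; channels
C, 2C, 4C, 8C).  Inside each block, tokens are normalised (LayerNorm),
attended within M×M windows with a learned relative-position bias added
to every attention logit, residual-added, then passed through a GELU MLP
with a second residual.  Blocks alternate regular and cyclically shifted
window partitions; shifted windows use an additive −∞ mask so tokens only
attend to tokens that shared their contiguous image region before the
shift, which is what gives cross-window information flow without extra
cost.

A top-down pyramid turns U1..U4 into S1..S4: the top level is processed
by one transformer block; lower levels add a laterally processed U_i to
the patch-expanded level above (patch expansion doubles resolution and
halves channels, so the sums are shape-compatible by construction) and
process the sum with another block.  All levels are projected to a common
width D.  The balance-enhancement step averages the four levels at the S2
resolution — bilinear interpolation upward, max-pooling downward — and
refines the average with an embedded-Gaussian non-local block (softmax
attention over all spatial positions, channel-reduced embeddings D→D/2, a
residual output projection), then adds the refined map back onto every
level to give P1..P4.  The intent is that every scale receives the same
globally balanced semantic content, which is what helps the small-crown
classes.

Detection follows the standard two-stage pattern: an RPN with three
anchors per position (one scale per level, aspect ratios 0.5/1/2) and
NMS-filtered proposals; RoI-Align pooling to 7×7; a two-FC head giving
class scores and class-agnostic box deltas; per-class NMS at inference.

### Dynamic training

Two quantities evolve during training.  The RoI label-assignment
threshold T_now starts at 0.5; every `update_interval` iterations it is
replaced by the mean of the recorded per-iteration statistics, where each
iteration records the K_I-th largest IoU between proposals and ground
truth (K_I expressed as a quantile rank, default 0.75).  The Smooth-L1
transition β_now starts at 1; it is replaced by the median of recorded
per-iteration K_β-th smallest regression errors (default K_β = 10),
where a proposal's error is the mean absolute value of its two center
coordinates' regression targets — only the centers enter, to keep the
statistic cheap and scale-free.  The rationale: early proposals are poor,
so a fixed high threshold starves the positive class; as proposals
improve, raising T_now and shrinking β_now focuses learning on precise
localisation.  T_now is clamped to [0.4, 0.9] and β_now to [0.02, 1.0] so
a pathological iteration cannot destabilise assignment or the loss.

Loss = RPN objectness (binary cross-entropy on sampled anchors, 0.7/0.3
IoU assignment plus best-anchor-per-GT) + RPN Smooth-L1 (β = 1) + RoI
cross-entropy + RoI dynamic Smooth-L1.  Optimisation is AdamW (lr 1e-4,
batch 4 by gradient accumulation over single images, linear LR decay,
100-epoch budget, early stop when validation loss has not improved for 20
epochs).  The comparison-experiment text mentions SGD; the method's own
training section specifies AdamW, which is what the trainer defaults to.

## Implementation substrate

No GPU framework is used: `snagdet.nn` is a small reverse-mode autodiff
engine over numpy (array-level primitives with hand-written
vector-Jacobian products, verified against central differences in the
test suite).  Convolutions in the RPN head are expressed as
shift-concatenate + linear; RoI-Align and bilinear resizing have manual
gradients via precomputed interpolation weights.  All computation is
float64, which keeps the brute-force oracle comparisons tight (≤ 1e-5 is
met with orders of magnitude to spare).

## Numerical conventions

These are fixed so the tests' independent oracles are exactly
reproducible:

- Boxes are (x_min, y_min, x_max, y_max), 0-based, half-open, pixels.
  COCO files use (x, y, w, h).
- Bilinear resizing uses half-pixel centers (corners not aligned);
  max-pool downscaling uses kernel = stride = the integer scale factor.
- RoI-Align: feature pixel (r, c) has its center at continuous
  coordinate (r+0.5, c+0.5); each output bin averages a 2×2 grid of
  bilinear samples; zero-area boxes are an error.
- Patch expansion reads the doubled channel vector as a row-major
  2×2×(c/2) spatial block.
- Softmax is computed shift-by-max; shifted-window masks use −1e9, and
  pad tokens (for inputs not divisible by the window or patch size) get
  unique negative region ids so they never influence valid tokens.
- Greedy evaluation matching: detections in descending score order, each
  matched to the unmatched ground truth of highest IoU ≥ threshold; ties
  at the assignment threshold count as positive (the rule is ≥).
- AP uses the COCO-style 101-recall-point interpolation of the monotone
  precision envelope; an exact all-point integral is available behind a
  flag.  The reported operating recall/precision/F1 are taken at the
  F1-maximising score threshold, which is printed in the report, because
  the published operating point is not stated.
- `split_dataset`: train and val take floor(n·f); the remainder joins the
  test split so counts always sum to n (568 → 397/56/115).  Augmented
  copies inherit their source tile's split, except copies of test tiles,
  which go to train — the test split is never augmented.

## Open design points and how they were resolved

- The backbone's stage widths/heads are the standard tiny-transformer
  convention (C=96, M=7, heads 3/6/12/24, MLP ratio 4); a CPU-sized test
  profile (C=24, M=4, depths (1,1,2,1), heads 1/2/4/8, D=32) is used by
  the tests.  With an odd stage depth a lone regular-window block is
  used, since the pairing of W-MSA/SW-MSA is conventional rather than
  structural.
- The patch embedding is a plain linear map on flattened 4×4 patches with
  LayerNorm; no absolute position embedding is added — the relative bias
  carries positional information.
- In the fusion rule, the per-channel weighting sometimes written into
  pyramid-fusion formulas is not implemented: fusion is element-wise
  addition of lateral and upsampled features followed by one transformer
  block.  Lateral paths carry one block and the upsampling path two
  (one before patch expansion), both configurable.
- The number of augmented images in the original survey (2031 from 568)
  is not an integer multiple of the source count, so the augmentation
  multiplicity is configuration (every requested op applied once per
  tile) rather than something to match.
- Rotation augmentation is restricted to k·90° so box remaps are exact;
  arbitrary angles would change box semantics.
- Anchor scale (8×stride), proposal counts (1000 train / 300 test after
  NMS at 0.7), RoI sampling (256 at 1:3 positives), inference thresholds
  (score 0.05, NMS 0.5) and the area-based RoI-to-level rule are standard
  two-stage-detector conventions, all exposed in configuration; the
  architecture description fixes none of them.
- TN is reported as not applicable: detection has no meaningful true
  negative.

## Synthetic data: what it emulates and what it does not

`snagdet.synth` renders textured green canopy (smooth illumination field
plus fine noise), live crowns as unions of jittered disks, and dead
crowns as sparse disk unions with radial branch strokes, drawn last so
every annotation is the tight envelope of visible dead pixels (a property
the tests check edge by edge).  Confusers — discolored live crowns and
bare-soil patches — are rendered but never annotated.  Default incidence
(1–3 dead crowns per 512 px tile) mirrors the sparse survey statistics;
size classes are controlled through the small/large radius ranges against
the 32²/96² area thresholds.

The generator does not attempt physically based rendering, species
morphology, shadows, view-angle or radiometric effects.  Passing tests
therefore establish that the architecture, losses, dynamic updates,
metrics and plumbing are correct and that the model can learn a
color/texture-separable target; they do not establish field accuracy on
real UAV imagery, whose headline numbers came from GPU-scale training on
a private dataset and are treated here as report fields only.

## Problem sizes used by tests and the acceptance script

These were chosen as the smallest sizes at which the stochastic checks
are stable: the end-to-end acceptance test trains the tiny profile on 200
easy 128×128 scenes for 3 epochs (batch 4, lr 1e-3 — the tiny profile
tolerates a larger step than the full model) and requires AP50 > 0.5 on
50 held-out scenes; observed runs reach ≈ 0.9.  The single-batch overfit
check requires a ≥50% loss drop within 200 iterations on 4 scenes;
observed runs halve it within ~10.  The acceptance script's training run
uses 120 scenes / 4 epochs / 30 test scenes.  The detectability-knob
property uses two 24-scene one-epoch runs at widely separated dead-crown
colors and asserts the AP ordering.

## Known limitations

- CPU-only float64 training: ~0.3 s per 128×128 image iteration at the
  tiny profile; the full 512-px profile is functional but slow, suitable
  for smoke runs rather than real training.
- One image per forward pass (batching is by gradient accumulation).
- The `prepare` workflow matches Labelme records to tiles by file stem;
  it does not re-project annotations drawn on the uncut mosaic.
- Checkpoints store parameters and dynamic state but not optimizer
  moments, so resumed training restarts AdamW statistics.
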