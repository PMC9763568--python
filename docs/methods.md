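# Methods

This note documents the models and procedures the package implements,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic phantoms do and do not establish
about real images.

## Label schema

Sixteen classes: background, vertebral bodies C2–T1, discs C2/3–C7/T1,
spinal canal, spinal cord.  The numeric id assignment (background = 0,
bodies 1–7 superior→inferior, discs 8–13, canal = 14, cord = 15) is a
repository convention — only the category list itself is fixed by the
task — and every rule in the package resolves ids through `LabelSchema`
rather than literals.  The quantity that drives post-processing is
`n_structures = 14`: the number of classes left after removing the
background and the cord, which equals the number of spatially separate
structures in an annotated slice (the cord is excluded because it lies
inside the canal and is handled by cavity filling instead of component
counting).

## Network

`SeDeepUnet` is a U-shaped encoder–decoder.  Defaults: `in_channels=1`,
`n_classes=16`, `depth=5` down/up-sampling stages, `base_channels=32`,
channel cap `max_channels=1024`, giving the schedule 32, 64, 128, 256,
512, 1024 and a 1024-channel 16×16 bottleneck from 512×512 input.  The
stated depth and bottleneck dimensions fix `base_channels=32` as the
only doubling schedule consistent with both; the cap exists so deeper
configurations do not grow past 1024 channels.

Open details were resolved conventionally and are flagged here as
assumptions:

- double conv is `conv3×3 → BatchNorm → ReLU`, twice, with the SE block
  after the second ReLU; batch normalization (`use_batchnorm`) is on by
  default because it stabilizes training at small batch sizes;
- the SE block sits in **every** double conv, encoder and decoder alike;
  its bottleneck ratio `se_reduction` defaults to 16, the customary
  value for squeeze-and-excitation blocks; `use_se=False` removes the
  blocks entirely and recovers a plain deepened U-Net (ablation A1);
- down-sampling is 2×2 max pooling; up-sampling defaults to a 2×2
  stride-2 transposed convolution halving the channel count
  (`upsample_mode="bilinear"` substitutes parameter-free bilinear
  upsampling);
- the network emits raw score maps; softmax lives in the loss.

Input edges must be divisible by 2^depth; this is checked at build time.

The layers are implemented directly in NumPy with hand-written
forward/backward passes (im2col convolutions, analytic BatchNorm and SE
gradients) and an RMSprop optimizer.  Correctness is established by
central-finite-difference gradient checks in the test suite; evaluation
mode uses BatchNorm running statistics and is fully deterministic.
Checkpoints store weights, BatchNorm running statistics and the model
config; restoring the best-validation epoch restores both the weights
and the matching running statistics (mixing the two belongs to different
epochs measurably degrades evaluation).

## Objective

`Loss = λ·CeLoss + (1−λ)·DeLoss` with `λ = 0.5`.  Cross-entropy clamps
its log argument at 1e-12 so hard-zero probabilities stay finite.  Soft
Dice per class uses smoothing `ε = 1e-6`; a class absent from both
prediction and truth therefore scores Dice 1 (absence correctly
predicted) rather than 0/0.  The Dice mean excludes the background by
default (`include_background_in_dice`) so the dominant background cannot
swamp the overlap term; evaluation means, by contrast, include the
background class, with foreground-only means reported alongside.  Both
loss terms are differentiated analytically through the softmax.

## Cutout

`hole_n = 5` squares of edge `mask_l = 47` are zero-filled at uniform
positions of the [0,1]-rescaled image.  Squares are sampled
independently (overlap allowed) and fully inside the frame, so the
zeroed-pixel count is bounded by `hole_n · mask_l²` and the bound is
exact — the indexing convention `rand ∈ [0, edge − mask_l]` avoids
partially clipped squares.  Zero is the dark extreme after rescaling,
matching the all-zero fill.  Augmentation is offline: one stored copy
per training image (350 → 700 records), labels shared with the
original; regenerating per epoch would change the sample count.
Sampled corners are returned so tests can reconstruct the square union
exactly.

## Post-processing

Stages run in fixed order; all area comparisons are strict
(`area < η` removes, equality keeps), components use 8-connectivity,
holes 4-connectivity (the standard complementary pairing).

1. **Large-anomaly removal.**  "Connected-domain operation with a large
   kernel" is realized as: label the foreground-union components, mark a
   component as a coarse-scale *block* iff any of it survives a
   morphological opening with a `ker_l`-square, and erase blocks with
   area < `η_l`.  Components the opening suppresses entirely — thin true
   structures such as discs — are deliberately exempt and left to the
   fine pass; without this exemption the coarse pass would delete thin
   anatomy at small image sizes.
2. **Small-anomaly removal.**  Plain per-class component labeling;
   components below `η_s` become background.
3. **Count reconciliation.**  K = components of the union of all classes
   except background and cord.  K = 14: uniform majority-class
   relabeling per component (ties break to the smaller id and are
   logged).  K > 14: the K−14 smallest components are erased, then
   relabeling.  K < 14: adhesion splitting — mixed vertebra+disc
   components are opened with a `ker_s` square (bridges thinner than
   `ker_s` are cut to background), the vertebra union and the disc union
   are then relabeled per component by majority class, and disc
   fragments below `η_d` (cord-contact slivers) are dropped.
4. **Cavity filling.**  Interior background holes of the cord and the
   canal (background regions unreachable from the border under
   4-connectivity) are filled with the enclosing class; no foreground
   pixel is ever altered.

Defaults `ker_l=7, ker_s=3, η_l=2000, η_s=100, η_d=30` are calibrated to
512×512 frames; `PostprocessConfig.for_shape` scales the areas by image
area and the kernels by linear size.  The invariants the suite enforces:
the chain is idempotent, clean phantoms are fixed points, external
stages only move pixels to background, cavity filling only moves
background pixels to foreground, per-stage pixel error versus truth
never increases on any defect fixture, and the structural union has
exactly 14 components afterwards.  Anatomical *ordering* (C3 above C4,
etc.) is deliberately **not** enforced; majority relabeling can in
principle assign an anatomically out-of-order class, and no rule exists
to arbitrate such conflicts.

## Phantoms

`generate_phantom` draws one sample per config: seven vertebra
rectangles (~3× taller than discs) stacked with six disc bands between
them, separated by thin background gaps; a canal band posterior to the
column; the cord strictly inside the canal.  Gaps mirror the annotation
property that the 14 structures form 14 separate connected domains —
the property stage 3 relies on.  The image is per-class mean intensity
(defaults distinct and monotone in class id, so a small network can
separate the classes quickly) plus additive Gaussian noise
(`noise_sd = 0.03` on the [0,1] scale) clipped to range; horizontal
placement jitters per structure (`jitter_sd = 2 px`) so dataset samples
are distinct.  Shapes are axis-aligned rectangles with corner rounding
off by default: post-processing and metrics depend only on topology, and
exact rectangles make morphological openings exact, which keeps the
truth-recovery oracles byte-exact.  Everything is a pure function of
(config, seed).

`make_degraded_prediction` injects the anomaly kinds observed in real
predictions — stray blobs, small islands, vertebra/disc adhesion
bridges, interior cavities — with exact pixel areas, so cleanup can be
asserted against known truth.

What phantoms do **not** model: MRI physics (bias fields, partial
volume, scanner-dependent intensity distributions), anatomical shape
variation and pathology, and touching structures without background
separation.  Tests passing on phantoms therefore establish the
correctness of the algorithms (loss arithmetic, component logic,
training mechanics), not clinical segmentation accuracy.

## Training

Study-condition defaults: RMSprop (smoothing 0.99, eps 1e-8 — the
framework-conventional values), learning rate 1e-5, batch size 6,
200 epochs, no class weighting in the cross-entropy (the Dice term is
the imbalance mitigation).  Model selection keeps the epoch with the
best validation mDSC.  Repeated-runs validation (`repeat_runs`) trains N
models with derived seeds; N is configurable with default 10.

The **desk profile** is the package's scaled-down condition for
CPU-only runs: 64×64 phantoms (16 train / 4 validation / 8 held-out),
a depth-3 network with base 8 channels capped at 64, batch 4, 30 epochs,
and learning rate 1e-2 — the short schedule needs the larger step size;
at the study's 1e-5 nothing converges in 30 epochs.  A full desk cycle
(generate → train → evaluate) takes well under a minute per run on one
core and reaches held-out mDSC in the 0.7–0.95 range depending on the
seed.

The cumulative ablation (`run_ablation`) stacks, onto a plain U-Net
baseline with one fewer stage: A1 channel attention, A2 the extra
down-sampling stage, A3 Cutout, A4 post-processing, re-training on the
same split and seed and reporting test mDSC/mIOU per configuration.

## Numerical choices

- All network arithmetic is float64; at the package's problem sizes the
  cost is acceptable and gradient checks are sharp.
- He-normal weight initialization, seeded from the model config.
- Softmax is max-shifted; the sigmoid is evaluated in its stable form in
  both tails.
- Majority-relabel ties break toward the smaller class id, logged in the
  stage record.
- Seeds everywhere derive from user seeds via `numpy.random.SeedSequence`
  chains, keeping independent consumers decorrelated and reproducible.

## Known limitations

- The NumPy network is single-threaded apart from BLAS matmuls; the
  default 31M-parameter configuration at 512×512 builds and describes
  itself quickly but is not practical to train at full scale on a CPU —
  the desk profile is the supported training regime here.
- Post-processing presumes all 14 structures are present in the frame;
  maps missing structures (K < 14 without adhesion) pass through the
  splitting branch, which only separates what exists.
- `evaluate` offers micro (pooled counts; default) and macro
  (per-image) averaging; the micro/macro choice changes means on
  heterogeneous test sets, so reports state which was used.
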