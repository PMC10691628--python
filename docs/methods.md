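# Methods

## Problem and model

`pisunet` segments cystic pancreatic lesions (pancreatic cystic neoplasms,
PCNs) in 2-D grayscale slices. Clinically these come in two morphologies
with different management: serous cystic neoplasms (SCN), typically benign
multi-cystic clusters, and mucinous cystic neoplasms (MCN), typically a
single large precancerous cyst. On T2-weighted MRI both appear as bright,
often low-contrast regions with blurred walls.

The segmenter is an encoder–decoder U-Net augmented in three ways, each
individually switchable so their contributions can be ablated:

1. **SE channel attention.** A squeeze-and-excitation gate compresses each
   feature map A (H × W per channel) by global average pooling,
   z_k = (1/HW) Σ_i Σ_j A_k(i,j), maps z through a bottleneck MLP,
   s = σ(W₂ · ReLU(W₁ · z)), and rescales channels, out_k = s_k · A_k.
   Bottleneck width is max(1, ⌊C/r⌋) with reduction ratio r = 16, so the
   gate stays well defined in narrow test models (C < 16).
2. **Inception multi-scale convolution.** Four parallel branches (1×1;
   1×1→3×3; 1×1→5×5; 3×3 max-pool→1×1), each contributing out/4 channels
   at unchanged spatial size. The 1×1 bottlenecks (width out/8) ahead of
   the 3×3 and 5×5 kernels make the block strictly cheaper than the dense
   3×3 convolution it replaces; the test suite asserts this parameter
   reduction both per block and for whole networks.
3. **Pyramid pooling module (PPM).** At the bottleneck, the map is
   adaptively average-pooled to p × p grids for p ∈ {1, 2, 4, 8}
   (PSPNet convention: the sizes are target grid sizes, not kernel
   sizes), reduced by 1×1 convolutions to C/4 channels each, bilinearly
   upsampled back, concatenated with the input and fused by a 1×1
   convolution. Output spatial size always equals input size.

The five variants form the ablation matrix: `unet`, `se_unet`, `ppm_unet`,
`is_unet` (Inception+SE composite replacing the *second* 3×3 convolution of
every encoder/decoder block), and `pis_unet` (all three). With SE alone,
the gate is appended after the second 3×3 convolution. The composite is
applied in the bottleneck block too by default (`composite_in_bottleneck`
flag to exclude). The SE scale step is implemented as the product of the
gate vector with the *feature map* (channel-wise), which is the only
reading under which the block is an attention mechanism; formulations that
scale the pooled vector itself are degenerate.

Backbone details: 4 levels (configurable `depth`), channels doubling from
`base_channels` (64 at full scale, 8 in tests); every convolution is
stride-1 'same'-padded and followed by batch normalisation + ReLU
(batchnorm removable via config — it is standard for this family even when
a description omits it); 2×2/stride-2 max pooling down, learned 2×2
transposed convolution up; skip connections by channel concatenation;
1×1 convolution + sigmoid head giving a one-channel probability map at
input resolution. Masks are produced by thresholding at 0.5.

## Numerical engine

No GPU framework is used: `pisunet.nn` is a compact reverse-mode autodiff
engine on numpy. Convolution is im2col + BLAS matmul; the transposed
2×2/stride-2 convolution uses the non-overlapping-kernel einsum; adaptive
average pooling and bilinear resampling are separable linear maps
`y = A x Bᵀ` whose adjoints give the backward passes. Working precision is
float32 (float64 supported and used by the finite-difference gradient
checks, which cover every operator). Weight init is He-normal from an
explicit `numpy.random.Generator`, so a model build is a pure function of
its seed.

## Training protocol

Adam with learning rate 1e-4 and β₁ = 0.9 (β₂ = 0.999), 30 epochs, batch
size 8, are the full-scale defaults; "momentum 0.9" is interpreted as β₁
because Adam has no classical momentum term. The loss is BCE + soft Dice
(smoothing 1) by default — a compound that is robust for foreground
fractions well below one half; pure `bce` and `dice` are selectable. The
checkpoint with minimum *validation* loss is kept: a 20 % validation
carve-out exists precisely to select models, so "minimum loss" is read as
validation loss. Batch order is drawn from the config seed; training is
bit-deterministic given (seed, data).

Evaluation: per-image Dice (DSC), volumetric overlap error (VOE), relative
volume difference (RVD), precision, recall. Two VOE conventions are
implemented because they genuinely differ: the default "fp" form
2|S∖G|/(|S|+|G|) charges only false positives (a strict subset prediction
scores 0), the `jaccard` form is the standard 1 − |∩|/|∪|. Empty-mask
conventions (documented in `pisunet.metrics`): both masks empty counts as
perfect agreement; RVD with empty ground truth raises rather than guessing.

Cross-validation is 3-fold, grouped by **patient**: adjacent slices of one
tumor are nearly duplicates, so slice-level splitting would leak test
information into training. (Slice-level splitting is available by passing
slice keys to `make_folds`.) The two lesion classes are trained separately,
one model per class per fold. Reported numbers are mean ± SD (ddof = 1) of
the three per-fold means, on the percent scale; per-image records are kept
in machine-readable unit scale.

## Phantom generator

`pisunet.phantom` renders the study conditions synthetically: ellipse-union
lesions (one large ellipse for MCN-like, 3–8 clustered sub-ellipses for
SCN-like) on a smooth Gaussian-random-field background (constant level 0.25,
texture amplitude 0.08 — non-constant so normalisation and ROI cropping are
non-trivial), lesion/background contrast drawn U(0.3, 0.7), border blur
U(0.5, 1.5) px, additive Gaussian noise sd 0.05, lesion radius U(0.10, 0.25)
of the image side. Slices of one synthetic patient share a base geometry
with ±10 % per-slice jitter. The mask is the pre-blur lesion support, so
labels stay exact while borders in the image are indistinct.

What the phantoms do **not** emulate: MRI physics (coil inhomogeneity,
partial volume, motion), anatomy surrounding the pancreas, 3-D continuity,
and the intensity statistics of real T2-weighted slices. Passing tests
therefore demonstrate that the architecture, metrics and protocol are
implemented correctly and that the networks can learn this lesion family —
not that clinical-grade accuracy would be reached on hospital data.

## Preprocessing

ROI localisation uses the annotation mask (no automatic detection — the
workflow is deliberately label-driven, matching the manual-bounding-box
stage of two-stage clinical pipelines). The tight bounding box is expanded
by `margin_frac` (default 0.25) of the box side per edge — the margin keeps
border context the network needs — clamped to bounds, resized (bilinear
image, nearest-neighbour mask) to the target size, and normalised (min-max
default; z-score available; constant images map to zeros). Resize is a
direct stretch by default because the crops are near-square by
construction; aspect-preserving pad-to-square is available
(`resize_pair(..., keep_aspect=True)`).

## Problem sizes used in tests and the acceptance script

Desk-scale (single CPU) runs use the miniature-study sizes: 64×64 phantoms,
`base_channels` 8, depth 4, learning rate 1e-3 (appropriate for a few
hundred updates from scratch; the full-scale default 1e-4 is tuned for 30
epochs over hundreds of slices). The learning checks are: (a) overfitting
8 training slices to mean train DSC > 0.9 within 100 epochs; (b) on a
30-patient single-slice-per-patient set, 3-fold CV at 10 epochs beats the
untrained (randomly initialised) networks by a large DSC margin across
seeds. Headline clinical DSC values from GPU-scale training on private
hospital data are out of scope by design.

## Known limitations

- 2-D only; no DICOM/NIfTI ingestion (PNG + CSV manifests are the
  fixture-friendly interface).
- The numpy engine is single-threaded BLAS-bound; it is meant for
  correctness and desk-scale experiments, not production training.
- BCE is computed on clipped probabilities (eps 1e-7) rather than from
  logits; at the scales used here this is numerically benign.
- `run_ablation` trains one model per (variant, class, fold) — 30 trainings
  for the full matrix — so full-scale ablations are long-running by nature.
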