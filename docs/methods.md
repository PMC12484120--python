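# Methods

## The segmentation problem

Ultrasound images of uterine fibroids are hard to segment automatically:
lesions are hypoechoic (darker than surrounding tissue) but low-contrast,
boundaries are blurred, and the whole image is corrupted by multiplicative
speckle. MAF-Net is a U-Net-style encoder–decoder for binary lesion
segmentation that attacks these problems with three attention modules:
multi-receptive context aggregation in the deep encoder (MAFM), dual-scale
attention in the decoder (DAEM), and SE-enhanced skip connections (DSEEM).

## Architecture

The network has four encoder stages at widths `stage_widths`
(default 32, 64, 128, 256) separated by three 2×2 max-poolings, a
three-step decoder mirroring them, and a 1×1 convolution + sigmoid head.
Inputs must therefore be divisible by 8 in both spatial extents. Every
convolution is stride-1, zero-padded ("same"), and followed by batch
normalization and a ReLU unless noted; spatial extents are preserved
through every block.

**MAFM** (encoder stages 3–4). A 1×1 entry convolution maps the input to
the working width. Three parallel 3×3 branches run at dilations
(d₁, d₂, d₃) = (1, 3, 5) by default, giving effective receptive sides
k + (k−1)(d−1) = 3, 7, 11. Branch 1 ends in spatial attention, branch 2 in
channel attention, branch 3 in spatial attention; each later branch's input
is the working features plus the earlier branches' outputs (element-wise
sum — the operator is a design choice; sum preserves width and gives the
residual-style coupling that motivates the cross-branch links). The three
branch outputs and the main path are concatenated and fused by a 1×1
convolution (a `fusion="sum"` toggle exists), and a final spatial attention
refines the result.

**DAEM** (decoder refinement). The block processes its input at native
resolution and at 2× up-sampled resolution (bilinear by default, nearest
available). Each scale passes a 3×3 convolution and channel attention, and
the pre- and post-attention maps are summed to retain structure. The 2×
branch is folded back to native resolution by 2× average pooling — fusion
happens at native resolution, which keeps the decoder's tensor ladder
intact (the alternative, fusing at the doubled resolution, was rejected as
it would force an extra resample for no benefit). The fused map then
passes two conv+attention stages: channel attention first, spatial second.
Odd extents work because the up-sample is an exact 2× resize, so the 2×2
average pool always lands back on the native grid.

**DSEEM** (skip connections). The encoder skip tensor is convolved 3×3 at
its own resolution; the deeper decoder tensor is up-sampled 2× (resize to
the skip extents, tolerating ±1 pixel). The aligned streams are
concatenated into base features B, which pass two cascaded
squeeze-and-excitation gates, each wrapped with an additive residual:
e₁ = B⊙w₁ + B, e₂ = e₁⊙w₂ + e₁. A 3×3 convolution of e₂ produces C, and
the final output is a 1×1 convolution of [e₁, e₂, C]. Single-path modes
(`input1_only`, `input2_only`) drop one stream and keep everything else,
which makes the path-selection experiment a pure config sweep. The
"down-sample the encoder features / up-sample the decoder features"
description is internally inconsistent about the fusion resolution; this
implementation fixes fusion at the skip resolution.

**Attention primitives.** Spatial attention concatenates channel-wise mean
and max maps and convolves them with one 7×7 filter (CBAM convention;
kernel configurable, odd ≥ 3) followed by a sigmoid. Channel attention
passes global average- and max-pooled descriptors through a shared
two-layer bottleneck C → C/r → C (ReLU between), sums, and applies a
sigmoid; the SE block is the same without the max path and with its own
parameters. The reduction ratio defaults to r = 8, which keeps the hidden
width ≥ 1 even at the narrowest configured stage (hidden width is clamped
to ≥ 1). Sharing the bottleneck across the two pooled descriptors is a
design choice following the CBAM lineage.

## Loss and metrics

Training minimizes the soft Dice loss
`L = 1 − (2·Σpᵢyᵢ + ε) / (Σyᵢ + Σpᵢ + ε)`. The smoothing constant
ε = 1e-9 exists solely to keep the empty-mask case finite; it is small
enough that the loss agrees with the unsmoothed formula to well below
1e-9 on any non-degenerate input.

Evaluation derives Dice, Matthews correlation, Jaccard, pixel accuracy and
recall from per-image TP/TN/FP/FN tallies after thresholding predictions
at 0.5. Degenerate denominators use the standard conventions: Dice,
Jaccard and recall are 1 when both masks are empty; Mcc is 0 when a
marginal is empty. Two aggregations are provided — `per_image_mean`
(default) and `global_pool` (metrics of the summed tallies) — because
dataset-level reporting can legitimately be either and they differ in
general.

## Numerics: the `mafnet.nn` stack

The network runs on a small reverse-mode autodiff engine over numpy
arrays written for this package: dynamically recorded op graphs,
GEMM-based stride-1 "same" convolution (dilated via tap striding; the
input gradient is the transposed convolution with channel-swapped,
180°-rotated kernels), reshape-based 2×2 pooling, dense-matrix separable
bilinear/nearest resizing (so resize gradients are also matmuls), batch
normalization with running statistics, and the five optimizers compared
in the tuning grid (SGD, Adam, Adamax, Adagrad, RMSprop, at their usual
moment defaults; Adam/Adamax betas (0.9, 0.999), RMSprop ρ = 0.9,
ε = 1e-8). Parameters are He-initialized from a module-level generator
reseeded by `build_model(cfg, seed)`, so builds are bit-reproducible.
Parameters default to float32 for speed; `Module.astype(np.float64)`
switches a model to double precision, which the closed-form and
oracle-agreement tests use for their ≤ 1e-10 tolerances. Gradient
correctness is tested against central finite differences for every op,
and the convolution against a nested-loop oracle.

Max pooling and channel-max gradients split ties evenly; ties are
measure-zero for float inputs and the choice never affects the forward
pass. Sigmoid uses `scipy.special.expit` for overflow-free evaluation.

## Synthetic phantoms

No clinical data ships with the package, so the generator emulates the
relevant degradations: a smooth background echo texture (heavily blurred
white noise around mid-gray), 1–3 rotated elliptical lesions per image
with semi-axes 5–25 % of the image side, hypoechoic attenuation of the
lesion interior by `contrast_drop` (default 0.5; a hyperechoic toggle
exists), multiplicative gamma speckle with mean 1 and shape k = 5
(variance 1/k; a Rayleigh-derived variant is available), and Gaussian blur
with σ = 1 px, then clipping to [0, 1]. Masks are the exact rasterized
ellipse unions, and lesions are placed fully inside the frame so mask area
matches the analytic ellipse area up to rasterization. An RGB variant
tints the phantom over a skin-tone gradient purely to exercise the
3-channel input path.

What the phantoms do *not* model: acoustic physics (no point-spread
function, attenuation with depth, shadowing or reverberation artifacts),
anatomical context, or annotation noise. Passing the learning tests
therefore shows that the architecture, loss, optimizer and pipeline can
fit ultrasound-like statistics — not that clinical-grade accuracy is
reached on real data.

## Training defaults and experiment grids

Defaults mirror the study settings: Adam, learning rate 0.001, 200
epochs, batch size 16, Dice loss, no augmentation, no LR schedule, no
early stopping (optional patience exists but is off). The curve logger
records train/val loss and pixel accuracy (threshold 0.5) each epoch, and
the best-validation-loss weights are what `train()` returns and
checkpoints. All randomness (initialization, shuffling, phantoms) funnels
through explicit seeds.

Four grids reproduce the published configuration sweeps as config
enumerations: the 5 module combinations, the 21 dilation triples
(1, a, b) with 2 ≤ a < b ≤ 8, the 3 skip-path modes, and the 5 optimizers.
Grid runs default to a desk-scale profile; the paper-scale profile
(256×256, 200 epochs, full widths) is reachable through the same configs
but is a GPU-sized computation.

## Problem sizes used by the tests and the acceptance script

CPU-friendly reductions, chosen once: architecture and training checks run
at 64×64 (the smallest extent exercising all three poolings comfortably)
with stage widths (8, 16, 32, 64) — or (4, 8, 16, 32) for pure contract
checks — and the learning-capability check overfits 8 phantoms for 150
full-batch Adam steps, which reliably drives training Dice above 0.8 while
plain SGD at the same learning rate stays far below (the optimizer-gap
ordering). Parameter-count assertions are orderings only: the published
width schedule is not public, so absolute counts are reported, not
matched.

## Known limitations

- The exact channel widths, attention kernel/reduction sizes and several
  fusion operators of the original network are unpublished; every such
  choice here is explicit in `ModelConfig` and recorded above.
- CPU-only: paper-scale training (256×256, thousands of images, 200
  epochs) is out of desk reach; the package is exercised end-to-end at
  reduced scale.
- Binary masks only; no DICOM ingestion; no augmentation pipeline.
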