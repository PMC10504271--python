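# Methods

## Problem and model

Pneumothorax appears on axial chest CT as a crescent of near-air
attenuation between the collapsed lung margin and the chest wall.  `faseg`
segments it with an encoder–decoder network whose decoder avoids
upsampling entirely.

**Encoder.**  A single-channel stem convolution (3×3, stride 2) followed by
five stages of mobile inverted bottleneck blocks (MBConv: 1×1 expansion,
depthwise convolution, squeeze-and-excitation gate, 1×1 projection,
residual skip when stride 1 and channels match).  Feature maps are tapped
after the stem and after stages 2–5, giving a five-level pyramid
F_i ∈ R^{C_i×H_i×W_i} at strides 2, 4, 8, 16, 32 — a 256×256 input yields
sides 128/64/32/16/8.  Batch normalisation follows every convolution;
activations are swish; padding is "same" so stride-2 layers produce
⌈side/2⌉.  Weight init is fan-out-scaled normal, fixed by a seed.

**Feature-alignment decoder.**  Each level's features, after a learned 1×1
projection to a common latent width C, are treated as latent codes sampled
at pixel centres ((r+0.5)/H_i, (c+0.5)/W_i) of the unit square — one global
coordinate frame for all levels.  For a query x_q ∈ [0,1]² the decoder
finds, per level, the nearest code z_i* (ties to the smaller row, then
column), the offset δx_i = x_q − x_i*, and a sinusoidal expansion

ψ(u) = (sin ω₁u, cos ω₁u, …, sin ω_L u, cos ω_L u),  ω_l = 2·e^l,

applied per offset component.  The concatenation of (z_i*, ψ(δx_i), δx_i)
over the five levels — width 5·(C + 4L + 2) — feeds a shared MLP
(rectifier hidden layers, linear output) that emits the two class logits:

D(x_q) = f_θ({z_i*}, {ψ(δx_i), δx_i}).

Because D is defined at every point of the unit square, one trained model
decodes at any output resolution; prediction is per-pixel argmax with ties
to background.

## Assumptions and conventions

- Rows index top→bottom, columns left→right, across all modules.
- Offsets are expressed in the global frame.  A config switch
  (`scale_offsets`) rescales δx_i by the level's grid size; default off, so
  coarse levels contribute smaller-magnitude offsets and ψ's fixed
  frequency bank resolves mainly the fine levels.
- ω_l = 2·e^l is used literally (natural exponential); both the base and L
  are configurable.  The encoding is one shared bank applied per level.
- Border queries use the nearest code with no padding or extrapolation.
- The model is 2-D: slices are independent samples; no volumetric context.

## Numerical core

The network runs on a small tape-based reverse-mode autodiff engine over
numpy (float32): dense/depthwise convolution via im2col and strided
windows, batch norm with running statistics, spatial gather with
scatter-add backward, softmax cross-entropy.  Gradients are verified
against central finite differences in the test suite.  Inference
(`predict`) instead runs a float64 plain-numpy decode path; the two paths
are pinned against each other to ~1e-6.  Consequences of this design:

- same seed + same shapes ⇒ bit-identical runs on CPU (BLAS summation
  order is fixed for a fixed problem shape; a *different* batch shape may
  change results by ~1 ulp, which is why repeatability is asserted for
  identical call shapes);
- checkpoints (a single `.npz` of every parameter/buffer plus the JSON
  config) round-trip bit-exactly.

## Preprocessing

HU values are recovered from DICOM rescale slope/intercept or the NIfTI
header, remapped through a linear window with clipping
(value = clip((HU − (c − w/2))/w, 0, 1)), and bilinearly resized (pixel-
centre aligned, matching the decoder's frame) to the model side; masks are
resized nearest-neighbour so they stay binary.  `WindowSpec` defaults to
width 1500 / centre +600 HU; the pipeline configs default to the standard
lung window (1500 / −600), without which lung parenchyma (≈ −800 HU) and
pleural air (≈ −950 HU) both clip to 0 and are indistinguishable.  Splits
are by patient, so no patient contributes slices to two subsets.

## Phantom generator

The generator emulates only the attenuation structure relevant to
segmentation: soft-tissue body ellipse (+40 HU) on air (−1000 HU), two
lung ellipses (−800 HU), and with probability 0.75 one crescent of pleural
air (−950 HU) formed as the set difference between the lung and a
shrunken, medially shifted inner ellipse, the shift bisected so the
crescent covers a target fraction (default 8–35 %) of the lung.  Gaussian
HU noise (default σ = 20 HU) models quantum mottle.  Every sample is a
pure function of (seed, index).

What the phantoms do **not** model: ribs and mediastinum, texture,
partial-volume boundaries, 3-D continuity, scanner artefacts, and the
anatomic variability of real patients.  Passing the phantom benchmarks
therefore demonstrates that the architecture, optimisation and evaluation
machinery work end to end — not clinical-grade performance on hospital CT.

## Training protocol

Softmax cross-entropy over the two classes, Adam (lr 0.001, β = 0.9/0.999,
constant schedule), batch size 16, no augmentation (a hook exists, default
off), lesion-free slices included by default, best checkpoint selected by
pooled validation Dice.  Supervision is applied at query points: by
default the full input-resolution grid; `points_per_image` draws a seeded
random subset per step, the standard economy for coordinate-MLP readouts
(evaluation always decodes full grids).  All randomness flows from the
config seed.

## Problem sizes used in tests and the acceptance script

Desk-scale conditions, chosen once: phantoms at 64×64 with the `tiny`
preset (stem+stage widths 8/8/16/24/32/48, depth 1, expansion 2, latent
width 32, L = 8, MLP 330→128→128→2; ≈ 0.08 M parameters).  The
overfitting oracle trains on 8 lesion-bearing phantoms for 300 steps with
1024 query points per image.  The generalization run trains on 512
phantoms for 30 epochs (batch 16) with a 16-phantom validation set and
evaluates on a held-out 64-phantom cohort; with these sizes the held-out
pooled Dice reaches ≈ 0.9, and shrinking the training cohort to 256/64
degrades it sharply (the coordinate MLP memorises small cohorts).  The
`b5like` preset (widths 48/24/40/64/176/512, depths 3/5/5/7/9, expansion
6) exists for realistic-scale configuration; its parameter/FLOP figures
are informational, reported by `faseg stats`.

## Metrics

Pixel confusion counts with lesion positive; Acc, Dice, IoU, sensitivity,
specificity by their standard formulas (specificity = TN/(TN+FP)).  When
prediction and truth are both empty, Dice/IoU/Sen are defined as 1
(correct rejection); any other zero denominator reports 0.  Two
aggregations are emitted: pooled counts (headline) and per-slice means.

## Known limitations

- The autodiff engine is single-threaded numpy; realistic-resolution
  training (256², `b5like`) is possible but slow — the package's training
  evidence is at phantom scale.
- Nearest-code lookup makes D piecewise-constant in z between code
  centres; continuity comes only through ψ and δx.
- Class imbalance is handled only by optional class weights; no focal or
  Dice loss.
- 8-bit PNG masks and single-frame DICOM only; no DICOM-RT, multi-frame,
  or MPR reconstructions.
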