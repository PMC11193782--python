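# Methods

This note records the modelling choices, numerical conventions and known
limitations of `melondet`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Architecture and scaling rules

Both variants share the small-scale single-stage topology: nominal
channels 64–128–256–512–1024 and stage repeats 3–6–6–3, scaled by width
0.25 and depth 0.33 (hence 16–32–64–128–256 channels and 1–2–2–1
repeats), SPPF with k = 5, a top-down/bottom-up pyramid neck, and three
detection scales at strides 8/16/32.  Channel widths round up to
multiples of 8.

The `cml` variant replaces, relative to the `v8n_baseline`:

* every **backbone** C2f inner bottleneck by a **Faster-EMA** block,
* every **neck** C2f inner bottleneck by a plain **FasterBlock**,
* the decoupled head by the **efficient shared-stem head**.

This placement is the unique assignment consistent with the component
parameter arithmetic: with it, the baseline counts 3,011,417 trainable
parameters (nc = 3) and the lightweight variant 1,724,217, and the two
intermediate configurations (attention-augmented backbone only;
efficient head only) land on 2.31 M and 2.42 M respectively — the
checked anchors of the acceptance suite.

Block conventions:

* **PConv** operates on the *first* `c_p = round(r·c)` contiguous
  channels (`r = 1/4` default), stride 1, same padding, no bias, no
  normalisation.
* **FasterBlock**: PConv(3×3) → 1×1 conv expanding `c → 2c`
  (BN + ReLU) → 1×1 conv reducing `2c → c` (no norm/activation),
  identity shortcut.  Expansion factor 2 matches the doubling described
  for the attention variant and is the only factor compatible with the
  1.72 M total.
* **EMA** follows the canonical grouped formulation: per group,
  directional average pooling feeds a shared 1×1 conv whose split
  outputs sigmoid-gate the group (followed by per-channel group
  normalisation); a 3×3 conv gives the local path; softmax-normalised
  globally pooled descriptors of each path are matrix-multiplied with
  the flattened features of the other, summed, and sigmoid-gated onto
  the input.  `ema_groups = 8` everywhere; with the hidden widths in
  play (16–128 channels) both 8 and 16 groups reproduce the printed
  totals, and 8 is kept as the smallest canonical choice.  One prose
  sentence of the source description ("the export of the minimum branch
  undergoes direct conversion…") is not interpretable; the canonical
  formulation is used.
* **Efficient head**: per level, stem = PConv(3×3, r = 1/4) then 1×1
  conv (BN + SiLU) at the level's own width, shared by the two 1×1
  projections (nc class logits; 4×16 distribution logits).  Stems are
  *not* shared across levels — cross-level sharing would force channel
  unification that the 0.2 M parameter anchor rules out.

## Loss

`L = 7.5·box + 0.5·cls + 1.5·dfl` (framework-conventional weights),
where box is the α-CIoU loss (α = 3) over positive anchors weighted by
their assignment score, cls is BCE-with-logits against task-aligned soft
labels normalised by the total target score, and dfl the distribution
focal loss over the two bins bracketing each box-side offset (clamped to
`reg_max − 1 − 0.01`).  The aspect-ratio weight `θ = v/((1 − IoU) + v)`
carries no gradient (standard CIoU practice); the α power is applied to
each of the three terms, with the distance term read as `(ρ²/c²)^α`, and
is *not* applied inside the DFL (the power family targets IoU-based
losses only).  Positive anchors come from a task-aligned assigner
(metric `score^0.5 · IoU^6`, top-10 candidates inside each target box,
conflicts resolved by highest overlap).  A numerical floor of 1e−7
guards IoU denominators, the enclosing-box diagonal and the arctan
arguments.

At an exact prediction–target match the IoU surface has a kink, so the
full gradient of the α-CIoU loss does not vanish identically; its
translation component does, and the loss value is zero.  The property
test asserts exactly that.

## Complexity accounting

* **Parameters**: element counts of trainable arrays (conv
  `c_in/groups · c_out · k²` + bias, normalisation `2c`).  The frozen
  expectation kernel of the distribution decoder and the quantised
  kernel of the distribution-shift benchmark block are buffers, not
  parameters.
* **FLOPs**: `2 ×` multiply-accumulates of convolution/projection
  layers, measured by one recorded forward pass at the stated input
  size; attention blocks that fold channel groups into the batch axis
  are charged for every group.  Pooling, activations and the attention
  matrix products are not counted (three orders of magnitude below the
  convolutions here).  Whole models are profiled **fused**
  (normalisation folded into the convolutions, contributing nothing);
  isolated sub-modules (the head-only figures) are profiled **unfused**,
  normalisation counted at 2 ops/element before doubling.  These are the
  conventions under which the published whole-model numbers (8.1 G at
  nc = 3, 8.7 G at nc = 80) and head ratios are reproduced.
* **Head reference class count**: the published head-only comparison is
  internally consistent only against the 80-class reference head (0.2 M
  is 22.3 % of the 0.897 M reference; 0.46 G is 12.6 % of ≈3.65 G), so
  head-only profiles default to nc = 80; the head *parameter* figure is
  quoted at the task's nc = 3 (0.165 M, printing as 0.2 M at one
  decimal).
* Under these conventions the baseline decoupled head measures
  3.63 GFLOPs, not the 3.46 G sometimes quoted alongside it; 3.46 equals
  42.7 % of the 8.1 G three-class total, which mixes class counts.  The
  acceptance suite reports the measured value and the corresponding
  check stays red rather than adjusting the convention per figure.
  Likewise the lightweight model measures 3.79 GFLOPs (a 53.1 %
  reduction), slightly below the 3.9 G companion figure, which cannot be
  reconciled with the parameter column under any uniform block swap —
  parameters and conv FLOPs scale identically for same-shape layers.
* The benchmark zoo reconstructs each block at 128 channels, kernel 3,
  convolution bias plus batch normalisation — the unique configuration
  reconciling the published parameter column (147.840 K plain conv,
  18.304 K depthwise-separable, 75.712 K slim conv with a 5×5 depthwise
  stage, 9.472 K partial conv without bias, 256 trainable parameters for
  the distribution-shift block whose quantised kernel is frozen).  The
  zoo's FLOPs-at-unstated-input-size and all timing columns are reported
  for information only.

## Data pipeline

Splits are uniformly random with the train share floored and the
remainder split val-first (1240 → 992/124/124).  The augmentation plan
derives exactly 1150 images per training set: rotation 150 (90°/270°,
split evenly), brightness 150 (±5–30 %), mirror 100
(horizontal/vertical), contrast 150 (±5–30 %), random erasure 150
(5–15 % of area, noise fill), deformation 150 (mild random affine:
scale ±10 %, shear ±0.08, translation ±5 %; boxes follow their warped
corner hulls, and a box shrunk below one pixel is dropped with a
warning), Gaussian noise 150 (σ = 1 % of dynamic range), Gaussian blur
150 (σ ∈ [1, 2] px).  Per-operation magnitudes are unstated upstream;
these defaults are chosen to be visibly mild.  Sources are drawn
uniformly without replacement per operation; validation and test splits
are never augmented.  Geometric ops transform boxes losslessly (90°
rotations, mirrors) or by corner-hull refit (affine); photometric ops
leave boxes untouched.

Mosaic augmentation exists as a minimal four-image collage behind an
on/off switch that disables itself for the final `close_mosaic_epochs`
(default 10); it is off by default and independent of the offline plan.

## Synthetic scenes

The generator stands in for the unreleased field imagery and emulates
its stated properties: leafy-green low-frequency noise backgrounds with
speckle, shaded (top-left-lit) rotated-ellipse fruits in class-
conditional colours — immature green close to the background,
semi-mature with a green-to-orange axial gradient, mature dark red —
optional leaf-shaped occluders at a configurable per-fruit rate, fruit
overlap, global brightness jitter (±20 %), and tight analytic boxes from
the rotated-ellipse extent.  Everything is deterministic under a seed.

What it does **not** emulate: real rind texture and striping, specular
highlights, branch geometry, perspective, camera noise and motion blur,
class-imbalanced label distributions, and fruit aspect ratios beyond
0.7–1.3.  Tests passing on these scenes demonstrate that the
architecture, losses, assignment, training loop and metrics function end
to end — not that field accuracy of any particular level would be
reached on real imagery.

## Training regime and desk scale

Published regime (kept as defaults): SGD, batch 64, 300 epochs, initial
learning rate 0.01, momentum 0.937, weight decay 0.0005 (applied to
weight matrices only), mosaic off for the final 10 epochs.  Warmup is
linear over 3 epochs, then linear decay to 1 % of the initial rate; the
shuffle stream is seeded per epoch so resuming from a checkpoint replays
the identical trajectory.  Pretrained-weight transfer is out of scope;
initialisation is Kaiming-style uniform under a fixed seed.

The convergence sanity check runs at desk scale: 50 synthetic 96×96
scenes (two fruits each, semi-axes 16–30 % of the side, 15 % occlusion),
batch 10, 100 epochs, evaluated on 16 held-out scenes with the
mAP@0.5 > 0.5 threshold — a trainability check, not an accuracy claim.
96 px is the smallest size at which the stride-32 level still sees a
3×3 map.  Batch normalisation uses momentum 0.03 and ε = 1e−3; mixed
precision does not exist in this stack (float32 throughout), which keeps
trajectories reproducible.

## Evaluation conventions

AP realises the precision–recall integral by 101-point interpolation of
the monotone envelope; mAP@0.5:0.95 averages thresholds 0.50–0.95 in
steps of 0.05.  Matching is greedy, confidence-ordered, one-to-one and
class-aware; mAP evaluation decodes at confidence 0.001 with class-wise
NMS at IoU 0.65 (the published test-time setting), while reported
precision/recall use confidence 0.25.  A class absent from the ground
truth has undefined AP and is excluded from the mean with a warning.
The confusion matrix (3 classes + background) matches class-agnostically
at confidence 0.25 / IoU 0.45 — display defaults, stated nowhere
upstream.  FPS is the reciprocal of the summed per-image stage means
(preprocess, inference, suppression); it is hardware-bound and never
asserted.

## Known limitations

* Inference and training run on a NumPy autograd core: correct and
  exactly profileable, but one to two orders of magnitude slower than a
  compiled GPU framework; absolute timings from the benchmark harness
  are not comparable to published wall-clock numbers.
* Deformable-convolution benchmark variants are not implemented.
* The grouped-attention matrix products are excluded from FLOP totals
  (consistent with the hook-based counters used for the published
  figures); at these widths they are ≲1 % of a model's total.
* The synthetic-scene domain gap listed above: no claim about real-field
  accuracy is made or tested.
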