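# Methods

This note documents the models, numerical choices and limitations behind
`oeyolo`, an oriented-bounding-box (OBB) detection toolkit for slender field
targets — rice panicles imaged by UAV being the motivating case.

## Oriented boxes and their canonical form

A box is `(cx, cy, w, h, θ)` in image coordinates (x right, y down, θ in
radians from the +x axis toward +y).  Rectangles are invariant under side
swaps (with a π/2 rotation) and under rotation by π, so every box has exactly
one canonical representation with `w ≥ h` and `θ ∈ [−π/2, π/2)`.  All public
functions return canonical boxes; internal regression targets may be
non-canonical, which is harmless because the losses below depend only on the
underlying rectangle.  Continuous coordinates use the half-open pixel domain
`[0, W) × [0, H)` with pixel `(r, c)` covering `[c, c+1) × [r, r+1)`; this
makes a horizontal flip `x → W − x` consistent between pixels and boxes.

## ProbIoU: probabilistic box overlap

Area IoU between rotated rectangles is non-smooth in the angle and vanishes
for non-overlapping boxes, which makes it a poor regression loss for slender
objects.  Instead each box is replaced by the 2-D Gaussian with the
rectangle's uniform-density second moments,

    μ = (cx, cy),   Σ = R(θ) diag(w²/12, h²/12) R(θ)ᵀ,

and a pair of boxes is scored by the Hellinger distance between the two
Gaussians:

    BC(p, q)     = ∫ √(p·q) dx            (Bhattacharyya coefficient)
    HD(p, q)     = √(1 − BC(p, q))
    ProbIoU(a,b) = 1 − HD(p, q) ∈ [0, 1].

For Gaussians BC has the closed form `exp(−B_D)` with

    B_D = ⅛ (μ₁−μ₂)ᵀ Σ̄⁻¹ (μ₁−μ₂) + ½ ln( det Σ̄ / √(det Σ₁ det Σ₂) ),
    Σ̄ = (Σ₁+Σ₂)/2.

Two forms of these equations circulate in the OBB-detection literature: one
without the square root inside BC and one without the radical in HD.  We
implement the standard forms above — without the √ inside BC the coefficient
of a distribution with itself is not 1, and without the radical HD is not a
metric — and expose `prob_iou(..., hellinger_sqrt=False)` to reproduce the
radical-free variant for comparison.  The w²/12 covariance scaling is the
uniform-rectangle convention of the original ProbIoU method.

Exact area IoU (`polygon_iou`, Sutherland–Hodgman clipping of convex
quadrilaterals) is used everywhere overlap is *measured* rather than
*optimized*: evaluation matching, NMS, and the synthetic generator's overlap
constraint.  ProbIoU is reserved for the training loss.

## Detector architecture

The detector follows the one-stage, anchor-free OBB design of the YOLO
family with three substitutions.

**EfficientNetV2 backbone.**  The trunk is the EfficientNetV2-S stage table
(stem conv; Fused-MBConv stages with expansions 1/4/4; MBConv stages with
expansion 4/6/6 and squeeze-excitation 0.25; the classifier stage is dropped
for detection).  Width and depth multipliers scale channels (rounded to
multiples of 8) and per-stage repeats.  Stages 3, 5 and 6 are tapped,
yielding stride-8/16/32 pyramid levels with 64/160/256 channels before
scaling.  Stochastic depth (linearly ramped drop-path, disabled at
inference) regularizes the residual blocks.

**Dynamic convolution.**  A dynamic convolution holds K parallel kernels
`W̃_k` and biases `b̃_k` and fuses them per input by attention weights from a
gating network: global average pooling over the feature map, a ReLU MLP with
hidden width `max(C/4, 4)`, and a softmax over K logits divided by a
temperature.  The fused kernel `ΣπₖW̃ₖ` is applied as one convolution; by
linearity this equals the π-weighted sum of the K individual convolution
outputs (a tested invariant).  Defaults: K = 4, temperature annealed 30 → 1
over the first 10 training epochs — values from the dynamic-convolution
literature; high early temperature keeps all kernels training before the
gate specializes.  The C3k2 cross-stage block of YOLOv11 becomes
`C3k2_DConv` by making the refinement convolution of each bottleneck
dynamic; the default configuration places C3k2_DConv in all three head
branches, with per-branch flags to ablate any subset of placements.

**Neck and OBB head.**  The deepest tap passes through SPPF (cascaded 5×5
max-pools) and C2PSA (cross-stage partial spatial self-attention), then a
PAN top-down/bottom-up fusion produces three feature maps.  Each decoupled
head branch outputs per location: one class logit per class, four side
distances as discretized distributions over `reg_max = 16` bins (decoded by
softmax expectation, in stride units, in the box's rotated frame), and one
angle logit mapped by a sigmoid-affine transform to `[−π/2, π/2)`.  A
direct-regression head (tanh-bounded offsets, sigmoid-bounded sizes) is
available by configuration.

**Parameter calibration.**  The OE-YOLO reference configuration totals
2.45 M parameters, but the width/depth multipliers behind that figure are
not part of the published architecture description.  With backbone width 0.25 / depth 0.5
and neck channels (48, 96, 188), the assembled default detector counts
2.4477 M trainable parameters (2.45 M at two decimals) and measures
4.63 GFLOPs at 608×608 (FLOPs counted as 2×MAC over convolutions, linear
maps and attention matmuls).  The neck channel triple is the calibration
knob; it was fixed once against the parameter target and not revisited.

## Training

Defaults mirror the reference protocol: SGD (momentum 0.937), initial
learning rate 0.01 with cosine annealing to lr/100, L2 weight decay 0.001,
110 epochs, 608 px inputs, batch 16.  One integer seed drives weight
initialization, data order, augmentation and stochastic depth.

**Assignment.**  The stated rule — candidates with exact IoU ≥ 0.7 against a
ground-truth box are positive — is implemented verbatim in
`assign_targets` and tested.  For the anchor-free grids, however, a literal
IoU threshold can never fire: a stride-8 cell box against a 100×14 px
panicle has IoU < 0.1 regardless of position, so training would see zero
positives.  The training loop therefore uses a center-prior assigner with
center sampling: each ground truth claims the cells whose centers fall
inside its rotated rectangle shrunk by 0.4 about the center (at least the
center row along the short side), at the single pyramid level whose cell
size still fits inside the box's short side (finest level otherwise); boxes
too small to contain any cell center claim the cell under their center;
cells claimed by several boxes go to the nearest center.  Center sampling
matters for slender targets: cells near a panicle's tips would have to
regress extreme offsets and, half-trained, yield duplicate detections that
greedy NMS cannot merge.

**Loss.**  `total = w_box · box + w_cls · cls` with `w_box = 7.5`,
`w_cls = 1`.  The box term is the mean over positives of
`1 − ProbIoU(pred, gt)`, computed on the autograd tape by the same closed
form as the geometry module (the two implementations agree to 1e−5 in
tests), plus — in distributional-regression mode — a small smooth-L1
penalty (weight 0.5, in cell units) between the decoded side distances and
the true cell-to-edge distances in the ground-truth frame.  The distance
term exists because the Gaussian overlap is nearly blind to length errors
along a slender box's major axis (that is the large-variance direction), so
with ProbIoU alone long panicles tend to split into several shorter
detections; the side-distance penalty restores that signal.
The classification term is binary cross-entropy summed over every
location of every level and normalized by the number of positives — the
detection convention that keeps the foreground gradient independent of how
many background cells the pyramid contains (a per-location mean dilutes the
~1–3% positives so much that coarse levels stay uncalibrated for the whole
schedule).  An optional positive-class weight is available (default 1).

**Initialization priors.**  The final classification convolution's bias is
initialized to −4.6 (background probability ≈ 1%), the standard dense-
detector prior that prevents an early flood of half-confident background
detections.  In the distributional box head the side-distance bins are
biased at initialization toward a slender shape — around 2–3 cells for the
long sides, under one cell for the short sides — so the first decoded boxes
already have panicle-like aspect ratios.  Both priors only shape the start
of optimization; they are ordinary trainable parameters afterwards.

**Inference.**  Detections above the confidence threshold (default 0.25)
are decoded, the top 800 by score enter exact-IoU greedy NMS at threshold
0.35 (the reference inference setting for dense canopies), and at most 300
survive.  Axis-aligned bounding boxes pre-filter NMS pairs; images are
letterboxed to a square multiple of 32 and boxes mapped back to source
coordinates.

## Synthetic scenes

The UAV dataset behind the reference results is available only on request,
so the generator emulates its geometry and statistics rather than its
radiometry: 15–40 (preset-dependent) textured capsule strokes per 608 px
scene — optionally bent into two joined segments — over low-frequency
green-brown clutter with blade-like distractor strokes.  Orientation is
uniform over `[−π/2, π/2)`; lengths 60–140 px and widths 10–18 px at the
3 m preset; the 10 m preset scales objects by 3/10; the filling preset is
denser (25–40 per scene), more overlapped (pairwise IoU cap 0.15 vs 0.05)
and golden-hued.  Ground truth is the minimum-area rotated rectangle of the
rendered mask, matching an "enclose all visible parts" annotation protocol;
rejection sampling enforces the pairwise-overlap cap.  Identical (spec,
seed) pairs render bit-identical scenes.

What passing tests on these scenes shows: the geometry, conversion,
assignment, optimization and evaluation machinery is correct end to end,
and the detector can learn slender-object localization from scratch.  What
it does not show: robustness to real-field nuisance factors — illumination,
wind blur, occlusion by leaves of the same color, perspective — which the
generator deliberately does not model.

## Scaled-down training benchmark

The repository's training benchmark trains a tiny-width configuration
(backbone width 0.125 / depth 0.25, neck (16, 24, 32), reg_max 8) for 30
epochs on 200 heading-stage 3 m scenes rendered at 608 px and trained at
288 px (a single-CPU-friendly size chosen once; ground truth is rescaled
with the images), evaluating mAP50 on 30 held-out scenes and panicle-count
error (MAPE at confidence 0.25) on the same scenes.  Augmentation is off
for this benchmark: train and validation scenes are draws from the same
generator, so regularization only slows the short schedule.  Validation
mAP uses a low confidence floor (0.05) to sweep the full precision-recall
curve.

## Numerical choices

- float32 throughout the network; closed-form ProbIoU guards: determinants
  clamped at 1e−9, `√x` backward clamped at 1e−12, BC clamped to [0, 1].
- Batch-norm eps 1e−3, momentum 0.03, running statistics at inference.
- Degenerate geometry: zero-area quads raise; `vertices_to_box` treats
  quads with opposite sides equal within 1% as exact rectangles and fits
  the minimum-area enclosing rectangle otherwise.
- AP uses all-point interpolation (precision envelope over recall steps);
  AP of a class with no ground truth and no detections is NaN and excluded
  from macro-averages.
- NMS ties (equal scores) break by lower class id, then input order.
- Tiling pads non-divisible images by reflection; boxes are clipped to each
  tile, re-fit as minimum-area rectangles and kept when the retained area
  is ≥ 30% of the original box, mirroring a "more than 30% visible"
  annotation protocol applied mechanically at tile borders.

## Known limitations

- Pure-numpy training: single-process, CPU-bound; the full 2.45 M-parameter
  configuration at 608 px trains at desk scale only for small datasets.
- Single-class focus; the class map is configurable but multi-class behavior
  is exercised only lightly.
- The exact neck wiring and head topology of the reference detector are not
  printed in full anywhere; the assembly here follows the YOLOv11
  conventions those figures depict, and the parameter calibration absorbs
  the residual ambiguity.
- The IoU-threshold assigner conflict described above is resolved by a
  design choice; other resolutions (e.g. task-aligned assignment) exist.
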