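# Methods

This note documents the model, the data pipeline, the evaluation stack and
the synthetic benchmark scenes, including the choices made where the design
space was genuinely open.

## Network architecture

The network follows the familiar one-stage segmentation layout: a
stride-2 stem, four backbone stages (each a stride-2 3×3 convolution
followed by a CSP-MUIB block), serial spatial pyramid pooling (SPPF) and a
partial pointwise-spatial-attention block (C2PSA) at the deepest level, a
fusion neck, and an anchor-free decoupled head. Width and depth scale
factors (default 0.5 each) shrink the base channel plan
[64, 128, 256, 512, 1024] and the per-stage block repeats, the convention
the YOLO family uses for its size variants.

### CSP-MUIB

A 1×1 convolution expands the input to two `hidden`-wide halves (a, b),
where `hidden = e · out_channels` with split ratio e = 0.5. Half `a` feeds
a stride-1, padding-1 3×3 max pool (so spatial resolution is preserved
literally) and is also carried through untouched as the cross-stage
connection. Half `b` runs through n residual unified inverted blocks
(ResUIB); the stack keeps every intermediate output including `b` itself.
The concatenation — pool output, n+1 stack features, cross-stage copy,
i.e. `hidden · (n+3)` channels — is fused by a final 1×1 convolution.

Each UIB uses the extra-depthwise layout (depthwise 3×3 → 1×1 expand ×E →
depthwise 3×3 → 1×1 linear project, E = 2), entirely convolutional: global
context is supplied by C2PSA and the DFS transformer instead, which keeps
the backbone blocks light. A ResUIB wraps each of its two UIBs in an
identity skip (`y = x + UIB(x)`, twice); with the final projections zeroed
the block is exactly the identity, which the tests exploit.

Stage repeats are depth-scaled from a (4, 2, 2, 2) base — two ResUIBs in
the high-resolution stage, one elsewhere at scale 0.5. Together with the
128-channel prototype-head width this places the default model at 10.39 M
parameters and 37.95 GFLOPs at 640×640, the efficiency budget of the
published operating point (10.1 M / 37.8 G, both within a few percent).

### Fusion neck

**PFA** aligns F2…F5 to the P3 grid: per-level 1×1 projection first, then
2× average pooling down or bilinear interpolation up (no corner
alignment). The initial fusion is `Conv1x1(Concat((F2'⊗F3')⊕F4', F5'))`
(⊗/⊕ element-wise). Two factorized branches — 1×3→3×1 and 1×5→5×1, each
convolution followed by batch norm and SiLU — emit C/2 channels each so
their concatenation has C channels and the residual add against `F_init`
type-checks without an extra projection.

**DFS** aligns F3…F5 to the P4 grid, computes the purely element-wise
`F_init' = (F3''⊗F4'')⊕F5''`, and refines it with the same two factorized
branches at full width C'' so their concatenation has D = 2C'' channels.
Tokens are per-pixel (N = H4·W4, depth D): a patch size of one makes the
rearrange a bit-exact bijection and needs no positional encoding. One
pre-norm transformer encoder layer (4 heads, 1/√d_k scaling, feed-forward
hidden width 2D, layer-norm eps 1e-5) provides global context; queries,
keys and values are projections of the layer-normalized input, matching
the "normalized input" wording of the design. The output channel count is
fixed by the transformer path at 2C'', so the residual 1×1 convolution
maps C'' → 2C''.

The P5 path downsamples the DFS output with a stride-2 convolution,
concatenates the P5 backbone tap and merges through one CSP-MUIB — the
only part of the neck wiring not pinned down by the block definitions, and
chosen as the minimal downsample-and-merge path.

### Head

Decoupled per-level branches on (P3, P4, P5): a box branch emitting
4·reg_max distribution-focal logits (reg_max 16), a depthwise-separable
class branch, and a mask-coefficient branch (32 coefficients). A prototype
head on P3 produces 32 stride-8 prototype maps through two 3×3
convolutions at width 128. Class-branch biases start at −log(99)
(≈ 1% prior positive rate) to keep early training stable.

Normalization everywhere is batch-style with eps 1e-3 and momentum 0.03,
activation SiLU, detector convention. Boxes are 0-based half-open pixel
(x1, y1, x2, y2); masks are image-resolution binary grids produced as
sigmoid(coefficients · prototypes), bilinearly upsampled, cropped to the
box and thresholded at 0.5.

## Numerical engine

The tensor layer is a compact reverse-mode autodiff engine on numpy:
convolutions lower to im2col + BLAS matmuls (with a shifted multiply-add
fast path for depthwise kernels), and the input gradient is computed as a
stride-dilated transposed convolution through the same lowering. Every op
is validated against central finite differences in the test suite. FLOP
counts come from an internal profiler that accumulates multiply-adds in
the convolution and matmul kernels during a profiled forward pass and
reports 2×MAC, the convention of the common detector profilers.

## Training

SGD with momentum 0.937 and weight decay 5e-4 (skipped on 1-d tensors),
linear warmup then cosine decay, gradient clipping at global norm 10, no
pretrained weights. The four-term loss is weighted 7.5 (box, complete-IoU
on decoded boxes), 0.5 (cls, BCE against soft task-aligned targets), 1.5
(dfl, two-neighbour-bin cross-entropy of the discretized offsets) and 1.0
(seg, per-positive BCE of the assembled prototype mask inside the ground
truth box, normalized by box area). Assignment is task-aligned top-k
(k = 10, metric score^0.5 · IoU^6, candidates restricted to anchors inside
the box, ties to the highest IoU) — the standard anchor-free recipe, since
the architecture definition specifies none. Dataset expansion is the
offline 6× augmentation; the loop itself does no online augmentation, so
the per-class instance accounting of the expanded table stays exact.

The overfit sanity configuration — width-0.25 model, eight 256×256
synthetic scenes (three close-range, blob-shaped plants each; the
`size_scale` zoom of the generator is set so plants span 11–16 prototype
cells), batch 4, 300 iterations, peak learning rate 0.015 with 50 warmup
steps — is sized to finish in minutes on one CPU core while reaching mask
mAP50 ≥ 0.8 on its own training scenes. Stride-8 prototypes cannot
represent plants only a few cells wide, so the sanity scenes deliberately
contain only targets above that resolving power; thin grass blades at
256² fall below it and are exercised by the box/classification paths
instead.

## Data pipeline

Annotations are polygons with derived boxes and shoelace areas; COCO-JSON
and normalized-polygon text dialects round-trip losslessly. Splits are
image-level with largest-remainder rounding (600 → 480/60/60 at 8:1:1).
Size bins follow the reference-resolution convention (1920×1088): Tiny
≤ 16², Small ≤ 32², Medium ≤ 128², Large > 128² by bounding-box area, with
coordinates from other resolutions rescaled proportionally first.

The 6× augmentation draws, per copy: rotation U(−30°, 30°) about the image
center (canvas preserved, polygons clipped to the frame), Gaussian pixel
noise σ = 5/255, translation U(−10%, 10%) of each side, vertical flip
(y → H − y, an involution), brightness factor U(0.7, 1.3). The method list
is fixed and each method contributes exactly one copy, because only a
deterministic multiplier reproduces an exact 6× instance table. Rotation
and translation parameters are re-drawn with progressively damped
magnitudes whenever a transform would push an instance (almost) fully out
of frame; the damping terminates at the identity, so no instance is ever
lost.

## Synthetic scenes

The generator emulates the statistical structure of close-range field
imagery: three shape families (broad-leaved crop rosettes, thin curved
grass blades, lobed broadleaf weeds), class-conditional green palettes
whose overlap is set by a separability knob (default 0.7 — grass and crop
deliberately share hues), soil-textured background, a directional
brightness ramp (strong under "harsh" lighting, with optional specular
spots), and a controllable occlusion rate. The default class mixture
(13.6 / 76.1 / 10.3%) and size mixture (18.5 / 25.1 / 35.7 / 20.7% over
Tiny/Small/Medium/Large) follow the instance statistics of a weed-infested
soybean plot scenario.

Class and size-bin targets are allocated exactly (largest remainder) and
instance areas are sampled log-uniformly inside each bin with a margin off
the bin edges, so that occlusion shrinkage rarely demotes an instance to a
smaller bin. Placement is a jittered shuffled grid for non-occluding
instances plus explicit edge-overlap placement for the occluding fraction;
larger plants are painted first (behind). Annotations are *visible*
polygons: each instance's polygon minus all later-painted polygons, where
occluders are eroded by ~1.5 px first so hairline overlaps (a grass blade
crossing a leaf) do not cut an annotation in two — the way human
annotators treat sub-pixel occlusion. Fully hidden instances and
annotations that would not cover a single pixel are dropped; the thinnest
sub-2 px² slivers get a minimum physical width so every annotation
rasterizes to at least one pixel. These guarantees make the self-scoring
identity exact: the generator's own annotations, fed back as predictions,
give mAP50 = mIoU = mAcc = 1.

What the scenes do **not** model: real leaf texture and venation,
perspective and depth-of-field, soil moisture variation, motion blur, and
real inter-species morphological similarity beyond palette overlap.
Passing tests on these scenes therefore demonstrate pipeline correctness
and trainability, not field-ready accuracy.

## Evaluation

Instance metrics follow the COCO convention: per-class greedy matching in
descending confidence order at IoU threshold t (highest-IoU unmatched
ground truth wins), AP by 101-point interpolation of the
precision–recall envelope, mAP50 at t = 0.5 and mAP50:95 averaged over
T = {0.50, 0.55, …, 0.95}. Precision is TP/(TP+FP) and recall TP/(TP+FN)
(0/0 → 0); reported P/R are computed from the detections as supplied, i.e.
at the confidence threshold used for inference. Pixel metrics collapse
instances to class-label grids (predicted overlaps resolved by
confidence), aggregate per-class TP/FP/FN over the whole set before
averaging, and exclude both the background and any class absent from
prediction and truth alike — the formulas index foreground classes only.
Mask IoU is computed on full-resolution binary grids.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; full-scale 640×640
  training is out of reach, which is why the training tests run the
  width-0.25 model on small synthetic scenes.
* Crowd/ignore regions, per-size AP breakdowns and panoptic quality are
  not implemented.
* The scene generator produces one visible polygon per instance (largest
  visible piece); multi-part visibility is not represented.
* Checkpoints store weights and config in a single `.npz` with a version
  tag; cross-version migration is not supported.
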