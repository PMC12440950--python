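# weednet

Lightweight instance segmentation of crops and weeds in field imagery.

Precision weeding needs a vision model that can tell a soybean leaf from a
grass blade from a broadleaf weed — per plant, with pixel-accurate masks —
while staying small enough for a robot or drone. This package implements a
YOLO-style segmentation network built around three components designed for
that regime, together with the data pipeline and the dual evaluation stack
used to measure it:

* **CSP-MUIB backbone blocks** — cross-stage-partial blocks whose transform
  branch is a stack of residual *unified inverted bottlenecks* (UIB: a
  narrow → expand → narrow channel pattern with depthwise 3×3 convolutions)
  and whose second branch is a stride-1 3×3 max pool, densely aggregated and
  fused by a 1×1 convolution.
* **PFA** (progressive feature aggregator) — fuses pyramid levels P2–P5 at
  the P3 grid: `F_init = Conv1x1(Concat((F2'⊗F3')⊕F4', F5'))`, refined by two
  factorized-convolution branches (1×3→3×1 and 1×5→5×1) whose concatenation
  is added back to `F_init`.
* **DFS** (deep feature synthesizer) — fuses P3–P5 at the P4 grid:
  `F_init' = (F3''⊗F4'')⊕F5''`, factorized branches, per-pixel tokenization,
  one transformer encoder layer for global context, and an output-channel
  residual `F_trans' ⊕ Conv1x1(F_init')`.

The head is anchor-free and decoupled: per-level class logits,
distribution-focal box offsets (reg_max 16) and 32 mask coefficients over a
shared stride-8 prototype bank.

Everything — including the tensor/autograd engine underneath — is
implemented on numpy, so the package runs anywhere scientific Python runs.
A procedural scene generator produces crop/weed imagery with instance
polygons, occlusion, size-distribution control and lighting variation, which
makes the entire pipeline testable end-to-end without any real data.

## Worked example

```pycon
>>> from weednet import ModelConfig, build_model, summarize
>>> summary = summarize(build_model(ModelConfig()), 640)
>>> print(f"{summary.parameters_m:.2f} M params, {summary.gflops:.2f} GFLOPs")
10.39 M params, 37.95 GFLOPs
```

That is the default operating point: width/depth scale 0.5, three classes,
640×640 inputs. The generator-plus-metrics loop closes exactly:

```pycon
>>> from weednet import SceneSpec, generate_dataset, evaluate
>>> from weednet.metrics import ground_truth_detections
>>> dataset, pixels = generate_dataset(SceneSpec(image_size=(160, 160), n_instances=6), 3, seed=2)
>>> report = evaluate(ground_truth_detections(dataset), dataset)
>>> report["mAP50_mask"], report["mIoU"], report["mAcc"]
(1.0, 1.0, 1.0)
```

Feeding the annotations back as perfect predictions yields mAP50 = mIoU =
mAcc = 1 exactly — the identity point both metric families must satisfy.
`examples/` contains short narrative scripts for each capability (model
summary, scene generation, augmentation accounting, evaluation, a tiny
training run).

## Command line

```bash
weednet synth --out data/demo --n-images 10 --size 320 --seed 0
weednet summary
weednet train --data data/demo --epochs 5 --batch 4 --imgsz 320 --out runs/demo
weednet eval --data data/demo --weights runs/demo/model.npz --report report.json
weednet predict --weights runs/demo/model.npz --source data/demo/images --save-overlays overlays/
```

## Evaluation stack

Instance level: precision, recall, AP by 101-point interpolation, mAP50 and
mAP50:95 (IoU thresholds 0.50–0.95 in steps of 0.05), computed separately
for boxes and masks with per-class greedy confidence-ordered matching.
Pixel level: class-averaged accuracy `mAcc = mean_i TP_i/(TP_i+FN_i)` and
IoU `mIoU = mean_i TP_i/(TP_i+FN_i+FP_i)` over foreground classes.

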