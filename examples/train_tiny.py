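"""Overfit a reduced model on a handful of synthetic scenes.

A width-0.25 network is trained for 60 iterations on four 128x128
scenes — enough to watch the four loss components fall. For the full
sanity run (300 iterations, 8 scenes at 256x256, mask mAP50 >= 0.8)
see the test suite; this script is the two-minute version.
"""

from weednet import ModelConfig, SceneSpec, build_model, generate_dataset
from weednet.training import TrainConfig, train

spec = SceneSpec(image_size=(128, 128), n_instances=3, occlusion_rate=0.1,
                 size_quota=(0.0, 0.0, 0.5, 0.5), separability=1.0)
dataset, _ = generate_dataset(spec, 4, seed=7)
model = build_model(ModelConfig(width_scale=0.25, n_classes=3, input_size=128), seed=1)
history = train(model, dataset,
                TrainConfig(batch_size=4, image_size=128, lr=0.01,
                            warmup_steps=20, seed=0, max_iterations=60))
for entry in history["epochs"][::10] + history["epochs"][-1:]:
    print(f"epoch {entry['epoch']:3d}  total {entry['total']:7.3f}  "
          f"box {entry['box']:6.3f}  cls {entry['cls']:6.3f}  "
          f"dfl {entry['dfl']:6.3f}  seg {entry['seg']:6.3f}")
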