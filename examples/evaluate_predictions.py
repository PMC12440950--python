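"""Score detections with the dual evaluation stack.

Feeding the ground truth back as predictions (confidence 1.0) gives
the identity point of both metric families: instance-level mAP50 and
pixel-level mIoU/mAcc all equal 1. Dropping one instance shows how
recall-side metrics fall while precision stays at 1.
"""

from weednet import SceneSpec, evaluate, generate_dataset
from weednet.detections import DetectionList
from weednet.metrics import ground_truth_detections

dataset, _ = generate_dataset(SceneSpec(image_size=(160, 160), n_instances=6), 3, seed=2)
perfect = ground_truth_detections(dataset)
print("perfect predictions:", {k: round(v, 3) for k, v in evaluate(perfect, dataset).items()})
partial = DetectionList(perfect.detections[1:])
print("one instance missed:", {k: round(v, 3) for k, v in evaluate(partial, dataset).items()})
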