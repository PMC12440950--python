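"""Split a dataset 8:1:1 and expand the training part six-fold.

The offline expansion adds exactly one copy per method (rotation,
noise, translation, vertical flip, brightness), so instance counts
multiply by exactly 6 — the bookkeeping a per-class instance table
relies on.
"""

from weednet import SceneSpec, augment_set, dataset_statistics, generate_dataset, split_dataset

dataset, _ = generate_dataset(SceneSpec(image_size=(160, 160), n_instances=10), 10, seed=0)
train, val, test = split_dataset(dataset, (8, 1, 1), seed=0)
print(f"split: {len(train.images)}/{len(val.images)}/{len(test.images)} images")
augmented = augment_set(train, seed=0)
print(f"train instances {len(train.instances)} -> {len(augmented.instances)} (x6)")
print("per class after:", dataset_statistics(augmented)["per_class"])
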