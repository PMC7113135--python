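"""Train a pixel classifier on synthetic patches and segment held-out ROIs.

Trains the classical (tree-ensemble) backend on 20 labeled synthetic
patches, predicts per-pixel tissue classes on held-out ROIs, transfers
labels to SLIC superpixels by majority vote, and prints pixel accuracy and
mean intersection-over-union against the generator's ground truth.
"""

import numpy as np

from hepath.pixel_classifiers import build_segmentation_model, predict_pixel_labels, train_pixel_classifier
from hepath.segmentation import mean_iou, slic_superpixels, superpixel_majority_vote
from hepath.synthetic import SyntheticSpec, generate_dataset, split_dataset

rois = generate_dataset(6, SyntheticSpec(size=192), seed=1)
train, test = split_dataset(rois, 0.25, seed=1)

model = build_segmentation_model("classical", seed=0)
train_pixel_classifier([(r.image.pixels, r.truth.labels) for r in train[:20]], model, seed=0)

accs, mious = [], []
for r in test[:4]:
    pixel_labels = predict_pixel_labels(r.image, model)
    accs.append((pixel_labels.labels == r.truth.labels).mean())
    superpixels = slic_superpixels(r.image, pixels_per_segment=100)
    voted = superpixel_majority_vote(pixel_labels, superpixels)
    mious.append(mean_iou(voted.labels, r.truth.labels))

print(f"held-out pixel accuracy:        {np.mean(accs):.4f}")
print(f"held-out superpixel-vote mIOU:  {np.mean(mious):.4f}")
print()
print("Accuracy is the per-pixel agreement with generator truth over the 8")
print("tissue classes; mIOU averages intersection-over-union across the")
print("classes present, after smoothing labels over superpixels.")
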