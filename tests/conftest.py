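"""Shared fixtures: synthetic datasets and trained desk-scale models.

Everything is generated programmatically; session scope keeps the expensive
pieces (detector training, cascade features) to a single computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from hepath.pipeline import PipelineConfig, train_roi_stage
from hepath.pixel_classifiers import build_segmentation_model, train_pixel_classifier
from hepath.segmentation import slic_superpixels, superpixel_majority_vote
from hepath.synthetic import SyntheticSpec, generate_dataset, generate_slide, ring_fixture, split_dataset

# Desk-scale study conditions: 192px ROIs with ~100px superpixels, and
# 2400px slides scanned by 600px windows with 400px overlap.
ROI_SIZE = 192
PIXELS_PER_SEGMENT = 100
SLIDE_SIZE = 2400
WINDOW = 600
OVERLAP = 400


@pytest.fixture(scope="session")
def seg_dataset():
    rois = generate_dataset(6, SyntheticSpec(size=ROI_SIZE), seed=1)
    return split_dataset(rois, 0.25, seed=1)


@pytest.fixture(scope="session")
def seg_model(seg_dataset):
    train, _ = seg_dataset
    model = build_segmentation_model("classical", seed=0)
    patches = [(r.image.pixels, r.truth.labels) for r in train[:20]]
    return train_pixel_classifier(patches, model, seed=0)


@pytest.fixture(scope="session")
def ring():
    return ring_fixture()


@pytest.fixture(scope="session")
def cascade_data():
    """Mid-level + structure features of 52 synthetic ROIs, split 40/12."""
    from hepath.diagnosis import extract_roi_features

    rois = generate_dataset(13, SyntheticSpec(size=ROI_SIZE), seed=2)
    train, test = split_dataset(rois, 0.23, seed=2)

    def featurize(group):
        feats, labels = [], []
        for r in group:
            sp = slic_superpixels(r.image, pixels_per_segment=PIXELS_PER_SEGMENT)
            sp_lab = superpixel_majority_vote(r.truth, sp)
            feats.append(extract_roi_features(sp_lab, sp, "both"))
            labels.append(r.diagnosis)
        return np.array(feats), labels

    xtr, ytr = featurize(train)
    xte, yte = featurize(test)
    return xtr, ytr, xte, yte


def make_synthetic_slide(seed: int):
    specs = [
        SyntheticSpec(size=800, diagnosis=d, seed=seed * 10 + i)
        for i, d in enumerate(("benign", "DCIS"))
    ]
    return generate_slide(SLIDE_SIZE, specs, seed=seed)


@pytest.fixture(scope="session")
def detector():
    """Detector trained on 6 synthetic slides + 2 held-out slides."""
    slides = [make_synthetic_slide(s) for s in range(8)]
    cfg = PipelineConfig(word_size=120, window=WINDOW, overlap=OVERLAP, k=16, seed=0)
    payload = train_roi_stage(slides[:6], cfg)
    return {"payload": payload, "config": cfg, "train": slides[:6], "test": slides[6:]}
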