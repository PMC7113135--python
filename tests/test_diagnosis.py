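from collections import Counter

import numpy as np
import pytest

from hepath.diagnosis import (
    CascadeTrainingError,
    EmptyInputError,
    classify,
    extract_roi_features,
    feature_names,
    identify_ducts,
    midlevel_feature_names,
    midlevel_features,
    peel_layers,
    split_midlevel,
    structure_features,
    superpixel_adjacency,
    superpixel_cooccurrence,
    superpixel_frequency,
    train_cascade,
)
from hepath.segmentation import (
    CLASS_CODES,
    CODE_TO_INDEX,
    SuperpixelMap,
    TissueLabelMap,
    superpixel_majority_vote,
)
from hepath.slide_io import DimensionError

from test_segmentation import random_label_map, random_superpixel_map


def brute_adjacency(ids):
    """All unordered 4-neighbor superpixel pairs by exhaustive pixel scan."""
    pairs = set()
    h, w = ids.shape
    for y in range(h):
        for x in range(w):
            for dy, dx in ((0, 1), (1, 0)):
                if y + dy < h and x + dx < w and ids[y, x] != ids[y + dy, x + dx]:
                    a, b = sorted((int(ids[y, x]), int(ids[y + dy, x + dx])))
                    pairs.add((a, b))
    return pairs


def sp_class_vector(lab, sp):
    return [int(lab.labels[sp.ids == s][0]) for s in range(sp.n_superpixels)]


class TestFrequency:
    def test_two_class_fractions(self):
        ids = np.arange(10).repeat(10).reshape(10, 10)
        codes = np.where(np.arange(10) < 4, 0, 4)
        lab = TissueLabelMap(codes[ids], granularity="superpixel")
        f = superpixel_frequency(lab, SuperpixelMap(ids))
        assert np.allclose(f, [0.4, 0, 0, 0.6, 0, 0, 0, 0])

    def test_single_class_unit_mass(self):
        ids = np.arange(4).repeat(4).reshape(4, 4)
        lab = TissueLabelMap(np.full((4, 4), 3, dtype=np.int64), granularity="superpixel")
        f = superpixel_frequency(lab, SuperpixelMap(ids))
        assert f[CODE_TO_INDEX[3]] == 1.0 and f.sum() == 1.0

    def test_matches_brute_force_and_raw_total(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            sp = random_superpixel_map(rng, (20, 20), 12)
            lab = superpixel_majority_vote(random_label_map(rng, (20, 20)), sp)
            raw = superpixel_frequency(lab, sp, normalize=False)
            assert raw.sum() == sp.n_superpixels
            counts = Counter(sp_class_vector(lab, sp))
            for code, idx in CODE_TO_INDEX.items():
                assert raw[idx] == counts.get(code, 0)


class TestAdjacency:
    def test_two_halves_single_pair(self):
        ids = np.zeros((6, 6), dtype=np.int64)
        ids[:, 3:] = 1
        assert superpixel_adjacency(SuperpixelMap(ids)) == {(0, 1)}

    def test_single_superpixel_no_pairs(self):
        assert superpixel_adjacency(SuperpixelMap(np.zeros((5, 5), dtype=np.int64))) == set()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            sp = random_superpixel_map(rng, (16, 16), 10)
            assert superpixel_adjacency(sp) == brute_adjacency(sp.ids)


class TestCooccurrence:
    def test_two_adjacent_classes_symmetric_mass(self):
        ids = np.zeros((6, 6), dtype=np.int64)
        ids[:, 3:] = 1
        codes = np.array([2, 3])
        lab = TissueLabelMap(codes[ids], granularity="superpixel")
        m = superpixel_cooccurrence(lab, SuperpixelMap(ids))
        i2, i3 = CODE_TO_INDEX[2], CODE_TO_INDEX[3]
        assert m[i2, i3] == m[i3, i2] == 0.5
        assert m.sum() == pytest.approx(1.0)

    def test_same_class_mass_on_diagonal(self):
        ids = np.zeros((6, 6), dtype=np.int64)
        ids[:, 3:] = 1
        lab = TissueLabelMap(np.full((6, 6), 5, dtype=np.int64), granularity="superpixel")
        m = superpixel_cooccurrence(lab, SuperpixelMap(ids))
        i5 = CODE_TO_INDEX[5]
        assert m[i5, i5] == 1.0

    def test_matches_brute_force_accumulation(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            sp = random_superpixel_map(rng, (18, 18), 12)
            lab = superpixel_majority_vote(random_label_map(rng, (18, 18)), sp)
            got = superpixel_cooccurrence(lab, sp, normalize=False)
            codes = sp_class_vector(lab, sp)
            expected = np.zeros((8, 8))
            for s, t in brute_adjacency(sp.ids):
                i, j = CODE_TO_INDEX[codes[s]], CODE_TO_INDEX[codes[t]]
                expected[i, j] += 1
                expected[j, i] += 1
            assert np.array_equal(got, expected)
            assert np.array_equal(got, got.T)
            # raw total: 2 units per adjacency pair under the symmetric rule
            assert got.sum() == 2 * len(brute_adjacency(sp.ids))


class TestMidlevelFeatures:
    def test_concatenation_layout(self):
        f = np.zeros(8)
        f[0] = 1.0
        v = midlevel_features(f, np.zeros((8, 8)))
        assert v[0] == 1.0 and v.sum() == 1.0 and len(v) == 72

    def test_split_round_trip(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(0, 1, 8)
        c = rng.uniform(0, 1, (8, 8))
        f2, c2 = split_midlevel(midlevel_features(f, c))
        assert np.array_equal(f, f2) and np.array_equal(c, c2)

    def test_names_align(self):
        assert len(midlevel_feature_names()) == 72
        assert len(feature_names("both")) == 72 + 5 * 8


class TestDucts:
    def test_ring_identified_exactly(self, ring):
        lab = superpixel_majority_vote(ring["truth"], ring["superpixels"])
        ducts = identify_ducts(lab, ring["superpixels"])
        assert len(ducts) == 1
        assert set(ducts[0].members) == ring["ring_superpixels"][1]

    def test_no_epithelium_no_ducts(self):
        ids = np.arange(9).repeat(9).reshape(9, 9)[:9, :9]
        ids = np.sort(ids)  # keep a valid partition
        lab = TissueLabelMap(np.zeros((9, 9), dtype=np.int64), granularity="superpixel")
        assert identify_ducts(lab, SuperpixelMap(np.zeros((9, 9), dtype=np.int64))) == []

    def test_two_rings_two_ducts(self):
        from hepath.synthetic import SyntheticSpec, generate_roi
        from hepath.segmentation import slic_superpixels

        roi = generate_roi(SyntheticSpec(size=192, diagnosis="benign", n_ducts=2, seed=11))
        sp = slic_superpixels(roi.image, pixels_per_segment=100)
        lab = superpixel_majority_vote(roi.truth, sp)
        assert len(identify_ducts(lab, sp)) == 2


class TestPeelLayers:
    def test_ring_layers_match_generator(self, ring):
        lab = superpixel_majority_vote(ring["truth"], ring["superpixels"])
        duct = identify_ducts(lab, ring["superpixels"])[0]
        peeled = peel_layers(duct, lab, ring["superpixels"], n_layers=2)
        rs = ring["ring_superpixels"]
        assert len(peeled.inner_layers) == 1  # lumen only, then peeling stops
        assert set(peeled.inner_layers[0]) == rs[0]
        assert set(peeled.outer_layers[0]) == rs[2]
        assert set(peeled.outer_layers[1]) == rs[3]

    def test_layers_disjoint_and_exclude_duct(self, ring):
        lab = superpixel_majority_vote(ring["truth"], ring["superpixels"])
        duct = identify_ducts(lab, ring["superpixels"])[0]
        peeled = peel_layers(duct, lab, ring["superpixels"], n_layers=3)
        all_layers = peeled.inner_layers + peeled.outer_layers
        seen = set(peeled.members)
        for layer in all_layers:
            assert not (layer & seen)
            seen |= layer

    def test_duct_without_lumen_has_no_inner_layers(self):
        # solid epithelial blob: fill_holes adds nothing -> no enclosed region
        ids = np.arange(16).repeat(16).reshape(16, 16)
        ids = np.sort(np.arange(256) // 16).reshape(16, 16)
        codes = np.where(np.arange(16) < 4, 3, 4)
        lab = TissueLabelMap(codes[ids], granularity="superpixel")
        sp = SuperpixelMap(ids)
        duct = identify_ducts(lab, sp)[0]
        peeled = peel_layers(duct, lab, sp)
        assert peeled.inner_layers == []
        assert not peeled.has_enclosed_region


class TestStructureFeatures:
    def test_ring_layer_histograms(self, ring):
        lab = superpixel_majority_vote(ring["truth"], ring["superpixels"])
        duct = peel_layers(
            identify_ducts(lab, ring["superpixels"])[0], lab, ring["superpixels"], 2
        )
        vec = structure_features([duct], lab, ring["superpixels"], 2).reshape(5, 8)
        # layout [inner_2, inner_1, duct, outer_1, outer_2]; codes (6,3,4,5)
        assert np.array_equal(vec[0], np.zeros(8))  # missing inner_2
        assert vec[1][CODE_TO_INDEX[6]] == 1.0
        assert vec[2][CODE_TO_INDEX[3]] == 1.0
        assert vec[3][CODE_TO_INDEX[4]] == 1.0
        assert vec[4][CODE_TO_INDEX[5]] == 1.0

    def test_two_identical_ducts_average_is_identity(self, ring):
        lab = superpixel_majority_vote(ring["truth"], ring["superpixels"])
        duct = peel_layers(
            identify_ducts(lab, ring["superpixels"])[0], lab, ring["superpixels"], 2
        )
        one = structure_features([duct], lab, ring["superpixels"], 2)
        two = structure_features([duct, duct], lab, ring["superpixels"], 2)
        assert np.allclose(one, two)

    def test_no_ducts_all_zero_vector(self):
        lab = TissueLabelMap(np.zeros((8, 8), dtype=np.int64), granularity="superpixel")
        sp = SuperpixelMap(np.zeros((8, 8), dtype=np.int64))
        vec = structure_features([], lab, sp, 2)
        assert vec.shape == (40,) and not vec.any()


class TestCascade:
    @pytest.fixture(scope="class")
    def separable(self):
        rng = np.random.default_rng(4)
        protos = {
            "benign": np.array([1.0, 0, 0, 0]),
            "atypia": np.array([0, 1.0, 0, 0]),
            "DCIS": np.array([0, 0, 1.0, 0]),
            "invasive": np.array([0, 0, 0, 1.0]),
        }
        x, y = [], []
        for label, p in protos.items():
            x.extend(p + rng.normal(0, 0.05, (20, 4)))
            y.extend([label] * 20)
        return np.array(x), y

    def test_separable_resubstitution_accuracy(self, separable):
        x, y = separable
        model = train_cascade(x, y, seed=0)
        pred = [classify(v, model).label for v in x]
        assert np.mean([p == t for p, t in zip(pred, y)]) == 1.0

    def test_stage_short_circuit(self, separable):
        x, y = separable
        model = train_cascade(x, y, seed=0)
        inv = classify(np.array([0, 0, 0, 1.0]), model)
        assert inv.label == "invasive"
        assert list(inv.stage_scores) == ["invasive_vs_rest"]
        dcis = classify(np.array([0, 0, 1.0, 0]), model)
        assert dcis.label == "DCIS"
        assert list(dcis.stage_scores) == [
            "invasive_vs_rest", "benign_vs_atypia_dcis", "dcis_vs_atypia",
        ]

    def test_missing_class_rejected(self, separable):
        x, y = separable
        keep = [i for i, label in enumerate(y) if label != "atypia"]
        with pytest.raises(CascadeTrainingError, match="atypia"):
            train_cascade(x[keep], [y[i] for i in keep], seed=0)

    def test_sample_order_invariance(self, separable):
        x, y = separable
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(y))
        m1 = train_cascade(x, y, seed=0)
        m2 = train_cascade(x[perm], [y[i] for i in perm], seed=0)
        probe = rng.uniform(0, 1, (20, 4))
        assert [classify(v, m1).label for v in probe] == [classify(v, m2).label for v in probe]

    def test_feature_length_checked(self, separable):
        x, y = separable
        model = train_cascade(x, y, seed=0)
        with pytest.raises(DimensionError):
            classify(np.zeros(7), model)

    def test_synthetic_holdout_accuracy(self, cascade_data):
        xtr, ytr, xte, yte = cascade_data
        model = train_cascade(xtr, ytr, seed=0)
        pred = [classify(v, model).label for v in xte]
        assert np.mean([p == t for p, t in zip(pred, yte)]) >= 0.9


class TestExtractRoiFeatures:
    def test_empty_map_rejected(self):
        with pytest.raises(EmptyInputError):
            superpixel_frequency(
                TissueLabelMap(np.zeros((0, 1), dtype=np.int64).reshape(1, 0), granularity="superpixel"),
                SuperpixelMap(np.zeros((1, 0), dtype=np.int64)),
            )

    def test_feature_vector_length(self, ring):
        lab = superpixel_majority_vote(ring["truth"], ring["superpixels"])
        v = extract_roi_features(lab, ring["superpixels"], "both", 2)
        assert v.shape == (72 + 40,)
        assert len(feature_names("both", 2)) == v.size
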