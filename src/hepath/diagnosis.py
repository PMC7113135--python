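"""ROI-level diagnosis from labeled superpixel maps.

Three feature families feed a tree-structured cascade of binary
margin classifiers:

* **Frequency** — the 8-bin histogram of superpixel tissue labels
  (one count per superpixel, normalized by superpixel count).
* **Co-occurrence** — the 8x8 histogram of tissue labels of touching
  superpixels (4-connected pixel adjacency lifted to superpixels;
  symmetric convention, L1-normalized).
* **Structure** — duct-centric layer histograms: connected epithelial
  components are the ducts; one-superpixel-wide layers are peeled toward
  the lumen (inside the duct's filled outline) and toward the stroma, and
  each layer contributes an 8-bin class histogram.

The cascade decides invasive-vs-rest first, then benign-vs-{atypia, DCIS},
then atypia-vs-DCIS, mirroring how the clinical 4-class problem decomposes
into progressively harder binary decisions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.svm import SVC

from .segmentation import (
    CLASS_CODES,
    CODE_TO_INDEX,
    CODE_TO_NAME,
    EPITHELIUM_CODES,
    N_CLASSES,
    SuperpixelMap,
    TissueLabelMap,
    superpixel_label_vector,
)
from .slide_io import DimensionError

DIAGNOSIS_CLASSES: tuple[str, ...] = ("benign", "atypia", "DCIS", "invasive")
MIN_DUCT_SUPERPIXELS = 3
DEFAULT_N_LAYERS = 2


class EmptyInputError(ValueError):
    pass


class CascadeTrainingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mid-level features
# ---------------------------------------------------------------------------


def superpixel_frequency(
    lab: TissueLabelMap, sp: SuperpixelMap, normalize: bool = True
) -> np.ndarray:
    """8-bin histogram of superpixel labels, one unit per superpixel."""
    if sp.ids.size == 0:
        raise EmptyInputError("empty superpixel map")
    codes = superpixel_label_vector(lab, sp)
    if codes.size == 0:
        raise EmptyInputError("no superpixels")
    hist = np.bincount(
        np.searchsorted(np.array(CLASS_CODES), codes), minlength=N_CLASSES
    ).astype(float)
    return hist / codes.size if normalize else hist


def superpixel_adjacency(sp: SuperpixelMap) -> set[tuple[int, int]]:
    """Unordered superpixel id pairs sharing a 4-connected pixel edge."""
    ids = sp.ids
    pairs: set[tuple[int, int]] = set()
    for a, b in ((ids[:, :-1], ids[:, 1:]), (ids[:-1, :], ids[1:, :])):
        diff = a != b
        lo = np.minimum(a[diff], b[diff])
        hi = np.maximum(a[diff], b[diff])
        pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


def superpixel_cooccurrence(
    lab: TissueLabelMap,
    sp: SuperpixelMap,
    normalize: bool = True,
    pairs: set[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Symmetric 8x8 label co-occurrence over touching superpixels.

    Each distinct-label pair adds one count at (a, b) and (b, a); each
    same-label pair adds two counts on the diagonal, so row sums track
    superpixel contact degrees consistently.  L1-normalized by default;
    an ROI with a single superpixel yields the zero matrix.
    """
    codes = superpixel_label_vector(lab, sp)
    if pairs is None:
        pairs = superpixel_adjacency(sp)
    mat = np.zeros((N_CLASSES, N_CLASSES))
    for s, t in pairs:
        i = CODE_TO_INDEX[int(codes[s])]
        j = CODE_TO_INDEX[int(codes[t])]
        mat[i, j] += 1.0
        mat[j, i] += 1.0
    if normalize:
        total = mat.sum()
        if total > 0:
            mat /= total
    return mat


def midlevel_features(frequency: np.ndarray, cooccurrence: np.ndarray) -> np.ndarray:
    """Concatenate the 8 frequency bins with the 64 row-major co-occurrence bins."""
    f = np.asarray(frequency, dtype=float).ravel()
    c = np.asarray(cooccurrence, dtype=float).ravel()
    if f.size != N_CLASSES or c.size != N_CLASSES * N_CLASSES:
        raise DimensionError(f"expected 8 + 64 entries, got {f.size} + {c.size}")
    return np.concatenate([f, c])


def split_midlevel(vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vec = np.asarray(vec, dtype=float).ravel()
    if vec.size != N_CLASSES + N_CLASSES**2:
        raise DimensionError(f"expected 72 entries, got {vec.size}")
    return vec[:N_CLASSES], vec[N_CLASSES:].reshape(N_CLASSES, N_CLASSES)


# ---------------------------------------------------------------------------
# Duct structure features
# ---------------------------------------------------------------------------


@dataclass
class DuctStructure:
    """One epithelial duct and its peeled superpixel layers."""

    duct_id: int
    members: frozenset[int]
    inner_layers: list[frozenset[int]] = field(default_factory=list)
    outer_layers: list[frozenset[int]] = field(default_factory=list)
    has_enclosed_region: bool = True


def _adjacency_lists(pairs: set[tuple[int, int]], n_sp: int) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(n_sp)]
    for s, t in pairs:
        adj[s].add(t)
        adj[t].add(s)
    return adj


def identify_ducts(
    lab: TissueLabelMap,
    sp: SuperpixelMap,
    min_duct_superpixels: int = MIN_DUCT_SUPERPIXELS,
    pairs: set[tuple[int, int]] | None = None,
) -> list[DuctStructure]:
    """Connected components of epithelial superpixels (codes 2 and 3)."""
    codes = superpixel_label_vector(lab, sp)
    epithelial = {int(s) for s in np.flatnonzero(np.isin(codes, EPITHELIUM_CODES))}
    if pairs is None:
        pairs = superpixel_adjacency(sp)
    adj = _adjacency_lists(pairs, sp.n_superpixels)
    ducts: list[DuctStructure] = []
    seen: set[int] = set()
    for start in sorted(epithelial):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            cur = frontier.pop()
            for nb in adj[cur]:
                if nb in epithelial and nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        seen |= comp
        if len(comp) >= min_duct_superpixels:
            ducts.append(DuctStructure(duct_id=len(ducts), members=frozenset(comp)))
    return ducts


def peel_layers(
    duct: DuctStructure,
    lab: TissueLabelMap,
    sp: SuperpixelMap,
    n_layers: int = DEFAULT_N_LAYERS,
    pairs: set[tuple[int, int]] | None = None,
) -> DuctStructure:
    """Peel one-superpixel-wide layers toward the lumen and toward the stroma.

    The enclosed (lumen-side) region is found by filling holes of the duct's
    pixel mask; a non-duct superpixel is *inside* when the majority of its
    pixels fall in the filled-minus-mask region.  Inner layer 1 is the
    inside superpixels touching the duct; layer k+1 the unassigned inside
    superpixels touching layer k.  Outer layers peel identically over the
    outside superpixels.  Peeling stops early at an empty layer.
    """
    if pairs is None:
        pairs = superpixel_adjacency(sp)
    adj = _adjacency_lists(pairs, sp.n_superpixels)
    member_mask = np.isin(sp.ids, np.array(sorted(duct.members)))
    filled = ndimage.binary_fill_holes(member_mask)
    enclosed = filled & ~member_mask
    n_sp = sp.n_superpixels
    inside_counts = np.bincount(sp.ids[enclosed].ravel(), minlength=n_sp)
    sp_sizes = np.bincount(sp.ids.ravel(), minlength=n_sp)
    inside = {
        int(s)
        for s in np.flatnonzero(inside_counts * 2 > sp_sizes)
        if s not in duct.members
    }
    has_enclosed = bool(enclosed.any())

    def peel(region: set[int]) -> list[frozenset[int]]:
        layers: list[frozenset[int]] = []
        assigned = set(duct.members)
        frontier = set(duct.members)
        for _ in range(n_layers):
            layer = {
                nb
                for cur in frontier
                for nb in adj[cur]
                if nb in region and nb not in assigned
            }
            if not layer:
                break
            layers.append(frozenset(layer))
            assigned |= layer
            frontier = layer
        return layers

    outside = set(range(n_sp)) - duct.members - inside
    return DuctStructure(
        duct_id=duct.duct_id,
        members=duct.members,
        inner_layers=peel(inside),
        outer_layers=peel(outside),
        has_enclosed_region=has_enclosed,
    )


def _layer_histogram(superpixels: frozenset[int] | set[int], codes: np.ndarray) -> np.ndarray:
    if not superpixels:
        return np.zeros(N_CLASSES)
    idx = [CODE_TO_INDEX[int(codes[s])] for s in sorted(superpixels)]
    hist = np.bincount(idx, minlength=N_CLASSES).astype(float)
    return hist / len(superpixels)


def structure_features(
    ducts: list[DuctStructure],
    lab: TissueLabelMap,
    sp: SuperpixelMap,
    n_layers: int = DEFAULT_N_LAYERS,
) -> np.ndarray:
    """ROI-level duct-layer feature vector, averaged over ducts.

    Per duct, layer blocks are ordered [inner_n .. inner_1, duct,
    outer_1 .. outer_n]; each block is an 8-bin class histogram over the
    layer's superpixels (all-zero for a missing layer).  Duct matrices are
    averaged into one (2*n_layers + 1) * 8 vector; an ROI with no ducts
    yields the all-zero vector.
    """
    width = (2 * n_layers + 1) * N_CLASSES
    if not ducts:
        return np.zeros(width)
    codes = superpixel_label_vector(lab, sp)
    mats = []
    for duct in ducts:
        blocks = []
        for i in range(n_layers - 1, -1, -1):
            layer = duct.inner_layers[i] if i < len(duct.inner_layers) else frozenset()
            blocks.append(_layer_histogram(layer, codes))
        blocks.append(_layer_histogram(duct.members, codes))
        for i in range(n_layers):
            layer = duct.outer_layers[i] if i < len(duct.outer_layers) else frozenset()
            blocks.append(_layer_histogram(layer, codes))
        mats.append(np.concatenate(blocks))
    return np.mean(mats, axis=0)


def structure_feature_names(n_layers: int = DEFAULT_N_LAYERS) -> list[str]:
    layers = [f"inner_{i}" for i in range(n_layers, 0, -1)] + ["duct"] + [
        f"outer_{i}" for i in range(1, n_layers + 1)
    ]
    return [f"struct_{layer}_{CODE_TO_NAME[c]}" for layer in layers for c in CLASS_CODES]


def midlevel_feature_names() -> list[str]:
    names = [f"freq_{CODE_TO_NAME[c]}" for c in CLASS_CODES]
    names += [
        f"cooc_{CODE_TO_NAME[ci]}_{CODE_TO_NAME[cj]}"
        for ci in CLASS_CODES
        for cj in CLASS_CODES
    ]
    return names


def write_feature_csv(path: str, rows: list[np.ndarray], names: list[str],
                      labels: list[str] | None = None) -> None:
    """Feature matrix as CSV with one named column per bin."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = list(names) + (["diagnosis"] if labels is not None else [])
        writer.writerow(header)
        for i, row in enumerate(rows):
            out = [f"{v:.10g}" for v in np.asarray(row).ravel()]
            if labels is not None:
                out.append(labels[i])
            writer.writerow(out)


# ---------------------------------------------------------------------------
# Cascade classifier
# ---------------------------------------------------------------------------


@dataclass
class DiagnosisResult:
    label: str
    stage_scores: dict[str, float]


@dataclass
class CascadeModel:
    """Three binary stages: invasive|rest, benign|{atypia,DCIS}, DCIS|atypia."""

    stage_invasive: SVC
    stage_benign: SVC
    stage_dcis: SVC
    n_features: int
    seed: int = 0

    def stage_arrays(self) -> list[np.ndarray]:
        out = []
        for svm in (self.stage_invasive, self.stage_benign, self.stage_dcis):
            out.extend([svm.support_vectors_.copy(), svm.dual_coef_.copy(),
                        np.atleast_1d(svm.intercept_).copy()])
        return out


def _canonical_order(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    keys = np.column_stack([y.astype(float), x])
    return np.lexsort(keys.T[::-1])


def _fit_stage(x: np.ndarray, y: np.ndarray, seed: int, C: float) -> SVC:
    order = _canonical_order(x, y)
    svm = SVC(kernel="linear", C=C, random_state=seed)
    svm.fit(x[order], y[order])
    return svm


def train_cascade(
    features: np.ndarray, labels: list[str], seed: int = 0, C: float = 10.0
) -> CascadeModel:
    """Fit the three cascade stages; every diagnosis class must be present."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    missing = [c for c in DIAGNOSIS_CLASSES if c not in set(y.tolist())]
    if missing:
        raise CascadeTrainingError(f"missing diagnosis class(es): {missing}")
    s1 = _fit_stage(x, (y == "invasive").astype(int), seed, C)
    ni = y != "invasive"
    s2 = _fit_stage(x[ni], (y[ni] == "benign").astype(int), seed, C)
    ad = np.isin(y, ["atypia", "DCIS"])
    s3 = _fit_stage(x[ad], (y[ad] == "DCIS").astype(int), seed, C)
    return CascadeModel(s1, s2, s3, n_features=x.shape[1], seed=seed)


def classify(features: np.ndarray, model: CascadeModel) -> DiagnosisResult:
    """Run the cascade: each stage short-circuits on a positive decision."""
    x = np.asarray(features, dtype=float).ravel()
    if x.size != model.n_features:
        raise DimensionError(f"expected {model.n_features} features, got {x.size}")
    x2 = x[None, :]
    scores: dict[str, float] = {}
    s1 = float(model.stage_invasive.decision_function(x2)[0])
    scores["invasive_vs_rest"] = s1
    if s1 >= 0:
        return DiagnosisResult("invasive", scores)
    s2 = float(model.stage_benign.decision_function(x2)[0])
    scores["benign_vs_atypia_dcis"] = s2
    if s2 >= 0:
        return DiagnosisResult("benign", scores)
    s3 = float(model.stage_dcis.decision_function(x2)[0])
    scores["dcis_vs_atypia"] = s3
    return DiagnosisResult("DCIS" if s3 >= 0 else "atypia", scores)


def extract_roi_features(
    lab: TissueLabelMap,
    sp: SuperpixelMap,
    feature_set: str = "both",
    n_layers: int = DEFAULT_N_LAYERS,
) -> np.ndarray:
    """Convenience: mid-level and/or structure features of one labeled ROI."""
    pairs = superpixel_adjacency(sp)
    parts = []
    if feature_set in ("midlevel", "both"):
        freq = superpixel_frequency(lab, sp)
        cooc = superpixel_cooccurrence(lab, sp, pairs=pairs)
        parts.append(midlevel_features(freq, cooc))
    if feature_set in ("structure", "both"):
        ducts = [
            peel_layers(d, lab, sp, n_layers, pairs=pairs)
            for d in identify_ducts(lab, sp, pairs=pairs)
        ]
        parts.append(structure_features(ducts, lab, sp, n_layers))
    if not parts:
        raise ValueError(f"unknown feature_set {feature_set!r}")
    return np.concatenate(parts)


def feature_names(feature_set: str = "both", n_layers: int = DEFAULT_N_LAYERS) -> list[str]:
    names: list[str] = []
    if feature_set in ("midlevel", "both"):
        names += midlevel_feature_names()
    if feature_set in ("structure", "both"):
        names += structure_feature_names(n_layers)
    return names
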