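# Methods

This note documents the models, parameter choices, and numerical
conventions behind `hepath`, and what the synthetic benchmarks do and do
not demonstrate.

## Coordinate and tiling conventions

Coordinates are 0-based with `x` the column, `y` the row; rectangles are
half-open `[x, x+w) × [y, y+h)`.  Word tiling anchors a non-overlapping
grid at (0,0) and discards partial border tiles — words feed fixed-length
histograms, so padding would distort them.  Sliding windows advance by
`window − overlap` (defaults 3600 − 2400 = 1200 px at ×40) and the final
window is clamped to the image edge so every pixel is covered; an image
smaller than one window yields a single whole-image window flagged as
undersized.  Inputs whose nominal magnification is not ×40 are accepted
with a logged warning, since all pixel-size defaults assume ×40 sampling.

## Stain model

Optical density is `OD = −log10((I + 1)/255)` per channel, the `+1`
guarding `log 0`; base 10 is a convention (any base rescales concentrations
uniformly) fixed for reproducibility.  Macenko estimation keeps pixels
with all OD channels above 0.15, projects them onto the top-two principal
directions of the OD cloud, and reads the 1st/99th percentile extreme
angles as the stain directions; the robust maximum concentration is the
99th percentile.  These are the standard Macenko defaults and are all
exposed in configuration.  Hematoxylin is the direction with the larger
blue-channel OD weight — a deterministic ordering that downstream code
relies on.  Normalization unmixes with the image's own stains, rescales
each stain's robust maximum to the package reference (Ruifrok–Johnston
H&E directions), and re-renders.  Per-slide estimation normalized to the
fixed package reference is the default; a caller can pass any reference.

Numerical note: uint8 quantization alone contributes up to ~1.5% relative
concentration error at low concentrations (ΔOD ≈ 0.5/(ln10·(I+1)) per
half-level).  Accuracy claims about the unmixing itself are therefore
stated on the continuous forward model, with separate quantized-image
bounds (±2 intensity levels on reconstruction round trips).

## ROI detector

Word descriptors concatenate an 8×8×8 CIELAB histogram (512 bins; L in
[0,100], a and b in [−128,128]) with 59-bin non-rotation-invariant uniform
LBP histograms (8 neighbors, radius 1) of the hematoxylin and eosin
concentration channels, each part L1-normalized.  Bin counts and the LBP
variant are unspecified upstream; these are standard values, fixed as
defaults and configurable.  Concentrations come from the fixed package
reference stains rather than per-word estimation, so blank words (no
tissue) are still describable.  The dictionary is k-means (default k=64,
single seeded init) with centroids sorted lexicographically so the model
is independent of k-means' internal ordering.  Bag histograms are
L1-normalized because clamped border windows hold fewer words.  Window
labeling for training: positive when ≥50% of the window area lies in a
truth ROI; negative when the window has zero truth overlap but its center
is within one window (3600 px) of a truth rectangle; other windows are
unused.  Overlapping positive windows are merged as connected components
of the pairwise-overlap graph, reported as bounding boxes.  Inference uses
no randomness.

Evaluation convention: recall is measured over ≥50%-overlap windows;
precision counts a flagged window as correct when it touches a truth ROI
at all, since boundary-straddling windows genuinely contain tissue.

## Tissue segmentation

Class codes follow the published 0, 2–8 scheme; code 1 is
reserved-unused and rejected (never remapped) wherever labels enter the
system.  SLIC runs in CIELAB with compactness 10, target superpixel area
`pixel_count / 3000` at full ×40 scale, minimum segment size 25% of
target; a post-pass relabels so every id is exactly one 4-connected
region.  When the requested segment count is so small that skimage's
seeding grid collapses, the request is internally doubled until the
returned count respects the `S ≥ n_segments/2` contract.

Two pixel-classifier backends share one interface:

* **Encoder-decoder (numpy).**  Two stride-2 encoder stages of efficient
  spatial-pyramid blocks (parallel 3×3 convolutions at dilations 1 and 2,
  concatenated with a residual), each stage concatenating an average-
  pooled copy of the raw input (input-aware encoding); decoder stages at
  1/2 and full resolution concatenate resized features from *all* encoder
  stages (dense connections); each decoder resolution has its own 1×1
  classification head and the per-path logits are summed at input
  resolution before the softmax (multi-path fusion).  Training is Adam on
  mean per-pixel cross-entropy, float64 throughout, hand-written backward
  passes verified against numerical gradients; training is bit-
  reproducible for a fixed seed.  Width and patch size are configurable;
  the default patch is 384 px, and desk-scale configurations (width 4–8,
  64–96 px patches) train in seconds to minutes on one CPU.
* **Classical.**  A 13-feature per-pixel stack (RGB, CIELAB, H&E
  concentrations, Gaussian-smoothed CIELAB at σ=1.5 and σ=4, local
  contrast) classified by a seeded extremely-randomized-trees ensemble
  (40 trees, ≤2000 pixels sampled per training patch).  It is the default
  backend: deterministic, data-efficient, and fast enough to serve as the
  reference implementation for everything downstream.

Whole-image inference tiles the raster with 50% overlap, averages class
scores over overlapping tiles (seam suppression), and takes the per-pixel
argmax with ties broken toward the lowest class code.  Majority-vote label
transfer breaks ties toward the lowest code as well; every tie-break in
the package resolves toward the lowest code or index for determinism.

## Diagnosis

Frequency counts one unit per superpixel (not per pixel): the feature is a
*superpixel label* histogram; a pixel-weighted mode exists in
configuration.  Adjacency is 4-connected at pixel level (8-connectivity
configurable).  Co-occurrence is symmetric: a touching pair with labels
a≠b adds one count at (a,b) and (b,a); a same-label pair adds two counts
to the diagonal, so row sums track superpixel contact degrees; the matrix
is L1-normalized before classification.  Mid-level features concatenate
the 8 frequency bins with the 64 row-major co-occurrence bins.

Ducts are connected components (superpixel adjacency) of epithelial
superpixels (codes 2 and 3) with at least 3 members.  The enclosed region
is the fill-holes of the duct's pixel mask minus the mask; a superpixel is
*inside* when the majority of its pixels fall there.  Inner layer 1 is the
inside superpixels adjacent to the duct, layer k+1 the unassigned inside
superpixels adjacent to layer k; outer layers peel identically over the
remaining superpixels; peeling stops at an empty layer.  Two layers per
side is the default.  Structure features order blocks
[inner_n … inner_1, duct, outer_1 … outer_n], each an 8-bin class
histogram over the layer's superpixels (all-zero for a missing layer), and
average the per-duct matrices into one ROI vector — averaging rather than
concatenation keeps the feature length independent of duct count; a
concatenate-top-k mode is left to configuration.

The cascade trains three binary linear SVMs: invasive vs. rest on all
samples, benign vs. {atypia, DCIS} on non-invasive samples, DCIS vs.
atypia on the remainder; classification short-circuits at the first
positive stage.  This stage order puts the easiest, most consequential
decision first.  Training samples are canonically sorted (label, then
feature lexicographic) before fitting, so fitted models are independent of
the caller's sample order.

## Synthetic data generator

The generator emulates the structural cues the pipeline exploits, not
histology realism: ducts are concentric disks (lumen inside an epithelial
ring) on a stroma background; the diagnosis class sets the composition —
benign: thin benign-epithelium rings, open lumina, ~5% desmoplastic
stroma; atypia: thick benign-epithelium rings, secretion lumina, ~20%;
DCIS: malignant-epithelium rings with central necrosis, ~45%; invasive:
small malignant rings plus scattered malignant islands and blood specks,
~75%.  The desmoplastic fraction is realized by thresholding a smoothed
Gaussian field at the matching quantile, so requested fractions are met
exactly on the stroma region.  Pixels render as per-class base color plus
class-specific sinusoidal texture plus Gaussian noise (σ=7), so both color
and LBP histograms are class-informative.  Every artifact is a pure
function of spec and seed.  A separate concentric-ring fixture draws a
duct as exact annuli split into angular-sector superpixels with recorded
ring indices — the oracle for layer peeling.

What passing these benchmarks shows: the geometry, features, training,
and inference machinery are correct and deterministic, and each trainable
stage can recover ground truth it is expressive enough to represent.
What they do not show: performance on real H&E tissue, whose intra-class
texture variation, staining variability, nuclei-scale structure, and
ambiguous class boundaries the generator deliberately omits.  Published
clinical accuracies (0.72 ROI accuracy, 0.44 mIOU, 0.94/0.70/0.83 cascade)
belong to the original proprietary 240-case/428-ROI dataset and are out of
scope here.

## Desk-scale study conditions

All defaults target ×40 whole-slide scale (120 px words, 3600/2400 px
windows, ~3000 px² superpixels).  The test suite and acceptance script
exercise the identical code paths at reduced scale so everything runs on
one CPU in minutes, as a package choice: 2400 px slides with 800 px tissue
blocks scanned by 600 px windows with 400 px overlap (same stride
arithmetic; the 120/3600/2400 defaults are verified exactly in the
geometry checks); 192 px ROIs with ~100 px² superpixels (about 12 px
across — large enough to be labeling units, small enough to resolve duct
rings at this scale); dictionary k=16 and 8; segmentation from 20 training
patches, evaluation on 4 held-out ROIs; cascade from 40 training ROIs,
12 held-out.  Geometry logic is size-independent, so nothing in the code
distinguishes the two scales.

## Known limitations

* The encoder-decoder is a faithful-but-small realization of the named
  architectural ideas; exact block widths and connection points of the
  original large-scale network are not published and are configurable
  here.  At desk scale the classical backend is more accurate per second
  of training and is therefore the default.
* Pyramidal/SVS slide formats are out of scope (plain TIFF/PNG/JPEG/BMP
  rasters only), as are stitching and slide-metadata parsing.
* `estimate_stains` assumes two stains and enough stain-dominated pixels;
  blank or single-color images raise an insufficient-tissue error rather
  than returning a degenerate matrix.
* Duct identification assumes epithelium forms connected rings after
  majority-vote labeling; fragmented rings (under-segmentation or poor
  pixel predictions) split into multiple small ducts or fall below the
  3-superpixel minimum.
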