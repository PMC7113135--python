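"""Estimate H&E stain vectors from a synthetic image and unmix it.

Builds a Beer-Lambert forward model with known hematoxylin/eosin optical-
density directions, renders an RGB image, then recovers the stain vectors
with the Macenko procedure and the per-pixel concentrations by
least-squares unmixing.  The printed angular errors (degrees) and relative
concentration error show how closely the known physics is recovered.
"""

import numpy as np

from hepath.stain import (
    StainMatrix,
    angular_error_deg,
    deconvolve,
    estimate_stains,
    od_to_rgb,
)

rng = np.random.default_rng(0)
truth = StainMatrix(np.array([0.60, 0.66, 0.46]), np.array([0.30, 0.88, 0.37]))

# Three pixel populations, as real tissue has: hematoxylin-dominated
# (nuclei), eosin-dominated (cytoplasm/stroma), and mixed.
n = 2000
c_h = np.concatenate([rng.uniform(0.5, 1.4, n), rng.uniform(0, 0.02, n), rng.uniform(0.3, 1.0, n)])
c_e = np.concatenate([rng.uniform(0, 0.02, n), rng.uniform(0.5, 1.2, n), rng.uniform(0.2, 0.8, n)])
image = od_to_rgb(np.stack([c_h, c_e], -1) @ truth.matrix.T).reshape(100, 60, 3)

estimated = estimate_stains(image)
print("hematoxylin angular error: %.3f deg" % angular_error_deg(estimated.hematoxylin, truth.hematoxylin))
print("eosin angular error:       %.3f deg" % angular_error_deg(estimated.eosin, truth.eosin))

concentrations = deconvolve(image, truth)
err = np.abs(concentrations.reshape(-1, 2)[:, 0] - c_h).sum() / c_h.sum()
print("hematoxylin concentration error: %.2f%%" % (100 * err))
print()
print("Sub-degree angles mean the two stain directions were recovered almost")
print("exactly from pixel statistics alone; the concentration error is the")
print("residual of unmixing every pixel back into stain amounts.")
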