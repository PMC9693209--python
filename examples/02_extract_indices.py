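"""Compute the eight chlorophyll-fluorescence indices of one sample.

Segments a synthetic cube, averages the leaf spectrum over the region
of interest, and evaluates the indices on that mean spectrum — the
per-sample feature vector the classifiers consume.
"""

import numpy as np

from fluorostress import BandLookup, SceneParams, index_vector, roi_mean_spectrum, segment_cube
from fluorostress.synthetic import make_scene

for label in ("controlled", "stressed", "recovered"):
    rng = np.random.default_rng(42)
    cube, _ = make_scene(SceneParams(seed=42), label, rng)
    mask = segment_cube(cube)
    spectrum = roi_mean_spectrum(cube, mask)
    vec = index_vector(spectrum, BandLookup.build(cube.wavelengths))
    print(f"{label:>10}: " + "  ".join(f"{k}={v:+.3f}" for k, v in vec.as_dict().items()))
# Healthy (controlled) leaves absorb more at 676/635 nm, so their
# normalized-difference and ratio indices (psnd_a, pssr_a, ...) exceed the
# stressed values; recovered sits between the two, nearer stressed.
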