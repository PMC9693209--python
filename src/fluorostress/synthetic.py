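"""Synthetic hyperspectral scenes with class-conditional leaf spectra.

The generator emulates the structure the analysis assumes in VNIR
fluorescence-reflectance cubes of potted strawberry plants: dark
background, bright leaf-shaped blobs, and leaf spectra with

* a low visible floor (500-600 nm),
* Gaussian chlorophyll absorption dips at 676 nm (chl a) and 635 nm
  (chl b), sigma ~ 15 nm,
* a logistic red-edge rise to an NIR plateau (760-900 nm),
* multiplicative band-independent Gaussian noise.

Three plant states are modelled. Healthy (controlled) leaves carry the
most chlorophyll: deepest absorption dips and the longest red-edge
position. Heat/water stress lowers chlorophyll: shallower dips, the red
edge retreats to shorter wavelengths. Recovered plants sit between the
two, deliberately nearer the stressed state so that the stressed and
recovered classes overlap — the regime in which stress staging is
actually hard. Effect sizes are the generator's own calibrated
defaults; no claim is made that they match any particular real plants.

The closed form of a noise-free leaf spectrum:

    R(lam) = clip( [floor + (plateau - floor) * sigmoid((lam - c)/w)]
                   * (1 - d676 * g(lam; 676, 15) - d635 * g(lam; 635, 15))
                   * (1 + eps), 0, 1)

with g a unit-height Gaussian and eps ~ N(0, noise_sd) per band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, fields as dataclass_fields

import numpy as np
import pandas as pd
from skimage.draw import ellipse

from .hsi_io import HyperspectralCube
from .indices import BandLookup, index_vector
from .features import make_table, clean_table
from .segmentation import EmptyROIError, roi_mean_spectrum, segment_cube

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralParams",
    "SceneParams",
    "DEFAULT_CLASS_PARAMS",
    "DEFAULT_JITTER",
    "default_wavelengths",
    "leaf_spectrum",
    "make_scene",
    "make_dataset",
    "interpolate_params",
    "class_params_with_gap",
]

#: Instrument grid the defaults emulate: 128 bands, 397-1003 nm
#: (~4.77 nm spacing).
N_BANDS = 128
WL_MIN, WL_MAX = 397.0, 1003.0

DIP_SIGMA_NM = 15.0
DIP_A_NM = 676.0
DIP_B_NM = 635.0


def default_wavelengths(n_bands: int = N_BANDS) -> np.ndarray:
    return np.linspace(WL_MIN, WL_MAX, n_bands)


@dataclass(frozen=True)
class SpectralParams:
    """Parameters of one leaf-spectrum archetype.

    All reflectance-valued fields are in [0, 1]; wavelengths in nm.
    """

    nir_plateau: float
    visible_floor: float
    dip676_depth: float
    dip635_depth: float
    rededge_center: float
    rededge_width: float
    noise_sd: float = 0.04

    def __post_init__(self) -> None:
        for name in ("nir_plateau", "visible_floor", "dip676_depth", "dip635_depth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 680.0 < self.rededge_center < 760.0:
            raise ValueError("rededge_center must lie in (680, 760) nm")


#: Calibrated class archetypes (controlled = healthy chamber plants;
#: stressed = after 6 days of 35 C heat without water; recovered = after
#: a 15-day return to control conditions, placed nearer stressed).
DEFAULT_CLASS_PARAMS: dict[str, SpectralParams] = {
    "controlled": SpectralParams(
        nir_plateau=0.55, visible_floor=0.08,
        dip676_depth=0.60, dip635_depth=0.42,
        rededge_center=722.0, rededge_width=16.0,
    ),
    "recovered": SpectralParams(
        nir_plateau=0.52, visible_floor=0.095,
        dip676_depth=0.46, dip635_depth=0.31,
        rededge_center=710.0, rededge_width=18.0,
    ),
    "stressed": SpectralParams(
        nir_plateau=0.50, visible_floor=0.10,
        dip676_depth=0.40, dip635_depth=0.26,
        rededge_center=705.0, rededge_width=19.0,
    ),
}

#: Between-plant variability: absolute s.d. of each parameter across
#: samples of one class (calibrated once with the class archetypes).
DEFAULT_JITTER: dict[str, float] = {
    "nir_plateau": 0.03,
    "visible_floor": 0.008,
    "dip676_depth": 0.028,
    "dip635_depth": 0.024,
    "rededge_center": 2.5,
    "rededge_width": 1.2,
}

#: Effective ROI pixel count the fast (spectrum-level) mode emulates:
#: averaging N leaf pixels shrinks band noise by sqrt(N).
FAST_MODE_ROI_PIXELS = 400


@dataclass(frozen=True)
class SceneParams:
    """Geometry and composition of a synthetic scene set."""

    shape: tuple[int, int] = (128, 128)
    n_blobs: int = 3
    blob_radius_range: tuple[float, float] = (10.0, 22.0)
    background_level: float = 0.04
    class_params: dict[str, SpectralParams] | None = None
    counts: dict[str, int] | None = None
    seed: int = 0
    n_bands: int = N_BANDS

    def resolved_class_params(self) -> dict[str, SpectralParams]:
        params = self.class_params or DEFAULT_CLASS_PARAMS
        _check_class_ordering(params)
        return params

    def resolved_counts(self) -> dict[str, int]:
        return self.counts or {"controlled": 45, "stressed": 43, "recovered": 43}


def _check_class_ordering(params: dict[str, SpectralParams]) -> None:
    """The stages must be spectrally ordered: controlled >= recovered >=
    stressed in dip depth and red-edge position."""
    c, r, s = params["controlled"], params["recovered"], params["stressed"]
    ok = (
        c.dip676_depth >= r.dip676_depth >= s.dip676_depth
        and c.dip635_depth >= r.dip635_depth >= s.dip635_depth
        and c.rededge_center >= r.rededge_center >= s.rededge_center
    )
    if not ok:
        raise ValueError("class parameters violate controlled >= recovered >= stressed ordering")


def _unit_gaussian(lam: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def leaf_spectrum(
    params: SpectralParams, wavelengths: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one leaf reflectance spectrum from the archetype."""
    lam = np.asarray(wavelengths, dtype=float)
    base = params.visible_floor + (params.nir_plateau - params.visible_floor) / (
        1.0 + np.exp(-(lam - params.rededge_center) / params.rededge_width)
    )
    absorb = (
        1.0
        - params.dip676_depth * _unit_gaussian(lam, DIP_A_NM, DIP_SIGMA_NM)
        - params.dip635_depth * _unit_gaussian(lam, DIP_B_NM, DIP_SIGMA_NM)
    )
    noise = 1.0 + rng.normal(0.0, params.noise_sd, size=lam.shape) if params.noise_sd else 1.0
    return np.clip(base * absorb * noise, 0.0, 1.0)


def _jitter_params(
    params: SpectralParams, rng: np.random.Generator, jitter: dict[str, float] | None
) -> SpectralParams:
    jitter = DEFAULT_JITTER if jitter is None else jitter
    updates = {}
    for f in dataclass_fields(params):
        sd = jitter.get(f.name, 0.0)
        if sd:
            updates[f.name] = getattr(params, f.name) + rng.normal(0.0, sd)
    p = replace(params, **updates)
    # keep jittered draws physical
    return replace(
        p,
        nir_plateau=float(np.clip(p.nir_plateau, 0.05, 1.0)),
        visible_floor=float(np.clip(p.visible_floor, 0.0, p.nir_plateau)),
        dip676_depth=float(np.clip(p.dip676_depth, 0.0, 0.95)),
        dip635_depth=float(np.clip(p.dip635_depth, 0.0, 0.95)),
        rededge_center=float(np.clip(p.rededge_center, 680.5, 759.5)),
        rededge_width=float(np.clip(p.rededge_width, 5.0, 40.0)),
    )


def make_scene(
    scene: SceneParams, label: str, rng: np.random.Generator
) -> tuple[HyperspectralCube, np.ndarray]:
    """Render one cube of the given class plus its ground-truth mask.

    Background pixels get a flat low spectrum with multiplicative noise;
    each leaf blob draws a jittered archetype, and every leaf pixel adds
    a small extra jitter on top so leaves are not uniform.
    """
    rows, cols = scene.shape
    wl = default_wavelengths(scene.n_bands)
    params = scene.resolved_class_params()[label]

    mask = np.zeros((rows, cols), dtype=bool)
    blob_ids = np.full((rows, cols), -1, dtype=int)
    for b in range(scene.n_blobs):
        r0, r1 = scene.blob_radius_range
        ra, rb = rng.uniform(r0, r1, size=2)
        cy = rng.uniform(max(ra, 1), rows - max(ra, 1))
        cx = rng.uniform(max(rb, 1), cols - max(rb, 1))
        rr, cc = ellipse(cy, cx, ra, rb, shape=(rows, cols), rotation=rng.uniform(0, np.pi))
        mask[rr, cc] = True
        blob_ids[rr, cc] = b

    data = np.empty((rows, cols, scene.n_bands))
    bg = scene.background_level * (
        1.0 + rng.normal(0.0, 0.10, size=(rows, cols, scene.n_bands))
    )
    data[:] = np.clip(bg, 0.0, 1.0)

    pixel_jitter = {k: v * 0.2 for k, v in DEFAULT_JITTER.items()}
    for b in range(scene.n_blobs):
        sel = blob_ids == b
        n_px = int(sel.sum())
        if n_px == 0:
            logger.warning("blob %d fell outside the image or was occluded", b)
            continue
        blob_params = _jitter_params(params, rng, None)
        spectra = np.stack(
            [
                leaf_spectrum(_jitter_params(blob_params, rng, pixel_jitter), wl, rng)
                for _ in range(n_px)
            ]
        )
        data[sel] = spectra

    cube = HyperspectralCube(data, wl, source=f"synthetic:{label}")
    return cube, mask


def make_dataset(
    scene: SceneParams | None = None,
    mode: str = "fast",
    jitter: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Generate the full labelled feature table.

    ``mode="fast"`` draws one jittered ROI-mean-like spectrum per sample
    (band noise shrunk by sqrt of the nominal ROI size) and evaluates
    the eight indices directly. ``mode="pipeline"`` renders each cube,
    segments it, takes the ROI mean and then the indices — the complete
    three-phase path; samples whose segmentation fails are dropped with a
    logged id. Both are fully reproducible from ``scene.seed``.
    """
    scene = scene or SceneParams()
    rng = np.random.default_rng(scene.seed)
    wl = default_wavelengths(scene.n_bands)
    lookup = BandLookup.build(wl)
    class_params = scene.resolved_class_params()

    rows, labels = [], []
    for label in ("controlled", "stressed", "recovered"):
        params = class_params[label]
        for k in range(scene.resolved_counts()[label]):
            if mode == "fast":
                p = _jitter_params(params, rng, jitter)
                p = replace(p, noise_sd=p.noise_sd / np.sqrt(FAST_MODE_ROI_PIXELS))
                spectrum = leaf_spectrum(p, wl, rng)
            elif mode == "pipeline":
                cube, _truth = make_scene(scene, label, rng)
                try:
                    mask = segment_cube(cube)
                    spectrum = roi_mean_spectrum(cube, mask)
                except EmptyROIError:
                    logger.warning("segmentation failed for sample %s/%d; dropped", label, k)
                    continue
            else:
                raise ValueError(f"unknown dataset mode '{mode}'")
            rows.append(index_vector(spectrum, lookup).as_dict())
            labels.append(label)
    return clean_table(make_table(rows, labels))


def interpolate_params(a: SpectralParams, b: SpectralParams, w: float) -> SpectralParams:
    """Field-wise linear interpolation ``a + w * (b - a)``."""
    updates = {
        f.name: (1.0 - w) * getattr(a, f.name) + w * getattr(b, f.name)
        for f in dataclass_fields(a)
    }
    return SpectralParams(**updates)


def class_params_with_gap(gap: float) -> dict[str, SpectralParams]:
    """Class archetypes with the controlled-vs-stressed contrast scaled.

    ``gap=1`` reproduces the defaults; ``gap=0`` collapses all three
    classes onto the controlled archetype. Recovered keeps its relative
    position between the two. Used to study how downstream classifier
    accuracy tracks the spectral effect size.
    """
    c = DEFAULT_CLASS_PARAMS["controlled"]
    return {
        "controlled": c,
        "recovered": interpolate_params(c, DEFAULT_CLASS_PARAMS["recovered"], gap),
        "stressed": interpolate_params(c, DEFAULT_CLASS_PARAMS["stressed"], gap),
    }
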