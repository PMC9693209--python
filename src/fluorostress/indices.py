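"""The eight chlorophyll-fluorescence indices.

All eight read reflectance at a handful of diagnostic wavelengths: the
chlorophyll-a and -b absorption bands (676 and 635 nm), the red edge
(700–752 nm), and the NIR reference plateau (790/810 nm), where
chlorophyll does not absorb. On an instrument grid each requested
wavelength resolves to the nearest band centre ("Near(R_lambda)");
at ~4.7 nm resolution 675 and 676 nm land on the same band, so SR and
PSSRa coincide numerically but are kept as distinct features because
they have distinct definition lineages in the vegetation-index
literature.

Definitions (R_x = reflectance at the band nearest x nm):

    PSNDa      = (R810 - R676) / (R810 + R676)
    PSNDb      = (R810 - R635) / (R810 + R635)
    PSSRa      = R810 / R676
    PSSRb      = R810 / R635
    CI-RedEdge = R810 / R700 - 1
    NDRE       = (R790 - R720) / (R790 + R720)
    SR         = R810 / R675
    RVSI       = (R714 + R752) / 2 - R733

The seven ratio forms are invariant to a positive rescaling of the
spectrum; RVSI is homogeneous of degree one, which is why a canonical
reflectance scale matters for it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dataclass_fields

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "INDEX_NAMES",
    "INDEX_WAVELENGTHS_NM",
    "BandLookup",
    "IndexVector",
    "nearest_band",
    "psnd",
    "index_vector",
    "index_maps",
]

#: Canonical feature order used by the feature table and all reports.
INDEX_NAMES = (
    "psnd_a",
    "psnd_b",
    "pssr_a",
    "pssr_b",
    "ci_rededge",
    "ndre",
    "sr",
    "rvsi",
)

#: Wavelengths (nm) the index formulas request.
INDEX_WAVELENGTHS_NM = (635, 675, 676, 700, 714, 720, 733, 752, 790, 810)

#: Flag a lookup whose nearest band is further than this from the target;
#: the instrument the defaults emulate has a 4.5-4.8 nm band spacing.
RESOLUTION_WARN_NM = 5.0


def nearest_band(wavelengths: np.ndarray, target: float) -> int:
    """Index of the band centre nearest ``target`` nm.

    Ties break toward the lower wavelength.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size == 0:
        raise ValueError("empty wavelength vector")
    return int(np.argmin(np.abs(wavelengths - target)))


@dataclass(frozen=True)
class BandLookup:
    """Resolved band positions for every wavelength the indices request."""

    wavelengths: np.ndarray
    resolved: dict[int, int]

    @classmethod
    def build(cls, wavelengths: np.ndarray) -> "BandLookup":
        wavelengths = np.asarray(wavelengths, dtype=float)
        resolved = {}
        for target in INDEX_WAVELENGTHS_NM:
            k = nearest_band(wavelengths, target)
            off = abs(wavelengths[k] - target)
            if off > RESOLUTION_WARN_NM:
                logger.warning(
                    "band nearest %d nm is %.1f nm away (at %.1f nm); "
                    "grid coarser than the indices assume",
                    target, off, wavelengths[k],
                )
            resolved[target] = k
        return cls(wavelengths, resolved)

    def __getitem__(self, target_nm: int) -> int:
        return self.resolved[target_nm]


@dataclass(frozen=True)
class IndexVector:
    """The eight index values for one sample (one ROI-mean spectrum)."""

    psnd_a: float
    psnd_b: float
    pssr_a: float
    pssr_b: float
    ci_rededge: float
    ndre: float
    sr: float
    rvsi: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in INDEX_NAMES])


def psnd(r_ref: np.ndarray | float, r_abs: np.ndarray | float):
    """Normalized difference (r_ref - r_abs) / (r_ref + r_abs).

    The shared kernel of PSNDa, PSNDb and NDRE. A zero denominator
    yields NaN (logged, not raised) so per-pixel maps never abort on a
    degenerate pixel.
    """
    r_ref = np.asarray(r_ref, dtype=float)
    r_abs = np.asarray(r_abs, dtype=float)
    denom = r_ref + r_abs
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (r_ref - r_abs) / np.where(denom != 0, denom, 1.0), np.nan)
    n_bad = int(np.sum(denom == 0))
    if n_bad:
        logger.info("psnd: %d degenerate zero-denominator pixel(s) -> NaN", n_bad)
    return out if out.ndim else float(out)


def _ratio(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    return out if out.ndim else float(out)


def _compute_all(r: dict[int, np.ndarray | float]) -> dict[str, np.ndarray | float]:
    return {
        "psnd_a": psnd(r[810], r[676]),
        "psnd_b": psnd(r[810], r[635]),
        "pssr_a": _ratio(r[810], r[676]),
        "pssr_b": _ratio(r[810], r[635]),
        "ci_rededge": np.asarray(_ratio(r[810], r[700])) - 1.0,
        "ndre": psnd(r[790], r[720]),
        "sr": _ratio(r[810], r[675]),
        "rvsi": (np.asarray(r[714], dtype=float) + np.asarray(r[752], dtype=float)) / 2.0
        - np.asarray(r[733], dtype=float),
    }


def index_vector(spectrum: np.ndarray, lookup: BandLookup) -> IndexVector:
    """Evaluate all eight indices on one spectrum."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != lookup.wavelengths.shape:
        raise ValueError(
            f"spectrum length {spectrum.size} does not match lookup grid "
            f"{lookup.wavelengths.size}"
        )
    r = {nm: float(spectrum[lookup[nm]]) for nm in INDEX_WAVELENGTHS_NM}
    vals = _compute_all(r)
    return IndexVector(**{k: float(np.asarray(v)) for k, v in vals.items()})


def index_maps(cube, mask: np.ndarray, lookup: BandLookup) -> dict[str, np.ndarray]:
    """Per-pixel index images over the masked region.

    Each returned map is defined exactly on masked pixels and NaN
    elsewhere; the value at a pixel equals :func:`index_vector` applied
    to that pixel's spectrum.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        from .segmentation import EmptyROIError

        raise EmptyROIError("mask selects no pixels")
    r = {nm: cube.data[:, :, lookup[nm]][mask] for nm in INDEX_WAVELENGTHS_NM}
    vals = _compute_all(r)
    maps = {}
    for name in INDEX_NAMES:
        img = np.full(mask.shape, np.nan)
        img[mask] = vals[name]
        maps[name] = img
    return maps
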