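"""Hyperspectral cube container and I/O.

A cube is a ``rows x cols x bands`` reflectance array together with a
strictly increasing vector of band-center wavelengths in nanometres.
Two on-disk representations are supported:

* **ENVI** — the field's de-facto raster exchange format: a raw binary
  array (BIL/BSQ/BIP interleave) next to an ASCII ``.hdr`` describing
  shape, interleave, data type and the wavelength list.
* **fixture** — a single ``.npz`` archive holding ``data`` and
  ``wavelengths``; bit-exact round-trip, used for tests and scratch files.

Reflectance is kept as floating point nominally in [0, 1]; integer DN
cubes are rescaled on read (header ``reflectance scale factor`` if
present, else the dtype's maximum representable value) because RVSI is
not scale-invariant, so a canonical scale matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HyperspectralCube",
    "CubeFormatError",
    "CubeMetadataError",
    "read_cube",
    "write_cube",
]


class CubeFormatError(ValueError):
    """Raised when a file cannot be parsed as the requested format."""


class CubeMetadataError(ValueError):
    """Raised when header metadata contradicts the data payload."""


# ENVI "data type" codes -> numpy dtypes (the subset that occurs in practice
# for VNIR reflectance products).
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperspectralCube:
    """Reflectance cube plus wavelength metadata.

    Parameters
    ----------
    data:
        ``(rows, cols, bands)`` float array, dimensionless reflectance,
        expected in [0, 1] after calibration.
    wavelengths:
        ``(bands,)`` strictly increasing band centres in nm.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise CubeMetadataError(
                f"cube data must be rows x cols x bands, got ndim={self.data.ndim}"
            )
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise CubeMetadataError(
                f"wavelength count {self.wavelengths.size} does not match "
                f"band dimension {self.data.shape[2]}"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise CubeMetadataError("wavelengths must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.data < 0):
                raise CubeMetadataError("negative reflectance values present")
            if np.any(self.data > 1):
                logger.warning(
                    "cube %s contains reflectance values > 1 (max %.3f)",
                    self.source or "<memory>",
                    float(np.nanmax(self.data)),
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    def band_image(self, index: int) -> np.ndarray:
        """Return the 2-D image of one band."""
        return self.data[:, :, index]


def _parse_envi_header(text: str) -> dict:
    """Parse an ENVI ASCII header into a flat dict (keys lower-cased).

    Values in ``{...}`` (possibly multi-line) become lists of strings.
    """
    # Strip the leading magic line if present.
    body = text
    if body.lstrip().lower().startswith("envi"):
        body = body.lstrip()[4:]
    fields: dict = {}
    i = 0
    n = len(body)
    while i < n:
        eq = body.find("=", i)
        if eq == -1:
            break
        key = body[i:eq].strip().lower()
        j = eq + 1
        while j < n and body[j] in " \t":
            j += 1
        if j < n and body[j] == "{":
            close = body.find("}", j)
            if close == -1:
                raise CubeFormatError(f"unterminated '{{' for header field '{key}'")
            raw = body[j + 1 : close]
            fields[key] = [tok.strip() for tok in raw.replace("\n", " ").split(",") if tok.strip()]
            i = close + 1
        else:
            end = body.find("\n", j)
            if end == -1:
                end = n
            fields[key] = body[j:end].strip()
            i = end + 1
    return fields


def _envi_paths(path: Path) -> tuple[Path, Path]:
    """Resolve (data file, header file) from either path."""
    path = Path(path)
    if path.suffix == ".hdr":
        hdr = path
        for cand in (path.with_suffix(".dat"), path.with_suffix(".img"), path.with_suffix("")):
            if cand.exists():
                return cand, hdr
        raise CubeFormatError(f"no data file found next to header {hdr}")
    hdr = path.with_suffix(path.suffix + ".hdr")
    if not hdr.exists():
        hdr = path.with_suffix(".hdr")
    return path, hdr


def _read_envi(path: Path) -> HyperspectralCube:
    data_path, hdr_path = _envi_paths(Path(path))
    if not hdr_path.exists():
        raise CubeFormatError(f"missing ENVI header for {data_path}")
    hdr = _parse_envi_header(hdr_path.read_text())
    try:
        samples = int(hdr["samples"])
        lines = int(hdr["lines"])
        bands = int(hdr["bands"])
    except KeyError as exc:
        raise CubeFormatError(f"ENVI header missing required field {exc}") from exc
    interleave = str(hdr.get("interleave", "bsq")).lower()
    dtype_code = int(hdr.get("data type", 4))
    if dtype_code not in _ENVI_DTYPES:
        raise CubeFormatError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    byte_order = int(hdr.get("byte order", 0))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")

    if "wavelength" not in hdr:
        raise CubeMetadataError(f"ENVI header {hdr_path} has no 'wavelength' field")
    wavelengths = np.array([float(w) for w in hdr["wavelength"]])
    if wavelengths.size != bands:
        raise CubeMetadataError(
            f"header lists {wavelengths.size} wavelengths but {bands} bands"
        )

    raw = np.fromfile(data_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise CubeMetadataError(
            f"data file holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise CubeFormatError(f"unknown interleave '{interleave}'")

    cube = np.ascontiguousarray(cube)
    if np.issubdtype(cube.dtype, np.integer):
        scale = float(hdr.get("reflectance scale factor", np.iinfo(cube.dtype).max))
        cube = cube.astype(np.float64) / scale
    else:
        cube = cube.astype(np.float64, copy=False)
    return HyperspectralCube(cube, wavelengths, source=str(data_path))


def _write_envi(cube: HyperspectralCube, path: Path, interleave: str = "bil") -> None:
    data_path = Path(path)
    if data_path.suffix == ".hdr":
        raise CubeFormatError("pass the data-file path, not the .hdr path")
    hdr_path = data_path.with_suffix(data_path.suffix + ".hdr")
    interleave = interleave.lower()
    rows, cols, bands = cube.shape
    arr = cube.data.astype(np.float32)
    if interleave == "bsq":
        payload = arr.transpose(2, 0, 1)
    elif interleave == "bil":
        payload = arr.transpose(0, 2, 1)
    elif interleave == "bip":
        payload = arr
    else:
        raise CubeFormatError(f"unknown interleave '{interleave}'")
    payload = np.ascontiguousarray(payload)
    payload.tofile(data_path)

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr_path.write_text(
        "ENVI\n"
        "description = {fluorostress export}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(np.float32)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )


def _read_fixture(path: Path) -> HyperspectralCube:
    try:
        with np.load(path) as archive:
            data = archive["data"]
            wavelengths = archive["wavelengths"]
    except (OSError, KeyError, ValueError) as exc:
        raise CubeFormatError(f"cannot read fixture archive {path}: {exc}") from exc
    return HyperspectralCube(data, wavelengths, source=str(path))


def _write_fixture(cube: HyperspectralCube, path: Path) -> None:
    np.savez(path, data=cube.data, wavelengths=cube.wavelengths)


def read_cube(path, format: str = "fixture") -> HyperspectralCube:
    """Read a hyperspectral cube from disk.

    Parameters
    ----------
    path:
        File path. For ENVI, either the data file or the ``.hdr``.
    format:
        ``"envi"`` or ``"fixture"``.

    Returns
    -------
    HyperspectralCube
        Cube normalised to rows x cols x bands regardless of the on-disk
        interleave.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "envi":
        return _read_envi(path)
    if format == "fixture":
        return _read_fixture(path)
    raise ValueError(f"unknown cube format '{format}'")


def write_cube(cube: HyperspectralCube, path, format: str = "fixture", interleave: str = "bil") -> None:
    """Write a cube so that :func:`read_cube` recovers it.

    Fixture round-trips are bit-exact; ENVI stores float32, so values are
    recovered to single precision.
    """
    if format == "envi":
        _write_envi(cube, Path(path), interleave=interleave)
    elif format == "fixture":
        _write_fixture(cube, Path(path))
    else:
        raise ValueError(f"unknown cube format '{format}'")
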