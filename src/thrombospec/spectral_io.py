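"""Hyperspectral cube and basis-spectra I/O.

Cubes are stored as ENVI header/binary pairs (band-sequential, little-endian
float32), the lingua franca of hyperspectral tooling.  Basis spectra — pure
reference spectra of plasma, red blood cells, the filter substrate and water
ice used as regressors in linear unmixing — travel as plain CSV with a
``wavelength`` column.

Conventions: pixel coordinates are (row, col), 0-based, row-major; band index
0-based and aligned with the wavelength axis.  Cubes are assumed to already be
in reflectance units; acquisition-side calibration (dark/white referencing) is
out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectralCube",
    "BasisSpectraSet",
    "SpectralFormatError",
    "GridMismatchError",
    "REQUIRED_COMPONENTS",
    "read_cube",
    "write_cube",
    "read_basis_library",
    "write_basis_library",
    "resample_spectrum",
    "preprocess_cube",
]

#: Component names every basis library must provide, in canonical order.
REQUIRED_COMPONENTS = ("plasma", "rbc", "filter", "ice")

#: Default acquisition grid: 150 bands spanning 470-900 nm.
DEFAULT_WAVELENGTHS = np.linspace(470.0, 900.0, 150)


class SpectralFormatError(ValueError):
    """Raised for missing/ill-formed headers or inconsistent band metadata."""


class GridMismatchError(ValueError):
    """Raised when two spectral objects live on different wavelength grids."""


@dataclass
class SpectralCube:
    """A hyperspectral reflectance image: an (H, W, B) array plus wavelengths.

    Each pixel carries a full reflectance spectrum (by default 150 bands over
    470-900 nm).  Values are non-negative reflectance intensities in arbitrary
    units.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.values.ndim != 3:
            raise SpectralFormatError(
                f"cube values must be (rows, cols, bands); got shape {self.values.shape}"
            )
        if any(s == 0 for s in self.values.shape):
            raise SpectralFormatError(f"cube has an empty dimension: {self.values.shape}")
        if self.values.shape[2] != self.wavelengths.size:
            raise SpectralFormatError(
                f"band count {self.values.shape[2]} != wavelength count {self.wavelengths.size}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise SpectralFormatError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise SpectralFormatError("cube contains non-finite reflectance values")
        if np.any(self.values < 0):
            raise SpectralFormatError("cube contains negative reflectance values")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def pixels(self) -> np.ndarray:
        """Return spectra as an (H*W, B) matrix, row-major pixel order."""
        return self.values.reshape(-1, self.n_bands)


@dataclass
class BasisSpectraSet:
    """Named pure-component spectra on a common wavelength grid.

    ``plasma``, ``rbc``, ``filter`` and ``ice`` must be present; extra
    components are carried along untouched.
    """

    wavelengths: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise SpectralFormatError("basis wavelengths must be strictly increasing")
        self.components = {k: np.asarray(v, dtype=np.float64) for k, v in self.components.items()}
        for name in REQUIRED_COMPONENTS:
            if name not in self.components:
                raise SpectralFormatError(f"missing component: {name}")
        for name, vec in self.components.items():
            if vec.shape != self.wavelengths.shape:
                raise SpectralFormatError(
                    f"component {name!r} length {vec.size} != grid length {self.wavelengths.size}"
                )
            if not np.all(np.isfinite(vec)) or np.any(vec < 0):
                raise SpectralFormatError(f"component {name!r} has non-finite or negative values")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.components[name]

    @property
    def names(self) -> list[str]:
        return list(self.components)

    def matrix(self, names: tuple[str, ...] = REQUIRED_COMPONENTS) -> np.ndarray:
        """Stack the named component spectra as columns of a (B, len(names)) matrix."""
        return np.column_stack([self.components[n] for n in names])

    def resample(self, target: np.ndarray) -> "BasisSpectraSet":
        """Return the set interpolated onto ``target`` (must lie inside the grid)."""
        return BasisSpectraSet(
            wavelengths=np.asarray(target, dtype=np.float64),
            components={
                n: resample_spectrum(v, self.wavelengths, target) for n, v in self.components.items()
            },
        )


# ---------------------------------------------------------------------------
# ENVI cube I/O

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _parse_envi_header(text: str) -> dict[str, str]:
    if not text.lstrip().upper().startswith("ENVI"):
        raise SpectralFormatError("not an ENVI header: missing 'ENVI' magic line")
    # collapse { ... } blocks (possibly multi-line) into single-line values
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def _header_int(fields: dict[str, str], key: str) -> int:
    if key not in fields:
        raise SpectralFormatError(f"ENVI header missing required key: {key}")
    try:
        return int(fields[key])
    except ValueError as exc:
        raise SpectralFormatError(f"ENVI header key {key!r} is not an integer: {fields[key]!r}") from exc


def read_cube(path: str | Path) -> SpectralCube:
    """Read an ENVI header (.hdr) + binary pair into a :class:`SpectralCube`.

    ``path`` may name either file of the pair.  Band-sequential (BSQ),
    band-interleaved-by-line (BIL) and by-pixel (BIP) interleaves are accepted.
    """
    path = Path(path)
    hdr_path = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise SpectralFormatError(f"ENVI header not found: {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())

    samples = _header_int(fields, "samples")
    lines = _header_int(fields, "lines")
    bands = _header_int(fields, "bands")
    dtype_code = _header_int(fields, "data type")
    if dtype_code not in _ENVI_DTYPES:
        raise SpectralFormatError(f"unsupported ENVI data type code: {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    byte_order = _header_int(fields, "byte order") if "byte order" in fields else 0
    if byte_order:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", "0"))

    if "wavelength" not in fields:
        raise SpectralFormatError("ENVI header missing required key: wavelength")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(x) for x in wl_text.split(",") if x.strip()], dtype=np.float64)
    if wavelengths.size != bands:
        raise SpectralFormatError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )

    sample_id = fields.get("description", "").strip().strip("{}").strip()

    bin_path = None
    for ext in (".bsq", ".img", ".dat", ".raw", ""):
        cand = hdr_path.with_suffix(ext) if ext else hdr_path.with_suffix("")
        if cand.exists() and cand != hdr_path:
            bin_path = cand
            break
    if bin_path is None:
        raise SpectralFormatError(f"binary companion of {hdr_path} not found")

    raw = np.fromfile(bin_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise SpectralFormatError(
            f"binary file holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":
        values = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        values = raw.reshape(lines, samples, bands)
    else:
        raise SpectralFormatError(f"unknown interleave: {interleave!r}")
    return SpectralCube(values=values, wavelengths=wavelengths, sample_id=sample_id)


def write_cube(cube: SpectralCube, path: str | Path) -> None:
    """Write ``cube`` as an ENVI .hdr + .bsq pair (little-endian float32)."""
    path = Path(path)
    hdr_path = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    bin_path = hdr_path.with_suffix(".bsq")

    data = cube.values.astype("<f4")
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{{cube.sample_id}}}\n"
        f"samples = {cube.width}\n"
        f"lines = {cube.height}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_DTYPE_CODES[np.dtype('float32')]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    hdr_path.write_text(header)
    data.transpose(2, 0, 1).tofile(bin_path)


# ---------------------------------------------------------------------------
# Basis libraries

def read_basis_library(path: str | Path) -> BasisSpectraSet:
    """Read a basis-spectra CSV (wavelength column + one column per component)."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "wavelength" not in cols:
        raise SpectralFormatError("basis CSV has no 'wavelength' column")
    wl = df[cols["wavelength"]].to_numpy(dtype=np.float64)
    components = {
        name.strip().lower(): df[orig].to_numpy(dtype=np.float64)
        for name, orig in cols.items()
        if name != "wavelength"
    }
    return BasisSpectraSet(wavelengths=wl, components=components)


def write_basis_library(basis: BasisSpectraSet, path: str | Path) -> None:
    """Write a basis set as CSV, required components first."""
    order = list(REQUIRED_COMPONENTS) + [n for n in basis.names if n not in REQUIRED_COMPONENTS]
    df = pd.DataFrame({"wavelength": basis.wavelengths})
    for name in order:
        df[name] = basis.components[name]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Grid alignment and preprocessing

def resample_spectrum(spectrum: np.ndarray, source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Piecewise-linearly interpolate ``spectrum`` from grid ``source`` to ``target``.

    Exact at shared grid points; extrapolation is refused.
    """
    source = np.asarray(source, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    spectrum = np.asarray(spectrum, dtype=np.float64)
    if target.min() < source.min() or target.max() > source.max():
        raise ValueError(
            f"target grid [{target.min()}, {target.max()}] extends outside "
            f"source range [{source.min()}, {source.max()}]"
        )
    return np.interp(target, source, spectrum)


def preprocess_cube(cube: SpectralCube, mode: str = "none") -> SpectralCube:
    """Optional spectral preprocessing.

    ``none`` returns the cube unchanged.  ``per_pixel_norm`` divides each pixel
    spectrum by its mean intensity, decoupling brightness from spectral shape;
    zero-mean pixels are left unchanged and counted on the returned cube as
    ``n_zero_pixels``.
    """
    if mode == "none":
        return cube
    if mode == "per_pixel_norm":
        means = cube.values.mean(axis=2, keepdims=True)
        zero = means[..., 0] == 0
        safe = np.where(means == 0, 1.0, means)
        out = SpectralCube(
            values=cube.values / safe, wavelengths=cube.wavelengths, sample_id=cube.sample_id
        )
        out.n_zero_pixels = int(zero.sum())  # type: ignore[attr-defined]
        return out
    raise ValueError(f"unknown preprocessing mode: {mode!r}")
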