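"""Per-pixel linear spectral unmixing against pure-component basis spectra.

Each pixel spectrum S(λ) is modelled as a constant offset plus a weighted sum
of the plasma, RBC, filter and ice basis spectra::

    S(λ) ≈ c0 + c_plasma·S_plasma(λ) + c_rbc·S_rbc(λ)
              + c_filter·S_filter(λ) + c_ice·S_ice(λ)

Least-squares coefficients characterise the pixel's composition; the residual
sum of squares (chi2) flags pixels the four components cannot explain.  Two
modes: ``nnls`` (default — component weights constrained non-negative, the
physically interpretable choice for additive reflectance contributions; the
offset stays free) and ``ols`` (fully unconstrained, used for closed-form
cross-checks).  The free offset under NNLS is handled exactly by splitting it
into positive and negative parts inside one non-negative solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .spectral_io import (
    REQUIRED_COMPONENTS,
    BasisSpectraSet,
    GridMismatchError,
    SpectralCube,
)

__all__ = ["PixelFit", "CoefficientMaps", "fit_pixel", "fit_cube", "render_coefficient_maps"]

COEFF_NAMES = ("c0",) + REQUIRED_COMPONENTS


@dataclass
class PixelFit:
    """Unmixing result for one pixel: offset, four component weights, chi2."""

    c0: float
    c_plasma: float
    c_rbc: float
    c_filter: float
    c_ice: float
    chi2: float
    dof: int
    mode: str = "nnls"
    rank_deficient: bool = False

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.c0, self.c_plasma, self.c_rbc, self.c_filter, self.c_ice])


@dataclass
class CoefficientMaps:
    """Per-coefficient spatial maps for a whole cube, plus the chi2 map."""

    c0: np.ndarray
    plasma: np.ndarray
    rbc: np.ndarray
    filter: np.ndarray
    ice: np.ndarray
    chi2: np.ndarray
    dof: int
    mode: str
    rank_deficient: bool = False
    sample_id: str = ""

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "c0": self.c0,
            "plasma": self.plasma,
            "rbc": self.rbc,
            "filter": self.filter,
            "ice": self.ice,
            "chi2": self.chi2,
        }


def _design(basis: BasisSpectraSet, wavelengths: np.ndarray) -> np.ndarray:
    """(B, 5) design matrix [1 | S_plasma | S_rbc | S_filter | S_ice] on the cube grid."""
    b = basis if np.array_equal(basis.wavelengths, wavelengths) else basis.resample(wavelengths)
    return np.column_stack([np.ones(wavelengths.size), b.matrix()])


def _solve_ols(A: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Minimum-norm least squares for all pixels at once; Y is (B, n)."""
    coef, _, rank, _ = np.linalg.lstsq(A, Y, rcond=None)
    return coef, rank < A.shape[1]


def _solve_nnls_pixel(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """NNLS with a free offset: offset = a − b with a, b ≥ 0 in the augmented design."""
    aug = np.column_stack([A, -A[:, :1]])  # columns: 1, S..., -1
    coef, _ = nnls(aug, y)
    out = coef[:-1].copy()
    out[0] -= coef[-1]
    return out


def fit_pixel(
    spectrum: np.ndarray, basis: BasisSpectraSet, mode: str = "nnls"
) -> PixelFit:
    """Unmix one spectrum (given on the basis grid) into the five coefficients."""
    y = np.asarray(spectrum, dtype=np.float64)
    if y.shape != basis.wavelengths.shape:
        raise GridMismatchError(
            f"spectrum has {y.size} bands, basis grid has {basis.wavelengths.size}"
        )
    if y.size < 5:
        raise ValueError("need at least 5 bands to fit 5 coefficients")
    A = _design(basis, basis.wavelengths)
    if mode == "ols":
        coef, deficient = _solve_ols(A, y[:, None])
        coef = coef[:, 0]
    elif mode == "nnls":
        deficient = np.linalg.matrix_rank(A) < A.shape[1]
        coef = _solve_nnls_pixel(A, y)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    resid = y - A @ coef
    return PixelFit(
        c0=float(coef[0]),
        c_plasma=float(coef[1]),
        c_rbc=float(coef[2]),
        c_filter=float(coef[3]),
        c_ice=float(coef[4]),
        chi2=float(resid @ resid),
        dof=y.size - 5,
        mode=mode,
        rank_deficient=bool(deficient),
    )


def fit_cube(cube: SpectralCube, basis: BasisSpectraSet, mode: str = "nnls") -> CoefficientMaps:
    """Unmix every pixel of a cube; returns coefficient and chi2 maps.

    OLS solves all pixels in one shared factorisation; NNLS runs the
    active-set solver per pixel.  Rank deficiency is flagged, not fatal —
    the minimum-norm solution is reported.
    """
    A = _design(basis, cube.wavelengths)
    Y = cube.pixels().T  # (B, n)
    n = Y.shape[1]
    if mode == "ols":
        coef, deficient = _solve_ols(A, Y)
        coef = coef.T  # (n, 5)
    elif mode == "nnls":
        deficient = np.linalg.matrix_rank(A) < A.shape[1]
        coef = np.empty((n, 5))
        for i in range(n):
            coef[i] = _solve_nnls_pixel(A, Y[:, i])
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    resid = Y - A @ coef.T
    chi2 = (resid * resid).sum(axis=0)
    shape = (cube.height, cube.width)
    return CoefficientMaps(
        c0=coef[:, 0].reshape(shape),
        plasma=coef[:, 1].reshape(shape),
        rbc=coef[:, 2].reshape(shape),
        filter=coef[:, 3].reshape(shape),
        ice=coef[:, 4].reshape(shape),
        chi2=chi2.reshape(shape),
        dof=cube.n_bands - 5,
        mode=mode,
        rank_deficient=bool(deficient),
        sample_id=cube.sample_id,
    )


def render_coefficient_maps(
    maps: CoefficientMaps, cmap: str = "viridis", shared_scale: bool = False
) -> dict[str, np.ndarray]:
    """False-colour (H, W, 3) uint8 rasters, one per coefficient plus chi2.

    With ``shared_scale`` the four component maps share one colour scale so
    their magnitudes are visually comparable.
    """
    from matplotlib import colormaps

    cm = colormaps[cmap]
    out: dict[str, np.ndarray] = {}
    comp = {k: v for k, v in maps.as_dict().items() if k not in ("c0", "chi2")}
    if shared_scale:
        lo = min(v.min() for v in comp.values())
        hi = max(v.max() for v in comp.values())
    for name, arr in maps.as_dict().items():
        if shared_scale and name in comp:
            vmin, vmax = lo, hi
        else:
            vmin, vmax = float(arr.min()), float(arr.max())
        span = vmax - vmin if vmax > vmin else 1.0
        rgba = cm((arr - vmin) / span)
        out[name] = (rgba[..., :3] * 255).astype(np.uint8)
    return out
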