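"""Synthetic hyperspectral scenes and patient cohorts with known ground truth.

Real thrombus-aspirate datasets of this kind are not publicly deposited, so
every stage of the pipeline is exercised against simulated data instead:

* :func:`make_basis_spectra` builds smooth pure-component reflectance spectra.
  The red-blood-cell spectrum carries the oxyhaemoglobin signature — twin
  absorption dips near 542 and 577 nm and a steep reflectance rise above
  600 nm — which is what lets clustering and unmixing discriminate
  erythrocyte-rich material.
* :func:`make_cube` paints a scene of disjoint regions (filter background,
  water ice, contaminating blood, thrombus of varying RBC/plasma composition),
  mixes the basis spectra with per-region weights, adds truncated Gaussian
  noise, and returns the cube together with its ground truth.
* :func:`make_cohort` samples per-patient k-fraction vectors on the simplex
  and generates a microvascular-injury index (IMR or MVO) from one of the four
  regression families, so parameter recovery and model discrimination can be
  tested against known coefficients.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral_io import REQUIRED_COMPONENTS, BasisSpectraSet, SpectralCube

__all__ = [
    "Region",
    "SceneSpec",
    "GroundTruth",
    "CohortSpec",
    "make_basis_spectra",
    "make_cube",
    "make_cohort",
    "reference_noise_sd",
    "default_scene",
    "rect_mask",
]

REGION_KINDS = ("filter_background", "ice", "blood", "thrombus")


def rect_mask(height: int, width: int, r0: int, r1: int, c0: int, c1: int) -> np.ndarray:
    """Boolean (height, width) mask that is True on rows [r0, r1) x cols [c0, c1)."""
    m = np.zeros((height, width), dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


@dataclass
class Region:
    """One scene region: a kind, a pixel mask, and mixing weights over the basis."""

    kind: str
    mask: np.ndarray
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind: {self.kind!r}")
        self.mask = np.asarray(self.mask, dtype=bool)
        w = np.array([self.weights.get(n, 0.0) for n in REQUIRED_COMPONENTS])
        if np.any(w < 0):
            raise ValueError(f"region {self.kind!r} has negative weights")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"region {self.kind!r} weights sum to {w.sum()}, expected 1")


@dataclass
class SceneSpec:
    """Layout of a synthetic sample: disjoint regions covering the image."""

    height: int
    width: int
    regions: list[Region]
    noise_sd: float = 0.0
    seed: int = 0
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        cover = np.zeros((self.height, self.width), dtype=int)
        for reg in self.regions:
            if reg.mask.shape != (self.height, self.width):
                raise ValueError("region mask shape does not match scene")
            cover += reg.mask
        if np.any(cover > 1):
            raise ValueError("region masks overlap")
        if np.any(cover == 0):
            raise ValueError("region masks do not cover the scene")


@dataclass
class GroundTruth:
    """Per-pixel truth for a synthetic cube (the oracle for every test)."""

    label_map: np.ndarray        # (H, W) index into `kinds`
    region_map: np.ndarray       # (H, W) index of the generating Region
    kinds: list[str]
    coefficient_maps: np.ndarray  # (H, W, 4) true weights, REQUIRED_COMPONENTS order
    thrombus_mask: np.ndarray
    true_area_fraction: float


def _smooth_jitter(grid: np.ndarray, rng: np.random.Generator, amplitude: float = 0.01) -> np.ndarray:
    """Small seeded sum of broad Gaussians — sample-to-sample spectral variation."""
    out = np.zeros_like(grid)
    for _ in range(3):
        centre = rng.uniform(grid.min(), grid.max())
        width = rng.uniform(60.0, 150.0)
        out += rng.normal(0.0, amplitude) * np.exp(-(((grid - centre) / width) ** 2))
    return out


def make_basis_spectra(grid: np.ndarray | None = None, seed: int = 0) -> BasisSpectraSet:
    """Smooth synthetic pure-component spectra on ``grid`` (default 150 bands, 470-900 nm).

    Shapes: ``rbc`` is an oxyhaemoglobin-like reflectance — low below 600 nm
    with absorption dips at 542 and 577 nm, then a steep rise to a red/NIR
    plateau; ``plasma`` is bright with a gentle upward slope; ``filter`` is
    near-flat; ``ice`` is flat with a mild blue-end elevation.  All values lie
    in (0, 1].  Deterministic given (grid, seed).
    """
    from .spectral_io import DEFAULT_WAVELENGTHS

    grid = DEFAULT_WAVELENGTHS if grid is None else np.asarray(grid, dtype=np.float64)
    if grid.min() < 470.0 - 1e-9 or grid.max() > 900.0 + 1e-9:
        raise ValueError("grid must lie within 470-900 nm")
    rng = np.random.default_rng(seed)

    rise = 1.0 / (1.0 + np.exp(-(grid - 605.0) / 15.0))
    rbc = (
        0.12
        + 0.55 * rise
        - 0.10 * np.exp(-(((grid - 542.0) / 12.0) ** 2))
        - 0.12 * np.exp(-(((grid - 577.0) / 11.0) ** 2))
    )
    plasma = 0.55 + 0.25 * (grid - 470.0) / 430.0
    filt = 0.45 + 0.02 * (grid - 470.0) / 430.0
    ice = 0.60 + 0.12 * np.exp(-(((grid - 470.0) / 60.0) ** 2))

    comps = {"plasma": plasma, "rbc": rbc, "filter": filt, "ice": ice}
    comps = {
        n: np.clip(v + _smooth_jitter(grid, rng), 1e-4, 1.0) for n, v in comps.items()
    }
    return BasisSpectraSet(wavelengths=grid, components=comps)


def make_cube(scene: SceneSpec, basis: BasisSpectraSet) -> tuple[SpectralCube, GroundTruth]:
    """Render a scene into a noisy cube plus its ground truth.

    Each pixel spectrum is the weighted sum of the basis spectra for its
    region, plus N(0, noise_sd^2) noise truncated at zero.
    """
    grid = basis.wavelengths
    B = grid.size
    H, W = scene.height, scene.width
    basis_mat = basis.matrix()  # (B, 4)

    values = np.zeros((H, W, B))
    label_map = np.full((H, W), -1, dtype=int)
    region_map = np.full((H, W), -1, dtype=int)
    coeff = np.zeros((H, W, len(REQUIRED_COMPONENTS)))
    for i, reg in enumerate(scene.regions):
        w = np.array([reg.weights.get(n, 0.0) for n in REQUIRED_COMPONENTS])
        values[reg.mask] = basis_mat @ w
        coeff[reg.mask] = w
        label_map[reg.mask] = REGION_KINDS.index(reg.kind)
        region_map[reg.mask] = i

    if scene.noise_sd > 0:
        rng = np.random.default_rng(scene.seed)
        values = np.maximum(values + rng.normal(0.0, scene.noise_sd, size=values.shape), 0.0)

    thrombus = label_map == REGION_KINDS.index("thrombus")
    cube = SpectralCube(values=values, wavelengths=grid, sample_id=scene.sample_id)
    truth = GroundTruth(
        label_map=label_map,
        region_map=region_map,
        kinds=list(REGION_KINDS),
        coefficient_maps=coeff,
        thrombus_mask=thrombus,
        true_area_fraction=float(thrombus.mean()),
    )
    return cube, truth


def default_scene(
    height: int = 64,
    width: int = 64,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "synthetic",
    thrombus_mixes: tuple[tuple[float, float], ...] = ((0.70, 0.30), (0.50, 0.50), (0.30, 0.70)),
) -> SceneSpec:
    """A representative aspirate-on-filter scene.

    Filter background everywhere, a water-ice patch, a contaminating-blood
    patch (erythrocyte-dominated), and one thrombus block per (rbc, plasma)
    mix in ``thrombus_mixes`` — compositional variety mirrors the red/white
    thrombus spectrum seen in aspirates.
    """
    regions: list[Region] = []
    hh, ww = height // 2, width // 2
    ice = rect_mask(height, width, 0, hh // 2, ww, width)
    blood = rect_mask(height, width, height - hh // 2, height, 0, ww)
    regions.append(Region("ice", ice, {"ice": 1.0}))
    regions.append(Region("blood", blood, {"rbc": 0.90, "plasma": 0.10}))

    n = len(thrombus_mixes)
    block_w = ww // max(n, 1)
    thrombus_cover = np.zeros((height, width), dtype=bool)
    for j, (w_rbc, w_plasma) in enumerate(thrombus_mixes):
        c0 = (width - ww) // 2 + j * block_w
        m = rect_mask(height, width, hh - hh // 2, hh + hh // 2, c0, c0 + block_w)
        m &= ~(ice | blood | thrombus_cover)
        thrombus_cover |= m
        regions.append(Region("thrombus", m, {"rbc": w_rbc, "plasma": w_plasma}))

    covered = ice | blood | thrombus_cover
    regions.insert(0, Region("filter_background", ~covered, {"filter": 1.0}))
    return SceneSpec(
        height=height, width=width, regions=regions, noise_sd=noise_sd, seed=seed, sample_id=sample_id
    )


# ---------------------------------------------------------------------------
# Cohorts

@dataclass
class CohortSpec:
    """Generative description of a patient cohort for the regression stage.

    ``coefficients`` is (c_0, c_1, ..., c_k) for the chosen model family;
    k-fraction vectors are sampled from a symmetric Dirichlet with
    concentration ``fraction_concentration`` (1.0 = uniform on the simplex).
    ``success_prob`` controls the share of patients whose thrombus area
    fraction lands above the 0.22 adequacy threshold, so the thresholding
    filter has both classes to work on.
    """

    n_patients: int
    k: int = 7
    model: str = "exp"
    coefficients: tuple[float, ...] = (150.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    noise_sd: float = 0.0
    fraction_concentration: float = 1.0
    seed: int = 0
    target: str = "imr"
    area_threshold: float = 0.22
    success_prob: float = 0.7
    low_score_prob: float = 0.0  # share of patients given an ineligible score 0-3

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.model not in ("linear", "power", "exp", "sat_exp"):
            raise ValueError(f"unknown model: {self.model!r}")
        if len(self.coefficients) != self.k + 1:
            raise ValueError(
                f"need k+1 = {self.k + 1} coefficients, got {len(self.coefficients)}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.target not in ("imr", "mvo"):
            raise ValueError(f"target must be 'imr' or 'mvo', got {self.target!r}")


def reference_noise_sd(
    fraction: float,
    model: str = "exp",
    coefficients: tuple[float, ...] | None = None,
    k: int = 7,
    concentration: float = 1.0,
) -> float:
    """Noise s.d. defined as a fraction of the noiseless response range.

    The range is measured on a fixed 2000-draw Dirichlet probe of the simplex
    (probe seed is a constant, so the noise level is a reproducible study
    condition rather than a per-run random quantity).
    """
    from .cohort_analysis import predict

    if coefficients is None:
        coefficients = CohortSpec(n_patients=2, k=k).coefficients
    rng = np.random.default_rng(0)
    F = rng.dirichlet(np.full(k, concentration), 2000)
    y = predict(model, np.asarray(coefficients, dtype=float), F)
    return fraction * float(y.max() - y.min())


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a patient table with known regression structure.

    Columns: patient_id, f_1..f_k, area_fraction, thrombus_score, and the
    generated target (``imr`` plus consistent pd/tmn, or ``mvo``).  Power-model
    fractions are floored at 1e-6 before exponentiation.
    """
    from .cohort_analysis import predict  # shared forward model

    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_patients, spec.k
    F = rng.dirichlet(np.full(k, spec.fraction_concentration), size=n)

    y = predict(spec.model, np.asarray(spec.coefficients, dtype=float), F)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n)

    above = rng.random(n) < spec.success_prob
    area = np.where(
        above,
        rng.uniform(spec.area_threshold, 0.8, size=n),
        rng.uniform(0.0, spec.area_threshold * 0.999, size=n),
    )
    score = rng.integers(4, 6, size=n)
    low = rng.random(n) < spec.low_score_prob
    score = np.where(low, rng.integers(0, 4, size=n), score)

    df = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)]})
    for j in range(k):
        df[f"f_{j + 1}"] = F[:, j]
    df["area_fraction"] = area
    df["thrombus_score"] = score
    if spec.target == "imr":
        pd_hyp = rng.uniform(60.0, 100.0, size=n)  # mmHg
        df["pd"] = pd_hyp
        df["tmn"] = np.maximum(y, 1e-9) / pd_hyp  # s; pd * tmn reproduces imr
        df["imr"] = y
        df["mvo"] = np.nan
    else:
        df["pd"] = np.nan
        df["tmn"] = np.nan
        df["imr"] = np.nan
        df["mvo"] = y
    return df
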