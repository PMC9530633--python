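"""Two-pass k-means classification of pixel spectra.

Pass one clusters every pixel of the pooled image set into K (default 11)
groups, separating filter, ice, blood and thrombus material.  Thrombus
clusters are then selected — automatically by spectral similarity to
RBC/plasma mixtures, or by explicit override — and masked.  Pass two
re-clusters the thrombus pixels alone into K2 (default 7) groups; the share of
thrombus pixels falling in each group is the sample's compositional
"k-fraction" profile f_1..f_K2, which sums to 1 and is the spectral signature
carried forward to the cohort regressions.

Fitting pools pixels across samples by default so that centroid identities —
and therefore k-fractions — are comparable across patients.

The k-means fit itself is a vectorised Lloyd iteration over scikit-learn's
k-means++ initialiser, best of ``n_restarts`` by within-cluster sum of squares
(SSE); the per-iteration SSE trace is recorded on the model so its monotone
descent can be asserted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.cluster import kmeans_plusplus

from .spectral_io import BasisSpectraSet, GridMismatchError, SpectralCube

__all__ = [
    "ClusterModel",
    "LabelMap",
    "KFractionProfile",
    "fit_kmeans",
    "assign_pixels",
    "identify_thrombus_clusters",
    "mask_thrombus",
    "thrombus_area_fraction",
    "kfractions",
    "fit_kfraction_model",
    "render_false_colour",
    "DEFAULT_PALETTE",
]


@dataclass
class ClusterModel:
    """A fitted k-means model: centroids on the cube wavelength grid + fit metadata."""

    K: int
    centroids: np.ndarray            # (K, B)
    wavelengths: np.ndarray
    fitted_on: str = "pooled"        # "pooled" | "single"
    seed: int = 0
    n_restarts: int = 25
    max_iter: int = 300
    tol: float = 1e-6
    final_sse: float = np.inf
    sse_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False


@dataclass
class LabelMap:
    """Per-pixel cluster ids in 1..K; 0 is reserved for masked-out pixels."""

    labels: np.ndarray  # (H, W) int
    K: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 0 or self.labels.max() > self.K:
            raise ValueError(f"labels must lie in 0..{self.K}")


@dataclass
class KFractionProfile:
    """Compositional signature of one sample's thrombus pixels.

    ``fractions[k-1]`` is the share of thrombus pixels assigned to cluster k of
    the K2-means model; fractions sum to 1 when the profile is not degenerate.
    """

    sample_id: str
    fractions: np.ndarray | None
    n_thrombus_pixels: int
    area_fraction: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Lloyd's algorithm

def _lloyd(X: np.ndarray, init: np.ndarray, max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """One Lloyd run from ``init``; returns (centroids, labels, sse_trace, converged)."""
    C = init.copy()
    K = C.shape[0]
    trace: list[float] = []
    labels = np.zeros(X.shape[0], dtype=int)
    converged = False
    x_sq = (X * X).sum(axis=1)
    for _ in range(max_iter):
        # squared Euclidean distances via the expansion trick
        d2 = x_sq[:, None] - 2.0 * X @ C.T + (C * C).sum(axis=1)[None, :]
        labels = np.argmin(d2, axis=1)
        sse = float(np.maximum(d2[np.arange(X.shape[0]), labels], 0.0).sum())
        trace.append(sse)
        new_C = np.empty_like(C)
        counts = np.bincount(labels, minlength=K)
        for k in range(K):
            if counts[k] == 0:
                # re-seed an empty cluster at the point farthest from its centroid
                far = int(np.argmax(d2[np.arange(X.shape[0]), labels]))
                new_C[k] = X[far]
            else:
                new_C[k] = X[labels == k].mean(axis=0)
        shift = float(np.sqrt(((new_C - C) ** 2).sum(axis=1)).max())
        C = new_C
        if shift < tol:
            converged = True
            break
    d2 = x_sq[:, None] - 2.0 * X @ C.T + (C * C).sum(axis=1)[None, :]
    labels = np.argmin(d2, axis=1)
    trace.append(float(np.maximum(d2[np.arange(X.shape[0]), labels], 0.0).sum()))
    return C, labels, trace, converged


def fit_kmeans(
    pixels: np.ndarray,
    K: int,
    seed: int = 0,
    n_restarts: int = 25,
    max_iter: int = 300,
    tol: float = 1e-6,
    wavelengths: np.ndarray | None = None,
    fitted_on: str = "pooled",
) -> ClusterModel:
    """Fit K-means to an (n, B) matrix of pixel spectra.

    k-means++ seeding, Lloyd iterations, best of ``n_restarts`` by SSE;
    deterministic given ``seed``.  Requires at least K distinct pixels.
    """
    X = np.asarray(pixels, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("pixels must be a non-empty (n, bands) matrix")
    n_distinct = np.unique(X, axis=0).shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n_distinct:
        raise ValueError(f"K={K} exceeds the number of distinct pixels ({n_distinct})")

    best: tuple[float, np.ndarray, list[float], bool] | None = None
    rng = np.random.RandomState(seed)
    for _ in range(n_restarts):
        if K == 1:
            init = X.mean(axis=0, keepdims=True)
        else:
            init, _ = kmeans_plusplus(X, n_clusters=K, random_state=rng)
        C, _, trace, conv = _lloyd(X, init, max_iter=max_iter, tol=tol)
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], C, trace, conv)
    assert best is not None
    sse, C, trace, conv = best
    wl = np.arange(X.shape[1], dtype=float) if wavelengths is None else np.asarray(wavelengths, float)
    return ClusterModel(
        K=K,
        centroids=C,
        wavelengths=wl,
        fitted_on=fitted_on,
        seed=seed,
        n_restarts=n_restarts,
        max_iter=max_iter,
        tol=tol,
        final_sse=sse,
        sse_trace=np.asarray(trace),
        converged=conv,
    )


def _assign(model: ClusterModel, X: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels in 1..K; ties broken toward the lowest id."""
    C = model.centroids
    d2 = (X * X).sum(axis=1)[:, None] - 2.0 * X @ C.T + (C * C).sum(axis=1)[None, :]
    return np.argmin(d2, axis=1) + 1  # argmin takes the first minimum -> lowest id


def assign_pixels(model: ClusterModel, cube: SpectralCube) -> LabelMap:
    """Label every cube pixel with its nearest centroid (Euclidean distance)."""
    if model.centroids.shape[1] != cube.n_bands or not np.allclose(
        model.wavelengths, cube.wavelengths
    ):
        raise GridMismatchError("cluster model and cube are on different wavelength grids")
    labels = _assign(model, cube.pixels()).reshape(cube.height, cube.width)
    return LabelMap(labels=labels, K=model.K, sample_id=cube.sample_id)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _mix_similarity(centroid: np.ndarray, columns: np.ndarray) -> float:
    """Cosine similarity of a centroid to its best nonnegative mix of ``columns``."""
    coef, _ = nnls(columns, centroid)
    fitted = columns @ coef
    return _cosine(centroid, fitted)


def identify_thrombus_clusters(
    model: ClusterModel,
    basis: BasisSpectraSet,
    sim_threshold: float = 0.98,
    override: set[int] | None = None,
) -> set[int]:
    """Select the cluster ids whose centroids look like thrombus.

    A cluster is selected when its centroid has cosine similarity >=
    ``sim_threshold`` to its best nonnegative mixture of the RBC and plasma
    basis spectra AND is not better explained by a filter/ice mixture.  An
    explicit ``override`` id set (the by-inspection assignment) is returned
    verbatim.  Emits a warning if the automatic selection is empty.
    """
    if override is not None:
        bad = {i for i in override if not 1 <= i <= model.K}
        if bad:
            raise ValueError(f"override ids out of range 1..{model.K}: {sorted(bad)}")
        return set(override)

    b = basis.resample(model.wavelengths)
    blood_cols = np.column_stack([b["rbc"], b["plasma"]])
    bg_cols = np.column_stack([b["filter"], b["ice"]])
    selected: set[int] = set()
    for k in range(model.K):
        c = model.centroids[k]
        sim_blood = _mix_similarity(c, blood_cols)
        sim_bg = _mix_similarity(c, bg_cols)
        if sim_blood >= sim_threshold and sim_blood > sim_bg:
            selected.add(k + 1)
    if not selected:
        warnings.warn(
            "no cluster matched the RBC/plasma signature; consider an explicit override",
            stacklevel=2,
        )
    return selected


def mask_thrombus(labels: LabelMap, thrombus_ids: set[int]) -> np.ndarray:
    """Boolean mask, True where the pixel's cluster id is in ``thrombus_ids``."""
    return np.isin(labels.labels, list(thrombus_ids))


def thrombus_area_fraction(mask: np.ndarray) -> float:
    """Share of image pixels flagged as thrombus, in [0, 1]."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty image")
    return float(mask.mean())


def fit_kfraction_model(
    pixel_sets: list[np.ndarray],
    K2: int = 7,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
    **kmeans_kw,
) -> ClusterModel:
    """Fit the second-pass K2-means model on thrombus pixels pooled across samples."""
    pooled = np.vstack([p for p in pixel_sets if p.size])
    return fit_kmeans(
        pooled, K2, seed=seed, wavelengths=wavelengths, fitted_on="pooled", **kmeans_kw
    )


def kfractions(
    cube: SpectralCube,
    mask: np.ndarray,
    K2: int = 7,
    seed: int = 0,
    model: ClusterModel | None = None,
    **kmeans_kw,
) -> KFractionProfile:
    """Compute a sample's k-fraction profile from its thrombus pixels.

    With ``model`` given (the pooled pre-fitted K2-means model) the pixels are
    assigned to its centroids; otherwise a single-sample model is fitted here.
    Fewer than K2 thrombus pixels yields a degenerate profile (fractions
    undefined).
    """
    mask = np.asarray(mask, dtype=bool)
    area = thrombus_area_fraction(mask)
    X = cube.pixels()[mask.ravel()]
    n = X.shape[0]
    if n < K2:
        return KFractionProfile(
            sample_id=cube.sample_id,
            fractions=None,
            n_thrombus_pixels=n,
            area_fraction=area,
            degenerate=True,
        )
    if model is None:
        model = fit_kmeans(
            X, K2, seed=seed, wavelengths=cube.wavelengths, fitted_on="single", **kmeans_kw
        )
    labels = _assign(model, X)
    counts = np.bincount(labels - 1, minlength=model.K)
    return KFractionProfile(
        sample_id=cube.sample_id,
        fractions=counts / n,
        n_thrombus_pixels=n,
        area_fraction=area,
    )


# ---------------------------------------------------------------------------
# Rendering

#: 11 visually distinct colours (index 0 unused; masked pixels render black).
DEFAULT_PALETTE = np.array(
    [
        [31, 119, 180], [255, 127, 14], [44, 160, 44], [214, 39, 40],
        [148, 103, 189], [140, 86, 75], [227, 119, 194], [127, 127, 127],
        [188, 189, 34], [23, 190, 207], [255, 187, 120], [174, 199, 232],
    ],
    dtype=np.uint8,
)


def render_false_colour(labels: LabelMap, palette: np.ndarray | None = None) -> np.ndarray:
    """Render a label map as an (H, W, 3) uint8 image, one colour per cluster.

    Masked-out pixels (label 0) are black.  The palette must provide at least
    K colours.
    """
    palette = DEFAULT_PALETTE if palette is None else np.asarray(palette, dtype=np.uint8)
    if palette.shape[0] < labels.K:
        raise ValueError(f"palette has {palette.shape[0]} colours but K={labels.K}")
    img = np.zeros(labels.labels.shape + (3,), dtype=np.uint8)
    fg = labels.labels > 0
    img[fg] = palette[labels.labels[fg] - 1]
    return img
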