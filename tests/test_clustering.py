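"""Two-pass k-means: Lloyd correctness against brute force, labels, k-fractions."""

import itertools

import numpy as np
import pytest

from thrombospec.clustering import (
    ClusterModel,
    LabelMap,
    assign_pixels,
    fit_kmeans,
    identify_thrombus_clusters,
    kfractions,
    mask_thrombus,
    render_false_colour,
    thrombus_area_fraction,
)
from thrombospec.spectral_io import GridMismatchError, SpectralCube


def brute_force_sse(X: np.ndarray, K: int) -> float:
    """Global k-means optimum by exhaustive enumeration of all assignments."""
    n = X.shape[0]
    best = np.inf
    for assign in itertools.product(range(K), repeat=n):
        sse = 0.0
        for k in range(K):
            members = X[np.array(assign) == k]
            if len(members):
                sse += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


class TestFitKmeans:
    def test_k1_centroid_is_mean(self):
        rng = np.random.default_rng(0)
        X = rng.random((20, 4))
        m = fit_kmeans(X, K=1, seed=0, n_restarts=1)
        np.testing.assert_allclose(m.centroids[0], X.mean(axis=0), rtol=1e-12)
        np.testing.assert_allclose(m.final_sse, ((X - X.mean(0)) ** 2).sum(), rtol=1e-12)

    def test_k_equals_n_gives_zero_sse(self):
        rng = np.random.default_rng(1)
        X = rng.random((6, 3))
        m = fit_kmeans(X, K=6, seed=0, n_restarts=25)
        assert m.final_sse == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n, b, K = rng.integers(4, 9), rng.integers(1, 3), rng.integers(2, 4)
        X = rng.random((n, b))
        m = fit_kmeans(X, K=int(K), seed=0, n_restarts=25)
        assert m.final_sse == pytest.approx(brute_force_sse(X, int(K)), rel=1e-9, abs=1e-12)

    def test_agrees_with_sklearn_reference(self):
        # independent cross-check of the Lloyd loop on a mid-size instance
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(4)
        X = rng.random((200, 10))
        ours = fit_kmeans(X, K=4, seed=0, n_restarts=10)
        ref = KMeans(n_clusters=4, n_init=10, random_state=0, tol=1e-10).fit(X)
        assert ours.final_sse == pytest.approx(ref.inertia_, rel=1e-6)

    def test_sse_trace_non_increasing(self):
        rng = np.random.default_rng(2)
        X = rng.random((100, 5))
        m = fit_kmeans(X, K=3, seed=0, n_restarts=5)
        assert np.all(np.diff(m.sse_trace) <= 1e-9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.random((50, 6))
        a = fit_kmeans(X, K=3, seed=11, n_restarts=5)
        b = fit_kmeans(X, K=3, seed=11, n_restarts=5)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_k_exceeding_distinct_points_rejected(self):
        X = np.array([[1.0], [1.0], [2.0]])
        with pytest.raises(ValueError, match="distinct"):
            fit_kmeans(X, K=3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_kmeans(np.empty((0, 3)), K=1)


def _model_from_centroids(C, wl):
    return ClusterModel(K=C.shape[0], centroids=np.asarray(C, float), wavelengths=np.asarray(wl, float))


class TestAssign:
    def test_pixel_equal_to_centroid(self):
        wl = np.array([500.0, 600.0])
        C = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        cube = SpectralCube(values=np.array([[[2.0, 2.0]]]), wavelengths=wl)
        lm = assign_pixels(_model_from_centroids(C, wl), cube)
        assert lm.labels[0, 0] == 3

    def test_tie_broken_to_lowest_id(self):
        wl = np.array([500.0, 600.0])
        C = np.array([[0.0, 0.0], [0.0, 0.0], [2.0, 2.0]])
        cube = SpectralCube(values=np.array([[[0.0, 0.0]]]), wavelengths=wl)
        lm = assign_pixels(_model_from_centroids(C, wl), cube)
        assert lm.labels[0, 0] == 1

    def test_training_assignment_is_fixed_point(self):
        rng = np.random.default_rng(5)
        X = rng.random((64, 8))
        wl = np.linspace(470, 900, 8)
        m = fit_kmeans(X, K=3, seed=0, n_restarts=5, wavelengths=wl)
        cube = SpectralCube(values=X.reshape(8, 8, 8), wavelengths=wl)
        lm = assign_pixels(m, cube)
        # re-computing centroids from the assignment reproduces the model
        for k in range(1, 4):
            members = X[lm.labels.ravel() == k]
            np.testing.assert_allclose(members.mean(axis=0), m.centroids[k - 1], atol=1e-8)

    def test_grid_mismatch_rejected(self):
        wl = np.array([500.0, 600.0])
        cube = SpectralCube(values=np.ones((1, 1, 3)), wavelengths=[500, 600, 700])
        with pytest.raises(GridMismatchError):
            assign_pixels(_model_from_centroids(np.ones((2, 2)), wl), cube)


class TestThrombusSelection:
    def test_override_returned_verbatim(self, basis, default_grid):
        m = _model_from_centroids(np.ones((11, default_grid.size)), default_grid)
        assert identify_thrombus_clusters(m, basis, override={9, 11}) == {9, 11}

    def test_override_out_of_range_rejected(self, basis, default_grid):
        m = _model_from_centroids(np.ones((11, default_grid.size)), default_grid)
        with pytest.raises(ValueError, match="range"):
            identify_thrombus_clusters(m, basis, override={0, 12})

    def test_rbc_centroid_selected_filter_not(self, basis, default_grid):
        C = np.vstack([basis["rbc"], basis["filter"], basis["ice"]])
        m = _model_from_centroids(C, default_grid)
        ids = identify_thrombus_clusters(m, basis)
        assert 1 in ids and 2 not in ids and 3 not in ids

    def test_empty_selection_warns(self, basis, default_grid):
        m = _model_from_centroids(np.vstack([basis["filter"], basis["ice"]]), default_grid)
        with pytest.warns(UserWarning, match="override"):
            ids = identify_thrombus_clusters(m, basis)
        assert ids == set()


class TestMaskAndArea:
    def test_mask_and_histogram_agree(self):
        labels = LabelMap(labels=np.array([[1, 2], [3, 2]]), K=3)
        mask = mask_thrombus(labels, {2})
        assert mask.sum() == (labels.labels == 2).sum() == 2

    def test_area_fraction_values(self):
        assert thrombus_area_fraction(np.ones((5, 5), bool)) == 1.0
        assert thrombus_area_fraction(np.zeros((5, 5), bool)) == 0.0
        m = np.zeros(100, bool)
        m[:30] = True
        assert thrombus_area_fraction(m.reshape(10, 10)) == pytest.approx(0.30)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            thrombus_area_fraction(np.zeros((0, 0), bool))


class TestKFractions:
    def _uniform_cube(self, value, n=20, b=4):
        vals = np.full((1, n, b), float(value))
        return SpectralCube(values=vals, wavelengths=np.linspace(470, 900, b))

    def test_identical_pixels_concentrate_in_one_cluster(self):
        cube = self._uniform_cube(0.5)
        mask = np.ones((1, 20), bool)
        prof = kfractions(cube, mask, K2=1)
        np.testing.assert_allclose(prof.fractions, [1.0])
        assert prof.n_thrombus_pixels == 20

    def test_two_balanced_subpopulations(self):
        vals = np.concatenate([np.zeros((1, 10, 3)), np.ones((1, 10, 3))], axis=1)
        cube = SpectralCube(values=vals, wavelengths=[500.0, 600.0, 700.0])
        prof = kfractions(cube, np.ones((1, 20), bool), K2=2, n_restarts=5)
        np.testing.assert_allclose(sorted(prof.fractions), [0.5, 0.5])

    def test_fractions_sum_to_one_and_bounded(self, basis):
        from thrombospec.synthetic_data import default_scene, make_cube

        cube, truth = make_cube(default_scene(24, 24, noise_sd=0.01, seed=6), basis)
        prof = kfractions(cube, truth.thrombus_mask, K2=7, n_restarts=5)
        assert prof.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((prof.fractions >= 0) & (prof.fractions <= 1))
        assert prof.area_fraction == pytest.approx(truth.true_area_fraction)

    def test_relabelling_permutes_fractions(self, basis):
        from thrombospec.synthetic_data import default_scene, make_cube

        cube, truth = make_cube(default_scene(24, 24, noise_sd=0.01, seed=6), basis)
        mask = truth.thrombus_mask
        X = cube.pixels()[mask.ravel()]
        m = fit_kmeans(X, K=3, seed=0, n_restarts=5, wavelengths=cube.wavelengths)
        prof = kfractions(cube, mask, K2=3, model=m)
        perm = np.array([2, 0, 1])
        m2 = ClusterModel(K=3, centroids=m.centroids[perm], wavelengths=m.wavelengths)
        prof2 = kfractions(cube, mask, K2=3, model=m2)
        np.testing.assert_allclose(prof2.fractions, prof.fractions[perm])

    def test_too_few_pixels_degenerate(self):
        cube = self._uniform_cube(0.5, n=3)
        mask = np.zeros((1, 3), bool)
        mask[0, 0] = True
        prof = kfractions(cube, mask, K2=7)
        assert prof.degenerate and prof.fractions is None


class TestRendering:
    def test_distinct_colours_and_black_mask(self):
        labels = LabelMap(labels=np.array([[0, 1], [2, 3]]), K=3)
        img = render_false_colour(labels)
        assert img.shape == (2, 2, 3)
        np.testing.assert_array_equal(img[0, 0], [0, 0, 0])
        colours = {tuple(img[i, j]) for i in range(2) for j in range(2)}
        assert len(colours) == 4

    def test_small_palette_rejected(self):
        labels = LabelMap(labels=np.array([[1, 2, 3]]), K=3)
        with pytest.raises(ValueError, match="palette"):
            render_false_colour(labels, palette=np.zeros((2, 3), np.uint8))
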