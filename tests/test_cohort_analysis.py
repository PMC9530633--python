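"""Clinical indices, thresholding, and the four regression families."""

import numpy as np
import pandas as pd
import pytest

from thrombospec.cohort_analysis import (
    compare_models,
    compute_imr,
    dichotomize,
    filter_successful,
    fit_model,
    predict,
)
from thrombospec.synthetic_data import CohortSpec, make_cohort


class TestIMR:
    def test_product(self):
        assert compute_imr(80.0, 0.5) == pytest.approx(40.0)
        assert compute_imr(60.0, 1.0) == pytest.approx(60.0)

    def test_vectorised(self):
        np.testing.assert_allclose(compute_imr([80, 100], [0.5, 0.2]), [40.0, 20.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            compute_imr(100.0, 0.0)
        with pytest.raises(ValueError):
            compute_imr(-1.0, 0.5)


class TestDichotomize:
    def test_thresholds_strict(self):
        df = pd.DataFrame({"imr": [50.0, 40.0, 30.0], "mvo": [2.0, 1.55, np.nan]})
        out = dichotomize(df)
        assert out["imr_high"].tolist() == [True, False, False]
        assert out["mvo_high"][0] and not out["mvo_high"][1]
        assert pd.isna(out["mvo_high"][2])

    def test_severe_requires_both(self):
        df = pd.DataFrame({"imr": [50.0, 50.0], "mvo": [2.0, 1.0]})
        out = dichotomize(df)
        assert out["severe"].tolist() == [True, False]


class TestFilterSuccessful:
    def _records(self):
        return pd.DataFrame(
            {
                "patient_id": ["a", "b", "c", "d", "e"],
                "thrombus_score": [5, 5, 3, 4, 4],
                "area_fraction": [0.30, 0.10, 0.50, 0.22, 0.219],
            }
        )

    def test_score_and_area_rules(self):
        kept, audit = filter_successful(self._records())
        assert kept["patient_id"].tolist() == ["a", "d"]  # 0.22 is inclusive
        assert audit["kept"].sum() == 2
        assert not audit.loc[audit["patient_id"] == "c", "score_ok"].item()

    def test_idempotent_and_order_independent(self):
        rec = self._records()
        once, _ = filter_successful(rec)
        twice, _ = filter_successful(once)
        pd.testing.assert_frame_equal(once, twice)
        shuffled, _ = filter_successful(rec.sample(frac=1, random_state=0))
        assert set(shuffled["patient_id"]) == set(once["patient_id"])


class TestPredict:
    def test_family_formulas(self):
        f = np.array([0.5, 0.5])
        assert predict("linear", np.array([1.0, 2.0, 3.0]), f) == pytest.approx(3.5)
        assert predict("exp", np.array([100.0, 0.0, 0.0]), f) == pytest.approx(100.0)
        assert predict("sat_exp", np.array([5.0, 0.0, 0.0]), f) == pytest.approx(0.0)
        assert predict("power", np.array([2.0, 1.0, 1.0]), f) == pytest.approx(2.0 * 0.25)

    def test_power_zero_fraction_guarded(self):
        y = predict("power", np.array([2.0, 1.0, 1.0]), np.array([0.0, 1.0]))
        assert np.isfinite(y) and y > 0


def _cohort(model="exp", n=100, noise=0.0, seed=0, coeffs=None):
    spec = CohortSpec(
        n_patients=n,
        model=model,
        noise_sd=noise,
        seed=seed,
        **({"coefficients": coeffs} if coeffs else {}),
    )
    return make_cohort(spec)


class TestFitModel:
    def test_noiseless_exp_recovery(self):
        truth = (150.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)  # min c_k = 0 gauge
        df = _cohort("exp", noise=0.0, seed=1, coeffs=truth)
        fit = fit_model(df, "imr", "exp", n_starts=5, seed=0, permutations=0)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(fit.coefficients, truth, rtol=1e-4)

    def test_noiseless_linear_recovery_r2_one(self):
        df = _cohort("linear", noise=0.0, seed=2, coeffs=(10.0, 1, 2, 3, 4, 5, 6, 7))
        fit = fit_model(df, "imr", "linear", permutations=0)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_target_r2_zero(self):
        df = _cohort("exp", seed=3)
        df["imr"] = 42.0
        for model in ("linear", "exp"):
            fit = fit_model(df, "imr", model, n_starts=3, permutations=0)
            assert fit.r2 == pytest.approx(0.0, abs=1e-9)

    def test_exp_matches_grid_search_oracle_k1(self):
        # single-fraction toy: dense (c0, c1) grid search is the oracle
        rng = np.random.default_rng(4)
        f1 = rng.uniform(0.05, 0.95, 10)
        y = 20.0 * np.exp(-1.5 * f1) + rng.normal(0, 0.3, 10)
        df = pd.DataFrame({"f_1": f1, "imr": y})
        fit = fit_model(df, "imr", "exp", n_starts=10, seed=0, permutations=0)
        c0g, c1g = np.meshgrid(np.linspace(10, 30, 201), np.linspace(0, 3, 201))
        sse = ((c0g[..., None] * np.exp(-c1g[..., None] * f1) - y) ** 2).sum(-1)
        assert fit.sse <= sse.min() + 1e-6  # optimizer at least as good as the grid

    def test_missing_targets_dropped_and_counted(self):
        df = _cohort("exp", n=40, seed=5)
        df.loc[:9, "imr"] = np.nan
        fit = fit_model(df, "imr", "exp", n_starts=3, permutations=0)
        assert fit.n == 30

    def test_insufficient_records_rejected(self):
        df = _cohort("exp", n=8, seed=6)
        with pytest.raises(ValueError, match="k\\+2"):
            fit_model(df, "imr", "exp", permutations=0)

    def test_permutation_p_small_for_real_signal(self):
        df = _cohort("exp", n=60, noise=2.0, seed=7)
        fit = fit_model(df, "imr", "linear", seed=0, permutations=99)
        assert fit.p_value == pytest.approx(0.01)  # strongest possible at B=99

    def test_linear_f_pvalue_reported(self):
        df = _cohort("exp", n=60, noise=2.0, seed=8)
        fit = fit_model(df, "imr", "linear", permutations=0)
        assert fit.f_pvalue is not None and 0 <= fit.f_pvalue < 0.05

    def test_r2_bounded_above_by_one(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({f"f_{j+1}": rng.dirichlet(np.ones(3), 30)[:, j] for j in range(3)})
        df["mvo"] = rng.normal(2.0, 0.5, 30)
        for model in ("linear", "power", "exp", "sat_exp"):
            fit = fit_model(df, "mvo", model, n_starts=3, seed=1, permutations=0)
            assert fit.r2 <= 1.0 + 1e-12


class TestCompareModels:
    def test_four_rows_ranked(self):
        df = _cohort("exp", n=80, noise=3.0, seed=10)
        table = compare_models(df, "imr", n_starts=3, permutations=0)
        assert len(table) == 4
        assert set(table["model"]) == {"linear", "power", "exp", "sat_exp"}
        assert (table["r2"].diff().dropna() <= 1e-12).all()  # descending

    def test_notable_threshold_applied(self):
        df = _cohort("exp", n=80, noise=0.5, seed=11)
        table = compare_models(df, "imr", n_starts=3, permutations=0)
        top = table.iloc[0]
        assert top["notable"] == (top["r2"] > 0.2)
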