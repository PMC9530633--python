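"""Cohort-level analysis: microvascular-injury indices regressed on k-fractions.

A patient record joins the spectral signature of the aspirated thrombus
(k-fractions f_1..f_k and thrombus area fraction) with clinical measurements:
the angiographic thrombus score (0-5), the index of microcirculatory
resistance IMR = hyperaemic distal pressure (mmHg) x mean transit time (s),
and microvascular obstruction MVO (% of LV mass from cardiac MRI).

The module provides:

* the IMR product and the standard dichotomisations (IMR > 40 U clinically
  significant; MVO > 1.55 % prognostically significant; both together =
  severe microvascular dysfunction);
* the thrombectomy-adequacy filter — only samples with angiographic score 4-5
  AND thrombus area fraction >= 0.22 represent the in-situ thrombus well
  enough to carry a spectral signal;
* four regression families linking an injury index y to the k-fractions:

  - linear:   y = c0 + Σ c_k f_k
  - power:    y = c0 · Π f_k^{c_k}
  - exp:      y = c0 · exp(−Σ c_k f_k)
  - sat_exp:  y = c0 · [1 − exp(−Σ c_k f_k)]

  fitted by closed-form least squares (linear) or multi-start nonlinear least
  squares, with R² goodness of fit and a permutation p-value.

Because the fractions sum to one, the linear and exp families carry a gauge
freedom (adding δ to every c_k is absorbed by the intercept / by rescaling
c0).  Reported exp-model coefficients are canonicalised to min_k c_k = 0; the
linear fit reports the minimum-norm solution.  R² and predictions are
unaffected by the gauge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "IMR_THRESHOLD",
    "MVO_THRESHOLD",
    "AREA_THRESHOLD",
    "RegressionFit",
    "MODELS",
    "compute_imr",
    "dichotomize",
    "filter_successful",
    "predict",
    "fit_model",
    "compare_models",
    "fraction_columns",
]

IMR_THRESHOLD = 40.0    # U, clinically significant microvascular resistance
MVO_THRESHOLD = 1.55    # % LV mass, prognostically significant obstruction
AREA_THRESHOLD = 0.22   # minimum thrombus area fraction for adequate thrombectomy
NOTABLE_R2 = 0.2        # R² above this is considered biologically notable

MODELS = ("linear", "power", "exp", "sat_exp")
_POWER_EPS = 1e-6       # floor on fractions before exponentiation


def compute_imr(pd_hyperaemic, transit_time):
    """IMR (U) = hyperaemic mean distal coronary pressure (mmHg) x mean transit time (s)."""
    p = np.asarray(pd_hyperaemic, dtype=float)
    t = np.asarray(transit_time, dtype=float)
    if np.any(p <= 0) or np.any(t <= 0):
        raise ValueError("pressure and transit time must both be positive")
    out = p * t
    return float(out) if out.ndim == 0 else out


def dichotomize(records: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Flag records against the clinical thresholds (strict '>' comparisons).

    Adds nullable-boolean columns ``imr_high`` (IMR > 40 U), ``mvo_high``
    (MVO > 1.55 %) and ``severe`` (both); missing inputs give missing flags.
    """
    df = records.to_frame().T if isinstance(records, pd.Series) else records.copy()
    imr = pd.to_numeric(df.get("imr"), errors="coerce") if "imr" in df else pd.Series(np.nan, index=df.index)
    mvo = pd.to_numeric(df.get("mvo"), errors="coerce") if "mvo" in df else pd.Series(np.nan, index=df.index)
    out = df.copy()
    out["imr_high"] = pd.array(np.where(imr.notna(), imr > IMR_THRESHOLD, None), dtype="boolean")
    out["mvo_high"] = pd.array(np.where(mvo.notna(), mvo > MVO_THRESHOLD, None), dtype="boolean")
    out["severe"] = out["imr_high"] & out["mvo_high"]
    return out


def filter_successful(
    records: pd.DataFrame,
    area_threshold: float = AREA_THRESHOLD,
    eligible_scores: set[int] = frozenset({4, 5}),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep records representing successful thrombectomy.

    A record passes when its angiographic thrombus score is eligible (4 or 5
    by default) AND its thrombus area fraction is at or above the threshold
    (0.22 is the stated minimum, hence '>=').  Returns (subset, audit) where
    the audit table records the per-record pass/fail of each condition.
    """
    score_ok = records["thrombus_score"].isin(list(eligible_scores))
    area_ok = records["area_fraction"] >= area_threshold
    kept = score_ok & area_ok
    audit = pd.DataFrame(
        {
            "patient_id": records.get("patient_id", pd.Series(records.index, index=records.index)),
            "thrombus_score": records["thrombus_score"],
            "area_fraction": records["area_fraction"],
            "score_ok": score_ok,
            "area_ok": area_ok,
            "kept": kept,
        }
    )
    return records[kept].copy(), audit


# ---------------------------------------------------------------------------
# Regression families

def fraction_columns(records: pd.DataFrame) -> list[str]:
    """The k-fraction columns f_1..f_k, in index order."""
    pat = re.compile(r"^f_(\d+)$")
    hits = [(int(m.group(1)), c) for c in records.columns if (m := pat.match(c))]
    return [c for _, c in sorted(hits)]


def predict(model: str, coefficients: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Evaluate a regression family at fraction vectors ``fractions`` (n, k) or (k,).

    Power-model fractions are floored at 1e-6 before exponentiation so that
    zero fractions cannot produce infinities.
    """
    c = np.asarray(coefficients, dtype=float)
    F = np.atleast_2d(np.asarray(fractions, dtype=float))
    if F.shape[1] != c.size - 1:
        raise ValueError(f"need {c.size - 1} fractions per record, got {F.shape[1]}")
    c0, ck = c[0], c[1:]
    if model == "linear":
        y = c0 + F @ ck
    elif model == "power":
        y = c0 * np.exp(np.log(np.maximum(F, _POWER_EPS)) @ ck)
    elif model == "exp":
        y = c0 * np.exp(-(F @ ck))
    elif model == "sat_exp":
        y = c0 * (1.0 - np.exp(-(F @ ck)))
    else:
        raise ValueError(f"unknown model: {model!r}")
    return y[0] if np.asarray(fractions).ndim == 1 else y


@dataclass
class RegressionFit:
    """A fitted family: coefficients (c0, c1..ck), R², permutation p, metadata."""

    model: str
    target: str
    coefficients: np.ndarray
    r2: float
    p_value: float | None
    n: int
    k: int
    sse: float
    converged: bool
    f_pvalue: float | None = None   # classical overall-F p, linear model only

    def predict(self, fractions: np.ndarray) -> np.ndarray:
        return predict(self.model, self.coefficients, fractions)


def _fit_linear(F: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    A = np.column_stack([np.ones(len(y)), F])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid), rank < A.shape[1]


def _start_for(model: str, F: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Linearisation-derived starting point for the nonlinear families."""
    k = F.shape[1]
    ymax = float(np.max(np.abs(y))) or 1.0
    ypos = np.maximum(y, 1e-6 * ymax)
    if model == "exp":
        # log y = log c0 − Σ c_k f_k
        coef, _, _ = _fit_linear(F, np.log(ypos))
        return np.concatenate([[np.exp(coef[0])], -coef[1:]])
    if model == "power":
        coef, _, _ = _fit_linear(np.log(np.maximum(F, _POWER_EPS)), np.log(ypos))
        return np.concatenate([[np.exp(coef[0])], coef[1:]])
    if model == "sat_exp":
        c0 = 1.2 * float(np.max(y)) if np.max(y) > 0 else 1.0
        frac = np.clip(ypos / c0, 1e-6, 1.0 - 1e-6)
        coef, _, _ = _fit_linear(F, -np.log(1.0 - frac))
        return np.concatenate([[c0], coef[1:]])
    raise ValueError(model)


def _canonicalize(model: str, coef: np.ndarray) -> np.ndarray:
    """Fix the simplex gauge: exp-model coefficients shifted to min_k c_k = 0."""
    coef = coef.copy()
    if model == "exp" and coef.size > 1:
        m = coef[1:].min()
        coef[1:] -= m
        coef[0] *= np.exp(-m)
    return coef


def _fit_nonlinear(
    model: str,
    F: np.ndarray,
    y: np.ndarray,
    n_starts: int,
    rng: np.random.Generator,
    ftol: float = 1e-10,
) -> tuple[np.ndarray, float, bool]:
    base = _start_for(model, F, y)
    scale = np.maximum(np.abs(base), 1.0)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return predict(model, theta, F) - y

    best_coef, best_sse, best_ok = base, np.inf, False
    for s in range(max(1, n_starts)):
        theta0 = base if s == 0 else base + rng.normal(0.0, 0.5, size=base.size) * scale
        if model in ("exp", "power", "sat_exp"):
            theta0[0] = abs(theta0[0]) or 1.0
        try:
            res = least_squares(residuals, theta0, ftol=ftol, xtol=1e-12, gtol=1e-12, max_nfev=200 * base.size)
        except (ValueError, FloatingPointError):
            continue
        sse = float(2.0 * res.cost)
        if sse < best_sse:
            best_coef, best_sse, best_ok = res.x, sse, bool(res.success)
    return _canonicalize(model, best_coef), best_sse, best_ok


def _r2(sse: float, y: np.ndarray) -> float:
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        return 0.0
    return 1.0 - sse / sst


def fit_model(
    records: pd.DataFrame,
    target: str,
    model: str,
    n_starts: int = 20,
    seed: int = 0,
    permutations: int = 999,
) -> RegressionFit:
    """Fit one regression family of ``target`` (imr or mvo) on the k-fractions.

    Records with a missing target are dropped (a patient missing MVO still
    contributes to the IMR fit and vice versa); at least k+2 complete records
    are required.  The linear family is solved in closed form and additionally
    reports the classical overall-F p-value; nonlinear families use
    multi-start nonlinear least squares from a linearisation-derived start.
    The permutation p-value shuffles the target across records and refits
    (p = (1 + #{R²_perm >= R²_obs}) / (B + 1)); permutations=0 disables it.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model: {model!r} (choose from {MODELS})")
    fcols = fraction_columns(records)
    if not fcols:
        raise ValueError("records carry no k-fraction columns f_1..f_k")
    k = len(fcols)
    sub = records.dropna(subset=[target])
    n = len(sub)
    if n < k + 2:
        raise ValueError(f"need at least k+2 = {k + 2} records with {target}, have {n}")
    F = sub[fcols].to_numpy(dtype=float)
    y = sub[target].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    def one_fit(yy: np.ndarray, starts: int) -> tuple[np.ndarray, float, bool, float | None]:
        if model == "linear":
            coef, sse, _deficient = _fit_linear(F, yy)
            fp = _linear_f_pvalue(F, yy, sse)
            return coef, sse, True, fp
        coef, sse, ok = _fit_nonlinear(model, F, yy, starts, rng)
        return coef, sse, ok, None

    coef, sse, converged, f_p = one_fit(y, n_starts)
    r2 = _r2(sse, y)

    p_value: float | None = None
    if permutations > 0:
        perm_starts = max(1, n_starts // 5)
        hits = 0
        for _ in range(permutations):
            yp = rng.permutation(y)
            _, sse_p, _, _ = one_fit(yp, perm_starts)
            if _r2(sse_p, yp) >= r2:
                hits += 1
        p_value = (1 + hits) / (permutations + 1)

    return RegressionFit(
        model=model,
        target=target,
        coefficients=coef,
        r2=r2,
        p_value=p_value,
        n=n,
        k=k,
        sse=sse,
        converged=converged,
        f_pvalue=f_p,
    )


def _linear_f_pvalue(F: np.ndarray, y: np.ndarray, sse: float) -> float | None:
    """Overall F-test of the linear fit, using the design's actual rank."""
    A = np.column_stack([np.ones(len(y)), F])
    rank = np.linalg.matrix_rank(A)
    df_model = rank - 1
    df_resid = len(y) - rank
    if df_model < 1 or df_resid < 1:
        return None
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = sst - sse
    if sse <= 0:
        return 0.0
    f = (ssr / df_model) / (sse / df_resid)
    return float(stats.f.sf(f, df_model, df_resid))


def compare_models(
    records: pd.DataFrame,
    target: str,
    n_starts: int = 20,
    seed: int = 0,
    permutations: int = 999,
) -> pd.DataFrame:
    """Fit all four families and rank them by R².

    Returns one row per family — model, R², permutation p, whether R²
    exceeds the 0.2 'biologically notable' threshold, convergence, n — sorted
    by R² descending; the fitted objects ride along in the ``fit`` column.
    """
    rows = []
    for i, model in enumerate(MODELS):
        fit = fit_model(
            records, target, model, n_starts=n_starts, seed=seed + i, permutations=permutations
        )
        rows.append(
            {
                "model": model,
                "r2": fit.r2,
                "p_value": fit.p_value,
                "notable": fit.r2 > NOTABLE_R2,
                "converged": fit.converged,
                "n": fit.n,
                "fit": fit,
            }
        )
    table = pd.DataFrame(rows).sort_values("r2", ascending=False, kind="stable").reset_index(drop=True)
    return table
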