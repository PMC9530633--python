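"""End-to-end orchestration: config validation and the full analysis run.

The pipeline mirrors the experimental flow: read cubes → (optional
preprocessing) → pooled K-means over all samples → thrombus-cluster selection
and masking → thrombus area fractions → pooled second-pass K2-means
k-fractions → per-pixel basis unmixing → join with the clinical table →
thrombectomy-adequacy thresholding → regression of IMR/MVO on the
k-fractions.  Every stage logs its parameters; identical configs and seeds
give identical numeric outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import basis_fitting, clustering, cohort_analysis, spectral_io

log = logging.getLogger("thrombospec")

__all__ = ["RunConfig", "ConfigError", "PipelineError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Aggregated configuration violations; ``.config`` holds the defaults-completed config."""

    def __init__(self, messages: list[str], config: "RunConfig"):
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(messages))
        self.messages = messages
        self.config = config


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run (defaults echo the method)."""

    cubes: list[str] = dc_field(default_factory=list)
    basis: str | None = None
    cohort: str | None = None
    output_dir: str = "thrombospec_out"
    preprocess: str = "none"
    K: int = 11
    K2: int = 7
    cluster_seed: int = 0
    restarts: int = 25
    pooled: bool = True
    thrombus_ids: list[int] | None = None
    sim_threshold: float = 0.98
    unmix_mode: str = "nnls"
    area_threshold: float = cohort_analysis.AREA_THRESHOLD
    eligible_scores: list[int] = dc_field(default_factory=lambda: [4, 5])
    targets: list[str] = dc_field(default_factory=lambda: ["imr", "mvo"])
    models: list[str] = dc_field(default_factory=lambda: list(cohort_analysis.MODELS))
    permutations: int = 999
    regression_seed: int = 0
    n_starts: int = 20


def validate_config(path: str | Path) -> RunConfig:
    """Parse a YAML config, apply defaults, and report every violation at once."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"], RunConfig())

    cfg = RunConfig()
    errors: list[str] = []

    cfg.cubes = [str(p) for p in raw.get("cubes", [])]
    cfg.basis = raw.get("basis")
    cfg.cohort = raw.get("cohort")
    cfg.output_dir = str(raw.get("output_dir", cfg.output_dir))
    cfg.preprocess = str(raw.get("preprocess", cfg.preprocess))

    cl = raw.get("clustering", {}) or {}
    cfg.K = int(cl.get("K", cfg.K))
    cfg.K2 = int(cl.get("K2", cfg.K2))
    cfg.cluster_seed = int(cl.get("seed", cfg.cluster_seed))
    cfg.restarts = int(cl.get("restarts", cfg.restarts))
    cfg.pooled = bool(cl.get("pooled", cfg.pooled))
    ids = cl.get("thrombus_ids")
    cfg.thrombus_ids = [int(i) for i in ids] if ids else None
    cfg.sim_threshold = float(cl.get("sim_threshold", cfg.sim_threshold))

    cfg.unmix_mode = str((raw.get("unmix", {}) or {}).get("mode", cfg.unmix_mode))

    th = raw.get("threshold", {}) or {}
    cfg.area_threshold = float(th.get("area", cfg.area_threshold))
    cfg.eligible_scores = [int(s) for s in th.get("scores", cfg.eligible_scores)]

    rg = raw.get("regression", {}) or {}
    cfg.targets = [str(t) for t in rg.get("targets", cfg.targets)]
    models = rg.get("models", "all")
    cfg.models = list(cohort_analysis.MODELS) if models in ("all", None) else [str(m) for m in models]
    cfg.permutations = int(rg.get("permutations", cfg.permutations))
    cfg.regression_seed = int(rg.get("seed", cfg.regression_seed))
    cfg.n_starts = int(rg.get("n_starts", cfg.n_starts))

    # -- violations, all reported together
    if not cfg.cubes:
        errors.append("no input cubes given (key: cubes)")
    for p in cfg.cubes:
        if not Path(p).exists() and not Path(p).with_suffix(".hdr").exists():
            errors.append(f"cube not found: {p}")
    if cfg.basis is None:
        errors.append("no basis-spectra file given (key: basis)")
    elif not Path(cfg.basis).exists():
        errors.append(f"basis file not found: {cfg.basis}")
    if cfg.cohort is not None and not Path(cfg.cohort).exists():
        errors.append(f"cohort file not found: {cfg.cohort}")
    if cfg.K < 1:
        errors.append(f"K must be >= 1, got {cfg.K}")
    if cfg.K2 < 1:
        errors.append(f"K2 must be >= 1, got {cfg.K2}")
    if not 0 < cfg.area_threshold < 1:
        errors.append(f"area threshold must lie in (0, 1), got {cfg.area_threshold}")
    if cfg.preprocess not in ("none", "per_pixel_norm"):
        errors.append(f"unknown preprocess mode: {cfg.preprocess}")
    if cfg.unmix_mode not in ("nnls", "ols"):
        errors.append(f"unknown unmix mode: {cfg.unmix_mode}")
    for m in cfg.models:
        if m not in cohort_analysis.MODELS:
            errors.append(f"unknown regression model: {m}")
    for t in cfg.targets:
        if t not in ("imr", "mvo"):
            errors.append(f"unknown regression target: {t}")
    if any(s not in range(6) for s in cfg.eligible_scores):
        errors.append("eligible scores must lie in 0..5")

    if errors:
        raise ConfigError(errors, cfg)
    return cfg


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            log.info("stage %s: start", name)
            try:
                return fn(*a, **kw)
            except (ConfigError, PipelineError):
                raise
            except Exception as exc:  # abort with the stage name; partial outputs remain
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run report (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "config": vars(config).copy()}

    basis = spectral_io.read_basis_library(config.basis)

    cubes = []
    for p in config.cubes:
        cube = spectral_io.read_cube(p)
        cube = spectral_io.preprocess_cube(cube, config.preprocess)
        cubes.append(cube)
    report["stages"]["read"] = {"n_cubes": len(cubes)}
    log.info("read %d cubes, basis with components %s", len(cubes), basis.names)

    grid = cubes[0].wavelengths
    for c in cubes[1:]:
        if not np.array_equal(c.wavelengths, grid):
            raise PipelineError("stage 'read' failed: cubes are on different wavelength grids")

    # pass 1: pooled K-means over every pixel of every sample
    pooled_pixels = np.vstack([c.pixels() for c in cubes])
    model1 = clustering.fit_kmeans(
        pooled_pixels,
        config.K,
        seed=config.cluster_seed,
        n_restarts=config.restarts,
        wavelengths=grid,
        fitted_on="pooled" if config.pooled else "single",
    )
    label_maps = [clustering.assign_pixels(model1, c) for c in cubes]
    report["stages"]["kmeans_full"] = {"K": config.K, "sse": model1.final_sse}

    override = set(config.thrombus_ids) if config.thrombus_ids else None
    thrombus_ids = clustering.identify_thrombus_clusters(
        model1, basis, sim_threshold=config.sim_threshold, override=override
    )
    report["stages"]["thrombus_selection"] = {"ids": sorted(thrombus_ids)}
    log.info("thrombus clusters: %s", sorted(thrombus_ids))

    masks = [clustering.mask_thrombus(lm, thrombus_ids) for lm in label_maps]

    # pass 2: pooled K2-means on thrombus pixels only
    thrombus_sets = [c.pixels()[m.ravel()] for c, m in zip(cubes, masks)]
    pooled_thrombus = np.vstack([t for t in thrombus_sets if t.size])
    if pooled_thrombus.shape[0] < config.K2:
        raise PipelineError(
            f"stage 'kmeans_thrombus' failed: only {pooled_thrombus.shape[0]} thrombus pixels"
        )
    model2 = clustering.fit_kmeans(
        pooled_thrombus,
        config.K2,
        seed=config.cluster_seed,
        n_restarts=config.restarts,
        wavelengths=grid,
        fitted_on="pooled",
    )

    profiles = [
        clustering.kfractions(c, m, K2=config.K2, model=model2 if config.pooled else None,
                              seed=config.cluster_seed)
        for c, m in zip(cubes, masks)
    ]
    kf_rows = []
    for prof in profiles:
        row = {"sample_id": prof.sample_id}
        for j in range(config.K2):
            row[f"f_{j + 1}"] = np.nan if prof.fractions is None else prof.fractions[j]
        row["n_pixels"] = prof.n_thrombus_pixels
        row["area_fraction"] = prof.area_fraction
        row["degenerate"] = prof.degenerate
        kf_rows.append(row)
    kf = pd.DataFrame(kf_rows)
    kf.to_csv(out / "kfractions.csv", index=False)
    report["stages"]["kfractions"] = {
        "n_samples": len(kf),
        "n_degenerate": int(kf["degenerate"].sum()),
    }

    # per-pixel unmixing
    for cube in cubes:
        maps = basis_fitting.fit_cube(cube, basis.resample(grid), mode=config.unmix_mode)
        frame = pd.DataFrame(
            {name: arr.ravel() for name, arr in maps.as_dict().items()}
        )
        frame.insert(0, "pixel", np.arange(len(frame)))
        frame.to_csv(out / f"unmix_{cube.sample_id or 'cube'}.csv", index=False)
    report["stages"]["unmix"] = {"mode": config.unmix_mode, "n_cubes": len(cubes)}

    # clinical join + thresholding + regression
    fits_table = None
    if config.cohort is not None:
        clinical = pd.read_csv(config.cohort)
        clinical_cols = [c for c in ("patient_id", "thrombus_score", "pd", "tmn", "imr", "mvo")
                         if c in clinical.columns]
        clinical = clinical[clinical_cols]
        joined = kf.merge(clinical, left_on="sample_id", right_on="patient_id", how="inner")
        if "pd" in joined and "tmn" in joined and "imr" in joined:
            need = joined["imr"].isna() & joined["pd"].notna() & joined["tmn"].notna()
            if need.any():
                joined.loc[need, "imr"] = cohort_analysis.compute_imr(
                    joined.loc[need, "pd"], joined.loc[need, "tmn"]
                )
        joined = cohort_analysis.dichotomize(joined)
        kept, audit = cohort_analysis.filter_successful(
            joined,
            area_threshold=config.area_threshold,
            eligible_scores=set(config.eligible_scores),
        )
        audit.to_csv(out / "threshold_audit.csv", index=False)
        report["stages"]["threshold"] = {"n_joined": len(joined), "n_kept": len(kept)}

        k = len(cohort_analysis.fraction_columns(kf))
        fit_rows = []
        for target in config.targets:
            n_avail = int(kept[target].notna().sum()) if target in kept else 0
            if n_avail < k + 2:
                log.warning("target %s: only %d complete records, skipping fits", target, n_avail)
                continue
            for i, model_name in enumerate(config.models):
                fit = cohort_analysis.fit_model(
                    kept,
                    target,
                    model_name,
                    n_starts=config.n_starts,
                    seed=config.regression_seed + i,
                    permutations=config.permutations,
                )
                row = {
                    "target": target,
                    "model": model_name,
                    "r2": fit.r2,
                    "p_value": fit.p_value,
                    "n": fit.n,
                    "converged": fit.converged,
                    "notable": fit.r2 > cohort_analysis.NOTABLE_R2,
                }
                for j, c in enumerate(fit.coefficients):
                    row[f"c_{j}"] = c
                fit_rows.append(row)
        fits_table = pd.DataFrame(fit_rows)
        fits_table.to_csv(out / "fits.csv", index=False)
        report["stages"]["regression"] = {"n_fits": len(fits_table)}

    lines = ["thrombospec run report", "======================", ""]
    for stage, info in report["stages"].items():
        lines.append(f"{stage}: " + ", ".join(f"{k}={v}" for k, v in info.items()))
    if fits_table is not None and len(fits_table):
        lines += ["", "model fits (by target):"]
        for _, r in fits_table.iterrows():
            lines.append(
                f"  {r['target']:>4} {r['model']:>8}: R2={r['r2']:.4f}"
                + (f" p={r['p_value']:.4f}" if pd.notna(r.get("p_value")) else "")
                + f" n={int(r['n'])}"
            )
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    report["report_path"] = str(out / "report.txt")
    return report
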