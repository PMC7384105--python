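"""Cohort CSV reading/writing, run configuration and the end-to-end pipeline.

A single YAML config governs the indicator-set variant (full profile,
minus-IQ, minus-IQ-and-severity), the class-number search range, EM
settings, the prediction stage plan and the bootstrap settings, plus the
seeds.  The pipeline runs preprocess -> class enumeration -> canonical
relabeling -> profiling -> staged prediction -> optimism correction and
writes a manifest sufficient for exact replay.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lpa, prediction, profiling, validation
from .preprocess import prepare_indicators
from .simulate import default_cohort_config, generate_cohort
from .variables import CohortTable, VariableSpec, default_indicator_specs, validate_column

log = logging.getLogger(__name__)

MISSING_TOKENS = ("", "NA")


def read_cohort_csv(path: str | Path, specs: list[VariableSpec]) -> CohortTable:
    """Typed, mask-aware cohort table from a headed CSV.

    Empty cells and "NA" are missing.  Out-of-support values raise an
    error naming the rows and column; unknown columns warn and pass
    through untyped (covariates such as a site string are expected).
    """
    df = pd.read_csv(path, na_values=list(MISSING_TOKENS), keep_default_na=False)
    known = {s.name for s in specs}
    unknown = [c for c in df.columns if c not in known and c not in
               ("site", "weight", "include_predictive", "participant_id")]
    if unknown:
        log.warning("unknown columns passed through untyped: %s", unknown)
    for s in specs:
        if s.name not in df.columns:
            raise ValueError(f"column {s.name!r} missing from {path}")
        bad = validate_column(s, df[s.name].to_numpy(dtype=float))
        if bad:
            raise ValueError(
                f"{path}: variable {s.name!r} has out-of-support values in rows {bad}"
            )
    weights = df.pop("weight") if "weight" in df.columns else None
    include = (
        df.pop("include_predictive").astype(bool)
        if "include_predictive" in df.columns else None
    )
    if "participant_id" in df.columns:
        df = df.set_index("participant_id")
    return CohortTable(df, specs=[s for s in specs if s.name in df.columns],
                       weights=weights, include_predictive=include)


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    """Canonical CSV export (missing as empty cells, floats at 10 sig figs)."""
    df = table.data.copy()
    if table.weights is not None:
        df["weight"] = table.weights
    if table.include_predictive is not None:
        df["include_predictive"] = table.include_predictive
    df.to_csv(path, index_label="participant_id", float_format="%.10g", na_rep="")


def default_config() -> dict:
    return {
        "variant": "full",  # full | minus_iq | minus_iq_css
        "seed": 0,
        "generator": {"n": 500, "use": True},
        "input_csv": None,
        "em": {"K_range": [2, 3, 4, 5], "n_restarts": 5,
               "tol": 1.0e-6, "max_iter": 300},
        "anchor": "viq",
        "bootstrap": {"B": 100, "stratified": False},
        "prediction": {"ridge": 0.0},
        "outdir": "results/pipeline",
    }


def load_config(path: str | Path | None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict | str | Path | None = None) -> dict:
    """Execute the full analysis; write artifacts + manifest; return summary."""
    cfg = config if isinstance(config, dict) else load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}

    def _stage(name):
        log.info("pipeline stage: %s", name)
        return time.perf_counter()

    variant = cfg["variant"]
    specs = default_indicator_specs(variant)

    t0 = _stage("load")
    try:
        if cfg.get("input_csv"):
            table = read_cohort_csv(cfg["input_csv"], specs)
            truth = None
        else:
            gen_cfg = default_cohort_config(variant)
            table, truth = generate_cohort(gen_cfg, n=int(cfg["generator"]["n"]),
                                           seed=seed)
            cohort_path = outdir / "cohort.csv"
            write_cohort_csv(table, cohort_path)
            outputs["cohort"] = str(cohort_path)
            truth_path = outdir / "true_labels.csv"
            pd.Series(truth, name="true_class").to_csv(truth_path, index_label="row")
            outputs["true_labels"] = str(truth_path)
    except Exception as e:
        raise RuntimeError(f"stage 'load' failed (seed {seed}): {e}") from e
    timings["load"] = time.perf_counter() - t0

    t0 = _stage("enumerate_classes")
    try:
        Y, ind_specs = prepare_indicators(table, specs)
        em = cfg["em"]
        sel_table, chosen_K, fits = lpa.enumerate_classes(
            Y, ind_specs, em["K_range"], n_restarts=int(em["n_restarts"]),
            tol=float(em["tol"]), max_iter=int(em["max_iter"]), seed=seed,
        )
        sel_path = outdir / "selection_table.csv"
        sel_table.to_csv(sel_path)
        outputs["selection_table"] = str(sel_path)
        fitted = fits[chosen_K]
        anchor = cfg["anchor"] if cfg["anchor"] in {s.name for s in ind_specs} \
            else next(s.name for s in ind_specs if s.family == "gaussian")
        fitted = profiling.relabel_canonical(fitted, ind_specs, anchor=anchor)
        model_path = outdir / "model.json"
        with open(model_path, "w") as fh:
            json.dump({
                "params": fitted.params.to_dict(),
                "neg_loglik": fitted.neg_loglik,
                "n_params": fitted.n_params,
                "bic": fitted.bic,
                "seed": seed,
                "loglik_trace": fitted.loglik_trace,
                "settings": em,
            }, fh, indent=1)
        outputs["model"] = str(model_path)
    except Exception as e:
        raise RuntimeError(f"stage 'enumerate_classes' failed (seed {seed}): {e}") from e
    timings["enumerate_classes"] = time.perf_counter() - t0

    t0 = _stage("profiling")
    try:
        profile = profiling.build_class_profile(table, fitted, ind_specs)
        prof_path = outdir / "profile_table.csv"
        profile.table.to_csv(prof_path)
        outputs["profile_table"] = str(prof_path)
        ve_path = outdir / "variance_explained.csv"
        pd.DataFrame({
            "variance_explained_pct": profile.variance_explained,
        }).to_csv(ve_path, index_label="variable")
        outputs["variance_explained"] = str(ve_path)
        prev_path = outdir / "prevalence.csv"
        pd.DataFrame({
            "prevalence": profile.prevalence,
            "weighted_prevalence": profile.weighted_prevalence,
            "mean_posterior": profile.mean_posterior,
        }, index=pd.Index(range(1, fitted.params.K + 1), name="class")
        ).to_csv(prev_path)
        outputs["prevalence"] = str(prev_path)
        labels, _ = profiling.assign_modal(fitted)
    except Exception as e:
        raise RuntimeError(f"stage 'profiling' failed (seed {seed}): {e}") from e
    timings["profiling"] = time.perf_counter() - t0

    t0 = _stage("prediction")
    try:
        plan = prediction.default_stage_plan()
        include = table.include_predictive.to_numpy()
        stage_results = prediction.run_stage_plan(
            table.data, labels, plan, include=include, K=fitted.params.K,
            ridge=float(cfg["prediction"]["ridge"]),
        )
        summaries = []
        for res in stage_results:
            s = res.summary.copy()
            s.insert(0, "stage", res.stage.name)
            s["chance"] = res.chance
            s["n_rows"] = len(res.rows)
            summaries.append(s.reset_index())
        stage_path = outdir / "stage_summaries.csv"
        pd.concat(summaries).to_csv(stage_path, index=False)
        outputs["stage_summaries"] = str(stage_path)
    except Exception as e:
        raise RuntimeError(f"stage 'prediction' failed (seed {seed}): {e}") from e
    timings["prediction"] = time.perf_counter() - t0

    t0 = _stage("validation")
    try:
        baseline = next(r for r in stage_results if r.stage.name == "age2_css_iq")
        rows = baseline.rows
        dfx, expansion = prediction.expand_categoricals(
            table.data, [v for st in plan.stages[:3] for v in st.variables]
        )
        cols = [c for st in plan.stages[:3] for v in st.variables
                for c in expansion[v]]
        X = np.column_stack(
            [np.ones(rows.size)]
            + [dfx.iloc[rows][c].to_numpy(float) for c in cols]
        )
        report = validation.bootstrap_optimism(
            X, labels[rows],
            validation.multinomial_fitter(fitted.params.K,
                                          ridge=float(cfg["prediction"]["ridge"])),
            B=int(cfg["bootstrap"]["B"]), seed=seed + 1,
            K=fitted.params.K, stratified=bool(cfg["bootstrap"]["stratified"]),
        )
        opt_path = outdir / "optimism_report.csv"
        report.to_frame().to_csv(opt_path)
        outputs["optimism_report"] = str(opt_path)
        trace_path = outdir / "optimism_trace.json"
        with open(trace_path, "w") as fh:
            json.dump({"seed": report.seed, "B": report.B,
                       "n_skipped": report.n_skipped,
                       "trace": report.trace.to_dict(orient="list")}, fh)
        outputs["optimism_trace"] = str(trace_path)
    except Exception as e:
        raise RuntimeError(f"stage 'validation' failed (seed {seed}): {e}") from e
    timings["validation"] = time.perf_counter() - t0

    manifest = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seeds": {"master": seed, "bootstrap": seed + 1},
        "version": _version(),
        "chosen_K": int(chosen_K),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": outputs,
    }
    man_path = outdir / "manifest.json"
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    manifest["manifest_path"] = str(man_path)
    return manifest


def _version() -> str:
    from . import __version__

    return __version__
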