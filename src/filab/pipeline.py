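"""End-to-end orchestration: simulate -> score -> build cohort ->
survival analysis -> discrimination -> report, with a run manifest.

Every stage writes plain CSV side files into the output directory; the
manifest (written last) snapshots the configuration, seeds, SHA-256
hashes of all outputs, stage timings and the package version, so a
rerun with the same manifest reproduces hash-identical outputs for all
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (apply_filters, drop_sparse_missing, impute_covariates,
                     prepare_analysis_table, vif_screen)
from .registry import load_registry
from .report import render_report, summarize_baseline
from .roc import roc_table
from .score import score_stays
from .simulate import SimulationConfig, generate_cohort, write_tables
from .survival import (MODEL_SETS, OUTCOMES, fit_cox, fit_rcs, hr_at,
                       km_logrank, subgroup_analysis)

__all__ = ["load_config", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "simulation": {},               # SimulationConfig field overrides
    "registry": None,               # path to a registry CSV, or None
    "scoring": {
        "max_missing": 12,
        "denominator": "measured",
        "tertile_cutpoints": "empirical",   # or a [c1, c2] pair
    },
    "cohort": {
        "sparse_threshold": 0.01,
        "sparse_mode": "rows",
        "impute_columns": ["age", "respiratory_rate", "bicarbonate",
                           "pao2_fio2", "apsiii", "sofa", "apache_ii", "cci"],
        "impute_max_iter": 10,
    },
    "analysis": {
        "outcomes": list(OUTCOMES),
        "models": list(MODEL_SETS),
        "rcs_knots": 4,
        "rcs_reference": "median",
        "km_horizon": 28,
        "subgroups": None,          # None = all defaults
    },
    "discrimination": {
        "scores": ["score", "sofa", "apache_ii"],
        "outcome": "death_28d",
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge the default config with a YAML file and explicit overrides."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: dict | str | Path | None = None,
    out_dir: str | Path = "filab_run",
    seed: int | None = None,
) -> dict:
    """Run all stages and return the manifest (also written as JSON).

    ``config`` may be a config dict, a YAML path, or ``None`` for the
    defaults; ``seed`` overrides the simulation seed.  On stage failure
    the partial outputs are retained and the manifest marks the failed
    stage before the exception propagates.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_kwargs = dict(cfg["simulation"])
    if seed is not None:
        sim_kwargs["seed"] = int(seed)
    if "admin_censor_days" in sim_kwargs:
        sim_kwargs["admin_censor_days"] = tuple(sim_kwargs["admin_censor_days"])
    sim_config = SimulationConfig(**sim_kwargs)
    registry = load_registry(cfg["registry"])

    manifest: dict = {
        "package_version": __version__,
        "config": {**cfg, "simulation": dataclasses.asdict(sim_config)},
        "seed": sim_config.seed,
        "stages": {},
        "outputs": {},
        "status": "running",
    }

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        tables = generate_cohort(sim_config, registry)
        write_tables(tables, out)
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "score"
        t0 = time.perf_counter()
        sc = cfg["scoring"]
        cut = sc["tertile_cutpoints"]
        if isinstance(cut, (list, tuple)):
            cut = tuple(cut)
        scores = score_stays(
            tables.lab_events, tables.vitals, registry,
            stay_ids=tables.stays["stay_id"],
            max_missing=sc["max_missing"], denominator=sc["denominator"],
            tertile_cutpoints=cut,
        )
        scores.to_csv(out / "filab_scores.csv", index=False)
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "build_cohort"
        t0 = time.perf_counter()
        cohort, log = apply_filters(tables.stays, scores)
        log.to_frame().to_csv(out / "exclusion_log.csv", index=False)
        cc = cfg["cohort"]
        imp_cols = [c for c in cc["impute_columns"] if c in cohort.columns]
        sparse_cols = [c for c in cohort.columns
                       if c not in imp_cols and cohort[c].isna().any()]
        if sparse_cols:
            cohort, _ = drop_sparse_missing(
                cohort, threshold=cc["sparse_threshold"],
                columns=sparse_cols, mode=cc["sparse_mode"])
        if cohort[imp_cols].isna().any().any():
            cohort = impute_covariates(
                cohort, columns=imp_cols,
                max_iter=cc["impute_max_iter"], seed=sim_config.seed)
        cohort = prepare_analysis_table(cohort)
        cohort.to_csv(out / "analysis_cohort.csv", index=False)
        vif_cols = ["filab_per_0_1"] + [
            c for c in MODEL_SETS["model3"] if c in cohort.columns]
        vif = vif_screen(cohort[vif_cols].astype(float))
        vif.to_csv(out / "vif_report.csv", index=False)
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "analyze"
        t0 = time.perf_counter()
        an = cfg["analysis"]
        cox_rows = []
        for outcome in an["outcomes"]:
            for coding in ("per_0_1_unit", "tertiles"):
                for model in an["models"]:
                    fit = fit_cox(cohort, outcome=outcome, coding=coding,
                                  adjustment=model)
                    for _, r in fit.terms.iterrows():
                        cox_rows.append({
                            "outcome": outcome, "coding": coding, "model": model,
                            "term": r["term"], "hr": r["hr"],
                            "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                            "p": r["p"], "p_for_trend": fit.p_for_trend,
                            "n": fit.n, "n_events": fit.n_events,
                        })
        cox_results = pd.DataFrame(cox_rows)
        cox_results.to_csv(out / "cox_results.csv", index=False)

        rcs = fit_rcs(cohort, outcome="mortality_28d", n_knots=an["rcs_knots"],
                      reference=an["rcs_reference"])
        rcs.curve.to_csv(out / "rcs_curve.csv", index=False)

        km = km_logrank(cohort, group_col="tertile",
                        outcome="mortality_28d", horizon=an["km_horizon"])
        km.curves.to_csv(out / "km_curves.csv", index=False)
        km.at_risk.to_csv(out / "km_at_risk.csv", index=False)

        forest = subgroup_analysis(cohort, variables=an["subgroups"])
        forest.to_csv(out / "subgroup_forest.csv", index=False)
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "discriminate"
        t0 = time.perf_counter()
        dd = cfg["discrimination"]
        roc = roc_table(cohort, dd["scores"], dd["outcome"])
        roc.per_score.to_csv(out / "roc_results.csv", index=False)
        roc.pairwise.to_csv(out / "roc_pairwise.csv", index=False)
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "report"
        t0 = time.perf_counter()
        table1_vars = [
            "age", "sex_male", "race_white", "smoking", "obesity",
            "respiratory_rate", "bicarbonate", "pao2_fio2", "apsiii", "sofa",
            "apache_ii", "cci", "mv", "vasopressors", "heart_failure",
            "hypertension", "diabetes", "copd", "aeba", "cardiac_shock",
            "sepsis", "icu_los_days", "death_icu", "death_28d", "death_90d",
        ]
        baseline = summarize_baseline(cohort, "tertile", variables=table1_vars)
        baseline.to_csv(out / "baseline_table.csv", index=False)
        text = render_report(
            baseline=baseline,
            cox_results=cox_results,
            rcs_summary={
                "knots": np.round(rcs.knots, 3).tolist(),
                "reference (HR = 1)": round(rcs.reference, 3),
                "p for non-linearity": round(rcs.p_nonlinearity, 3),
                "HR at reference + 0.1": round(hr_at(rcs, rcs.reference + 0.1), 3),
            },
            km_summary={
                "groups": km.groups,
                "log-rank chi-square": None if km.logrank_stat is None
                else round(km.logrank_stat, 2),
                "log-rank p": km.logrank_p,
                "df": km.df,
            },
            subgroup=forest,
            roc_per_score=roc.per_score,
            roc_pairwise=roc.pairwise,
            meta={
                "package version": __version__,
                "seed": sim_config.seed,
                "n simulated": sim_config.n_patients,
                "n analyzed": len(cohort),
            },
        )
        (out / "report.md").write_text(text)
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)
        manifest["status"] = "complete"
    except Exception:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    for p in sorted(out.glob("*.csv")) + [out / "report.md"]:
        manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
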