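"""End-to-end pipeline: simulate/load -> preprocess -> fit -> compare.

Each stage writes its tables under the run's output directory and logs a
JSON-lines event with the counts of every filter applied, so a run report
can reconstruct exactly what happened to the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cio
from .compare import (compare_sexwise, diurnal_effect,
                      extract_sex_spline_table, male_from_differences,
                      male_from_draws)
from .descriptives import cohort_mean_cv, summary_table
from .model import ModelSpec, fit_model
from .preprocess import (preprocess_forearm, preprocess_urine,
                         standardize_age_pooled)
from .synthetic import CohortConfig, write_cohort

__all__ = ["PipelineConfig", "run_pipeline", "correlations_from_table2"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and sampler settings for one full run."""
    input_dir: str | None = None       # None -> simulate first
    output_dir: str = "results/run"
    seed: int = 0
    sg_min: float = 1.003
    positivity_epsilon: float | None = None   # None -> half min positive
    n_knots: int = 10
    n_chains: int = 5
    n_iter: int = 10000
    n_warmup: int = 2000
    adapt_delta: float = 0.99
    max_treedepth: int = 10
    fast: bool = False                 # desk settings: 2 chains x 1500
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def model_spec(self, response: str) -> ModelSpec:
        spec = ModelSpec(response=response, n_knots=self.n_knots,
                         n_chains=self.n_chains, n_iter=self.n_iter,
                         n_warmup=self.n_warmup,
                         adapt_delta=self.adapt_delta,
                         max_treedepth=self.max_treedepth, seed=self.seed)
        if self.fast:
            spec = spec.reduced(n_chains=2, n_iter=1500, n_warmup=500,
                                adapt_delta=0.9, max_treedepth=8)
        return spec


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the run report (also written as JSON)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = cio.JsonlLogger(out / "run_log.jsonl")
    report: dict = {"provenance": cio.provenance_record(
        {"pipeline": str(config)}, config.seed)}

    if config.input_dir is None:
        counts = write_cohort(config.cohort, out / "cohort")
        logger.event("simulate", **counts)
        report["simulated"] = counts
        input_dir = out / "cohort"
    else:
        input_dir = Path(config.input_dir)

    individuals = cio.read_individuals(input_dir / "individuals.csv")
    forearm = cio.read_forearm(input_dir / "forearm.csv")
    urine = cio.read_urine(input_dir / "urine.csv")

    processed, exclusions, sg_ref = preprocess_urine(
        urine, individuals, sg_min=config.sg_min)
    velocity, eps_used, n_clamped = preprocess_forearm(
        forearm, individuals, epsilon=config.positivity_epsilon)
    urine_std, vel_std, std_params = standardize_age_pooled(
        processed, velocity)
    logger.event("preprocess", n_urine_in=len(urine),
                 n_urine_retained=len(processed),
                 n_sg_excluded=len(exclusions), sg_ref=sg_ref,
                 n_velocity=len(velocity), n_clamped=n_clamped,
                 positivity_epsilon=eps_used)
    report["preprocess"] = {
        "sg_exclusions": len(exclusions), "sg_ref": sg_ref,
        "velocity_records": len(velocity),
        "negative_velocities_clamped": n_clamped,
        "positivity_epsilon_cm_per_day": eps_used,
    }
    urine_std.to_csv(out / "processed_urine.csv", index=False)
    vel_std.to_csv(out / "velocity.csv", index=False)
    cio.write_standardization(std_params, out / "standardization.json")

    table1 = summary_table(processed)
    table1.to_csv(out / "table1.csv", index=False)
    if len(table1):
        report["descriptives"] = {
            "n_individuals_summarized": len(table1),
            "cohort_mean_cv_percent": cohort_mean_cv(
                list(table1["cv_percent"])),
        }
    logger.event("descriptives", **report.get("descriptives", {}))

    fits = {}
    for response, data in (("log_fgv", vel_std), ("log_ctx", urine_std)):
        spec = config.model_spec(response)
        fits[response] = fit_model(data, spec)
        f = fits[response]
        rh = max(f.rhat.values()) if f.rhat else float("nan")
        logger.event("fit", response=response, n_obs=f.design.n_obs,
                     n_divergent=f.n_divergent, max_rhat=rh,
                     runtime_s=f.runtime_s)
        report.setdefault("fits", {})[response] = {
            "n_obs": f.design.n_obs, "max_rhat": rh,
            "n_divergent": f.n_divergent, "runtime_s": f.runtime_s}

    tables = {}
    for response, fit_res in fits.items():
        female = extract_sex_spline_table(fit_res, "F")
        diff = extract_sex_spline_table(fit_res, "diff")
        male = male_from_differences(female, diff)
        male_proper = male_from_draws(fit_res)
        tables[response] = {"F": female, "M": male, "diff": diff,
                            "M_posterior_sum": male_proper}
    _write_estimate_tables(tables, out)

    corr = compare_sexwise(
        {s: tables["log_fgv"][s] for s in ("F", "M")},
        {s: tables["log_ctx"][s] for s in ("F", "M")})
    est, se, lci, uci = diurnal_effect(fits["log_ctx"])
    report["diurnal_time_effect"] = {"estimate": est, "se": se,
                                     "lci": lci, "uci": uci}
    report["correlations"] = {
        sex: {"rho": r.rho, "n": r.n, "df": r.df, "p": r.p_value,
              "method": r.method} for sex, r in corr.items()}
    (out / "correlations.json").write_text(
        json.dumps(report["correlations"], indent=2))
    logger.event("compare", **report["correlations"])
    (out / "run_report.json").write_text(
        json.dumps(report, indent=2, default=str))
    return report


def _write_estimate_tables(tables: dict, out: Path) -> None:
    """table2.csv: per-sex estimates; table3.csv: male-female deviations."""
    rows2, rows3 = [], []
    for sex in ("F", "M", "M_posterior_sum"):
        merged = tables["log_fgv"][sex].table.merge(
            tables["log_ctx"][sex].table, on=("spline", "window"),
            suffixes=("_fgv", "_ctx"))
        merged.insert(2, "sex", "M" if sex.startswith("M") else sex)
        merged.insert(3, "derivation", tables["log_fgv"][sex].derivation)
        rows2.append(merged)
    pd.concat(rows2, ignore_index=True).rename(columns={
        "beta_fgv": "fgv_beta", "lci_fgv": "fgv_lci", "uci_fgv": "fgv_uci",
        "beta_ctx": "ctx_beta", "lci_ctx": "ctx_lci", "uci_ctx": "ctx_uci",
    }).to_csv(out / "table2.csv", index=False)
    merged3 = tables["log_fgv"]["diff"].table.merge(
        tables["log_ctx"]["diff"].table, on=("spline", "window"),
        suffixes=("_fgv", "_ctx"))
    merged3.rename(columns={
        "beta_fgv": "fgv_beta", "lci_fgv": "fgv_lci", "uci_fgv": "fgv_uci",
        "beta_ctx": "ctx_beta", "lci_ctx": "ctx_lci", "uci_ctx": "ctx_uci",
    }).to_csv(out / "table3.csv", index=False)


def correlations_from_table2(table2: pd.DataFrame) -> dict:
    """Per-sex Spearman correlations straight from a Table-2-schema frame
    (columns sex, fgv_beta, ctx_beta; nine splines per sex)."""
    from .compare import spearman

    required = {"sex", "spline", "fgv_beta", "ctx_beta"}
    missing = required - set(table2.columns)
    if missing:
        raise ValueError(f"table2 schema missing columns: {sorted(missing)}")
    out = {}
    for sex, g in table2.groupby("sex"):
        if len(g) != 9:
            raise ValueError(
                f"expected 9 spline rows for sex {sex}, got {len(g)}")
        r = spearman(g["fgv_beta"].to_numpy(), g["ctx_beta"].to_numpy())
        out[sex] = {"rho": r.rho, "n": r.n, "df": r.df, "p": r.p_value,
                    "method": r.method}
    return out
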