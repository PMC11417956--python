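"""Raw-table preprocessing: SG correction, QC, velocities, standardization.

Turns the raw urine and forearm tables into the model-ready variables:

* urine: specific-gravity (SG) corrected CTX-I concentration and its log,
  collection time in minutes, age in years, with samples below the SG
  retention threshold discarded and logged;
* forearm: per-pair growth velocities anchored at the midpoint "velocity
  date", forced positive, and log-transformed;
* predictors: age (pooled across both datasets), sex and time centered
  and scaled to two standard deviations, so binary and continuous
  predictors live on one scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StandardizationParams", "sg_correct", "qc_filter", "time_to_minutes",
    "compute_velocities", "enforce_positive", "standardize_2sd",
    "apply_standardization", "invert_standardization",
    "preprocess_urine", "preprocess_forearm", "standardize_age_pooled",
]

log = logging.getLogger(__name__)

SG_MIN_DEFAULT = 1.003
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class StandardizationParams:
    """Center/scale pair for the 2-SD standardization x -> (x - center)/scale."""
    variable: str
    center: float
    scale: float    # = 2 * SD of the fitted values

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("standardization scale must be > 0 "
                             "(constant input?)")


def sg_correct(ctx_raw, sg_sample, sg_ref):
    """Correct a concentration for urine dilution via specific gravity:
    ``ctx_raw * (sg_ref - 1) / (sg_sample - 1)``.

    A dilute sample (SG near 1) is scaled up to what it would read at the
    reference SG; the correction is exact under pure water dilution.
    """
    ctx_raw = np.asarray(ctx_raw, dtype=float)
    sg_sample = np.asarray(sg_sample, dtype=float)
    if np.any(sg_sample <= 1.000):
        raise ValueError("sg_sample must exceed 1.000 for SG correction")
    if np.any(np.asarray(sg_ref) <= 1.000):
        raise ValueError("sg_ref must exceed 1.000")
    return ctx_raw * (sg_ref - 1.0) / (sg_sample - 1.0)


def qc_filter(samples: pd.DataFrame, sg_min: float = SG_MIN_DEFAULT):
    """Retain samples with ``sg >= sg_min`` (strict ``<`` discards).

    Returns ``(retained, exclusions)``; exclusions carry a ``reason``
    column and the counts are logged.
    """
    samples = samples.copy()
    bad = samples["sg"] < sg_min
    exclusions = samples.loc[bad].copy()
    exclusions["reason"] = f"sg below {sg_min}"
    retained = samples.loc[~bad].copy()
    log.info("qc_filter: retained %d of %d samples (%d below SG %.3f)",
             len(retained), len(samples), int(bad.sum()), sg_min)
    return retained, exclusions


def time_to_minutes(hhmm: str) -> int:
    """'HH:MM' 24-hour clock string -> minutes since midnight."""
    parts = str(hhmm).strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"malformed clock time {hhmm!r}")
    try:
        h, m = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ValueError(f"malformed clock time {hhmm!r}") from exc
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"invalid clock time {hhmm!r}")
    return 60 * h + m


def compute_velocities(measurements: pd.DataFrame, birthdate) -> pd.DataFrame:
    """Per-pair growth velocities for one individual.

    ``measurements`` needs ``date`` (datetime-like) and ``length_cm``
    columns with strictly increasing dates.  Each consecutive pair yields
    ``fgv = (L2 - L1) / days`` anchored at the midpoint "velocity date";
    age in years is measured from ``birthdate`` to that date.
    """
    if len(measurements) < 2:
        return pd.DataFrame(columns=["velocity_date", "age_years", "fgv"])
    m = measurements.sort_values("date").reset_index(drop=True)
    dates = pd.to_datetime(m["date"])
    deltas = dates.diff().dt.days.iloc[1:].to_numpy(dtype=float)
    if np.any(deltas <= 0):
        raise ValueError("duplicate or non-increasing measurement dates")
    lengths = m["length_cm"].to_numpy(dtype=float)
    fgv = np.diff(lengths) / deltas
    mid = dates.iloc[:-1].to_numpy() + (dates.diff().iloc[1:].to_numpy() / 2)
    birth = pd.Timestamp(birthdate)
    age = (pd.DatetimeIndex(mid) - birth).days / DAYS_PER_YEAR
    out = pd.DataFrame({"velocity_date": mid, "age_years": age, "fgv": fgv})
    if "id" in m.columns:
        out.insert(0, "individual_id", m["id"].iloc[0])
    return out


def enforce_positive(fgv, epsilon=None, fallback=1e-6):
    """Force velocities positive by clamping non-positive values.

    Default clamp: half the smallest positive observed velocity; if no
    positive value exists, ``fallback`` (cm/day) is used and a warning is
    logged.  Positive inputs pass through unchanged, preserving order.

    Returns ``(fgv_pos, epsilon_used, n_clamped)``.
    """
    fgv = np.asarray(fgv, dtype=float)
    if epsilon is None:
        pos = fgv[fgv > 0]
        if pos.size:
            epsilon = 0.5 * pos.min()
        else:
            epsilon = fallback
            log.warning("enforce_positive: no positive velocities; "
                        "clamping all to fallback %.2g cm/day", fallback)
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    out = np.where(fgv > 0, fgv, epsilon)
    n_clamped = int((fgv <= 0).sum())
    if n_clamped:
        log.info("enforce_positive: clamped %d non-positive velocities "
                 "to %.3g cm/day", n_clamped, epsilon)
    return out, float(epsilon), n_clamped


def standardize_2sd(values, variable="x"):
    """Center at the mean and scale by two standard deviations.

    The transformed vector has mean 0 and SD 0.5; a two-SD change in the
    raw predictor is one unit, making binary (0/1) and continuous
    predictors comparable.  Returns ``(standardized, params)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError("standardize_2sd needs >= 2 distinct values")
    center = float(values.mean())
    scale = 2.0 * float(values.std(ddof=1))
    params = StandardizationParams(variable, center, scale)
    return (values - center) / scale, params


def apply_standardization(values, params: StandardizationParams):
    return (np.asarray(values, dtype=float) - params.center) / params.scale


def invert_standardization(std_values, params: StandardizationParams):
    return np.asarray(std_values, dtype=float) * params.scale + params.center


def preprocess_urine(urine: pd.DataFrame, individuals: pd.DataFrame,
                     sg_min: float = SG_MIN_DEFAULT, sg_ref=None):
    """Raw urine table -> processed samples.

    Joins metadata, QC-filters on SG, corrects concentrations to the
    (default: retained-sample mean) reference SG, logs and ages each
    sample.  Returns ``(processed, exclusions, sg_ref_used)``.
    """
    merged = urine.merge(
        individuals[["id", "sex", "birthdate", "site_id"]], on="id",
        how="left", validate="many_to_one")
    if merged["birthdate"].isna().any():
        missing = sorted(set(urine["id"]) - set(individuals["id"]))
        raise KeyError(f"urine samples reference unknown individuals: {missing}")
    retained, exclusions = qc_filter(merged, sg_min=sg_min)
    if sg_ref is None:
        sg_ref = float(retained["sg"].mean())
    ctx_sg = sg_correct(retained["ctx_ng_ml"].to_numpy(),
                        retained["sg"].to_numpy(), sg_ref)
    birth = pd.to_datetime(retained["birthdate"])
    date = pd.to_datetime(retained["date"])
    out = pd.DataFrame({
        "individual_id": retained["id"].to_numpy(),
        "sex": retained["sex"].to_numpy(),
        "site_id": retained["site_id"].to_numpy(),
        "collection_date": date.to_numpy(),
        "minutes_of_day": [time_to_minutes(t) for t in retained["time_hhmm"]],
        "age_years": ((date - birth).dt.days / DAYS_PER_YEAR).to_numpy(),
        "ctx_sg": ctx_sg,
        "log_ctx": np.log(ctx_sg),
    })
    if (out["age_years"] < 0).any():
        raise ValueError("sample collected before birthdate")
    return out.reset_index(drop=True), exclusions, sg_ref


def preprocess_forearm(forearm: pd.DataFrame, individuals: pd.DataFrame,
                       epsilon=None):
    """Raw forearm table -> velocity records with positive, logged FGV.

    Velocities are computed per individual, clamped positive with one
    dataset-wide epsilon, and log-transformed.  Returns
    ``(velocity_df, epsilon_used, n_clamped)``.
    """
    meta = individuals.set_index("id")
    missing = sorted(set(forearm["id"]) - set(meta.index))
    if missing:
        raise KeyError(f"forearm rows reference unknown individuals: {missing}")
    frames = []
    for iid, g in forearm.groupby("id", sort=True):
        rec = compute_velocities(g, meta.loc[iid, "birthdate"])
        if len(rec):
            rec["sex"] = meta.loc[iid, "sex"]
            rec["site_id"] = meta.loc[iid, "site_id"]
            frames.append(rec)
    if not frames:
        return (pd.DataFrame(columns=["individual_id", "velocity_date",
                                      "age_years", "fgv", "fgv_pos",
                                      "log_fgv", "sex", "site_id"]),
                np.nan, 0)
    vel = pd.concat(frames, ignore_index=True)
    vel["fgv_pos"], eps, n_clamped = enforce_positive(vel["fgv"], epsilon)
    vel["log_fgv"] = np.log(vel["fgv_pos"])
    return vel, eps, n_clamped


def standardize_age_pooled(urine_proc: pd.DataFrame, velocity: pd.DataFrame):
    """2-SD standardize age on the POOLED age gradient of both datasets,
    then apply the single center/scale to each; sex (0/1 male indicator)
    and collection time are standardized within their datasets.

    Mutates copies; returns ``(urine_out, velocity_out, params_dict)``.
    """
    pooled = np.concatenate([urine_proc["age_years"].to_numpy(),
                             velocity["age_years"].to_numpy()])
    _, age_params = standardize_2sd(pooled, "age_years")
    urine_out = urine_proc.copy()
    velocity_out = velocity.copy()
    params = {"age_years": age_params}
    for df in (urine_out, velocity_out):
        df["age_std"] = apply_standardization(df["age_years"], age_params)
        df["male"] = (df["sex"] == "M").astype(float)
    both_sex = np.concatenate([urine_out["male"], velocity_out["male"]])
    _, sex_params = standardize_2sd(both_sex, "male")
    params["male"] = sex_params
    for df in (urine_out, velocity_out):
        df["sex_std"] = apply_standardization(df["male"], sex_params)
    _, t_params = standardize_2sd(urine_out["minutes_of_day"], "minutes_of_day")
    params["minutes_of_day"] = t_params
    urine_out["time_std"] = apply_standardization(
        urine_out["minutes_of_day"], t_params)
    return urine_out, velocity_out, params
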