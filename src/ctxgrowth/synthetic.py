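"""Synthetic bonobo-like cohort generator.

Emulates the statistical structure of a longitudinal zoo study of urinary
CTX-I (a bone-resorption marker) and forearm growth: a cohort of
individuals of both sexes housed across several sites, each contributing

* irregular forearm-length measurements (cm), from which downstream code
  derives growth velocities, and
* urine samples collected between 07:00 and 18:00 with a raw CTX-I
  concentration (ng/mL) and a specific-gravity (SG) reading.

The generator owns a ground-truth layer (per-sex mean growth-velocity and
log-CTX age curves, random-effect standard deviations, a diurnal log-slope,
a day-to-day variability target) so that every downstream estimator can be
checked against known truth.  Default sizes mirror the validation-study
scale: 48 urine-sampled individuals with 187 samples, 81 measured
individuals with 364 forearm measurements, 11 housing sites.

Key structural choices
----------------------
* Growth velocity: a Gaussian age bump (the adolescent spurt) optionally
  mixed with a birth plateau, multiplied by a quadratic taper that reaches
  exactly zero at the cessation age.  Females default to an earlier,
  narrower spurt; males to a later bump on a high plateau.
* Day-to-day variability: a per-(individual, day) lognormal effect plus a
  skew-normal within-day residual.  Their log-scale variances sum to
  ``log(1 + day_cv**2)`` so the natural-scale coefficient of variation of
  repeated same-time samples matches ``day_cv`` by construction.
* Diurnal pattern: linear in minutes on the log scale, referenced to
  07:00; ``diurnal_log_slope`` defaults to ``log(0.55)/660`` so the
  expected 18:00/07:00 concentration ratio is 0.55.
* Coupling: per-sex weight blending the base log-CTX age curve with a
  monotone transform of the growth-velocity curve; weight 1 makes the CTX
  curve a rank-preserving image of the velocity curve, weight 0 leaves it
  independent of the velocity parameters.  Defaults couple females only,
  the condition under which a velocity/CTX correspondence exists to
  detect.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .skewnormal import skewnormal_rvs

__all__ = [
    "FGVParams", "CTXParams", "CohortConfig", "IndividualRecord",
    "TrueTrajectory", "generate_cohort", "mean_fgv_curve",
    "mean_log_ctx_curve", "true_log_ctx_curve", "mean_forearm_length",
    "simulate_forearm_series", "simulate_urine_series",
    "simulate_cohort_tables", "write_cohort",
]

DAYS_PER_YEAR = 365.25
MORNING_MINUTES = 7 * 60       # collection window start, 07:00
EVENING_MINUTES = 18 * 60      # collection window end, 18:00


@dataclass(frozen=True)
class FGVParams:
    """Per-sex mean growth-velocity curve parameters."""
    peak_age: float            # years, center of the spurt bump
    width: float               # years, bump scale
    peak_height: float         # cm/day, curve scale
    cessation_age: float       # years, velocity is exactly 0 from here on
    plateau: float = 0.0       # [0,1) mix of an age-constant component


@dataclass(frozen=True)
class CTXParams:
    """Per-sex baseline log-CTX age-curve parameters."""
    peak_age: float            # years, curve maximum (gamma-type bump)
    amplitude: float           # log ng/mL, bump height over baseline
    log_baseline: float        # log ng/mL at age 0
    decline_rate: float        # extra log-units/year decline after age 10


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults emulate the study scale."""

    n_individuals: int = 81
    n_urine_individuals: int = 48
    n_urine_samples: int = 187
    n_forearm_measurements: int = 364
    sex_ratio: float = 0.46            # fraction female
    n_sites: int = 11
    fgv_curve_params: dict = field(default_factory=lambda: {
        "F": FGVParams(5.5, 2.2, 0.012, 18.0, 0.0),
        "M": FGVParams(7.0, 2.5, 0.0095, 20.0, 0.3),
    })
    ctx_curve_params: dict = field(default_factory=lambda: {
        "F": CTXParams(4.0, 1.2, np.log(2.0), 0.05),
        # decoupled male biomarker: a gentle peak and slow decline whose
        # age structure is weak relative to biological noise, so male CTX
        # carries no growth-velocity signal (the condition the validation
        # contrast is designed to detect)
        "M": CTXParams(4.0, 0.12, np.log(2.2), 0.015),
    })
    coupling: dict = field(default_factory=lambda: {"F": 1.0, "M": 0.0})
    diurnal_log_slope: float = np.log(0.55) / (EVENING_MINUTES - MORNING_MINUTES)
    day_cv: float = 0.25               # day-to-day CV target, natural scale
    day_effect_share: float = 0.6      # fraction of log-variance on day level
    skew_alpha: float = -4.0           # residual shape; negative = left skew
    ind_sd_ctx: float = 0.30           # individual log-CTX intercept SD
    ind_sd_fgv: float = 0.10           # individual log-velocity scale SD
    site_sd_ctx: float = 0.10          # site intercepts, both outcomes
    site_sd_fgv: float = 0.05
    forearm_noise_sd: float = 0.05     # cm, length measurement error
    birth_length_cm: float = 22.0
    min_gap_days: int = 90             # minimum forearm re-measurement gap
    sg_mean: float = 1.013
    sg_sd: float = 0.006
    reference_date: dt.date = dt.date(2022, 3, 1)
    max_age: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.day_cv <= 0:
            raise ValueError("day_cv must be > 0")
        if self.sg_mean <= 1.000:
            raise ValueError("sg_mean must exceed 1.000")
        for sex, cp in self.coupling.items():
            if not 0.0 <= cp <= 1.0:
                raise ValueError(f"coupling[{sex}] must lie in [0, 1]")
        for sex, fp in self.fgv_curve_params.items():
            if fp.cessation_age > self.max_age:
                raise ValueError(
                    f"cessation age for sex {sex} exceeds the maximum "
                    f"analyzed age {self.max_age}")

    @property
    def total_log_sd(self) -> float:
        """Log-scale SD equivalent of the day-to-day CV target."""
        return float(np.sqrt(np.log(1.0 + self.day_cv**2)))

    @property
    def day_log_sd(self) -> float:
        return self.total_log_sd * np.sqrt(self.day_effect_share)

    @property
    def resid_log_sd(self) -> float:
        return self.total_log_sd * np.sqrt(1.0 - self.day_effect_share)


@dataclass(frozen=True)
class IndividualRecord:
    id: str
    sex: str                   # "F" or "M"
    birthdate: dt.date
    site_id: str


@dataclass
class TrueTrajectory:
    """Generator ground truth on an age grid, for recovery tests."""
    age_grid: np.ndarray
    fgv_mean: np.ndarray       # cm/day
    log_ctx_mean: np.ndarray   # log ng/mL


def _check_age(age, max_age=20.0):
    age = np.asarray(age, dtype=float)
    if np.any(age < 0) or np.any(age > max_age):
        raise ValueError(f"age must lie in [0, {max_age}] years")
    return age


def mean_fgv_curve(age, sex, params) -> np.ndarray:
    """Mean forearm growth velocity (cm/day) at ``age`` years.

    Gaussian spurt bump (optionally mixed with a plateau) tapered by
    ``(1 - age/cessation)**2``, clipped to zero beyond cessation.
    """
    age = _check_age(age)
    p: FGVParams = params[sex] if isinstance(params, dict) else params
    bump = np.exp(-0.5 * ((age - p.peak_age) / p.width) ** 2)
    shape = (1.0 - p.plateau) * bump + p.plateau
    taper = np.clip(1.0 - age / p.cessation_age, 0.0, None) ** 2
    return p.peak_height * shape * taper


def mean_log_ctx_curve(age, sex, params) -> np.ndarray:
    """Baseline mean log CTX-I concentration (log ng/mL) at ``age`` years.

    Gamma-type bump peaking at ``peak_age`` with an extra linear log
    decline after age 10 (the post-growth fall in bone turnover).
    """
    age = _check_age(age)
    p: CTXParams = params[sex] if isinstance(params, dict) else params
    rel = age / p.peak_age
    bump = rel * np.exp(1.0 - rel)
    return p.log_baseline + p.amplitude * bump \
        - p.decline_rate * np.maximum(age - 10.0, 0.0)


def true_log_ctx_curve(age, sex, config: CohortConfig) -> np.ndarray:
    """Effective mean log-CTX curve after velocity coupling.

    With coupling weight ``k`` for this sex, blends the baseline curve with
    a monotone (rank-preserving) image of the growth-velocity curve scaled
    to the baseline curve's own location and spread, so ``k = 1`` makes
    log CTX a strictly increasing function of velocity.
    """
    age = _check_age(age, config.max_age)
    base = mean_log_ctx_curve(age, sex, config.ctx_curve_params)
    k = config.coupling.get(sex, 0.0)
    if k == 0.0:
        return base
    fp = config.fgv_curve_params[sex]
    cp = config.ctx_curve_params[sex]
    # monotone image of the velocity curve: log(v + floor), where the
    # floor (5% of peak velocity) is the baseline skeletal remodeling
    # that persists after long-bone growth stops; standardized to the
    # CTX amplitude so the coupled curve varies on the biomarker's scale
    floor = 0.05 * fp.peak_height
    grid = np.linspace(0.0, config.max_age, 401)
    base_grid = mean_log_ctx_curve(grid, sex, config.ctx_curve_params)
    v_grid = np.log(mean_fgv_curve(grid, sex, config.fgv_curve_params) + floor)
    v = np.log(mean_fgv_curve(age, sex, config.fgv_curve_params) + floor)
    v_std = (v - v_grid.mean()) / v_grid.std()
    shaped = base_grid.mean() + cp.amplitude * v_std
    return (1.0 - k) * base + k * shaped


def true_trajectory(sex, config: CohortConfig, n_grid: int = 201) -> TrueTrajectory:
    grid = np.linspace(0.0, config.max_age, n_grid)
    return TrueTrajectory(
        age_grid=grid,
        fgv_mean=mean_fgv_curve(grid, sex, config.fgv_curve_params),
        log_ctx_mean=true_log_ctx_curve(grid, sex, config),
    )


def mean_forearm_length(age, sex, params, birth_length_cm=22.0) -> float:
    """Expected forearm length (cm): birth length plus the integrated mean
    velocity curve (adaptive quadrature; the curve has a kink at the
    cessation age, passed as a breakpoint)."""
    p: FGVParams = params[sex] if isinstance(params, dict) else params
    age = float(age)
    total, _ = quad(lambda a: mean_fgv_curve(a, sex, {sex: p}), 0.0, age,
                    points=[min(p.cessation_age, age)], limit=200,
                    epsabs=1e-12, epsrel=1e-12)
    return birth_length_cm + DAYS_PER_YEAR * total


def generate_cohort(config: CohortConfig) -> list[IndividualRecord]:
    """Deterministically (per seed) assign ids, sexes, sites, birthdates."""
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    n_f = int(round(n * config.sex_ratio))
    sexes = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(sexes)
    sites = rng.integers(0, max(config.n_sites, 1), size=n)
    # age at the reference date; observations later restrict to [0, 20]
    ages_now = rng.uniform(1.5, config.max_age, size=n)
    out = []
    for i in range(n):
        birth = config.reference_date - dt.timedelta(
            days=float(ages_now[i]) * DAYS_PER_YEAR)
        out.append(IndividualRecord(
            id=f"B{i + 1:03d}", sex=str(sexes[i]), birthdate=birth,
            site_id=f"Z{int(sites[i]) + 1:02d}"))
    return out


def _allocate_counts(total, n, lo, hi, rng, concentration=1.2):
    """Apportion ``total`` observations over ``n`` individuals with counts
    in [lo, hi]; skewed weights give a few heavily sampled individuals."""
    if n == 0:
        return np.zeros(0, dtype=int)
    if total < n * lo or total > n * hi:
        raise ValueError("total incompatible with per-individual bounds")
    w = rng.lognormal(0.0, concentration, size=n)
    counts = np.full(n, lo, dtype=int)
    remaining = total - lo * n
    probs = w / w.sum()
    while remaining > 0:
        idx = rng.choice(n, p=probs)
        if counts[idx] < hi:
            counts[idx] += 1
            remaining -= 1
        else:
            probs[idx] = 0.0
            probs = probs / probs.sum()
    return counts


def _age_years(date: dt.date, birth: dt.date) -> float:
    return (date - birth).days / DAYS_PER_YEAR


def simulate_forearm_series(individual: IndividualRecord, schedule,
                            noise_sd, seed, *, params=None,
                            birth_length_cm=22.0, ind_log_scale=0.0):
    """Simulate forearm lengths (cm) at the given measurement dates.

    Length is the integrated mean velocity curve (scaled by the
    individual's lognormal growth factor) plus iid Gaussian measurement
    error.  Raises for dates before the individual's birthdate.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if params is None:
        params = CohortConfig().fgv_curve_params
    rng = np.random.default_rng(seed)
    lengths = []
    scale = np.exp(ind_log_scale)
    for d in schedule:
        if d < individual.birthdate:
            raise ValueError(f"measurement date {d} precedes birthdate")
        age = _age_years(d, individual.birthdate)
        mean_len = birth_length_cm + scale * (
            mean_forearm_length(age, individual.sex, params,
                                birth_length_cm=0.0))
        lengths.append(mean_len + rng.normal(0.0, noise_sd))
    return np.array(lengths)


def simulate_urine_series(individual: IndividualRecord, schedule,
                          config: CohortConfig, seed, *,
                          ind_effect=0.0, site_effect=0.0,
                          freeze_age_at=None):
    """Simulate urine samples at ``schedule`` = [(date, minutes-of-day)].

    Log concentration = coupled age curve + diurnal slope x (minutes from
    07:00) + individual and site intercepts + a per-(date) day effect + a
    skew-normal residual; SG is truncated normal (>= 1.0005).
    ``freeze_age_at`` evaluates the age curve at a fixed age (used when
    isolating day-to-day variability from age trends).

    Returns a DataFrame with one row per sample.
    """
    rows = []
    if len(schedule) == 0:
        return pd.DataFrame(columns=[
            "id", "date", "time_hhmm", "ctx_ng_ml", "sg"])
    rng = np.random.default_rng(seed)
    day_effects = {}
    for d, minutes in schedule:
        minutes = int(minutes)
        if not 0 <= minutes < 1440:
            raise ValueError("minutes-of-day must lie in [0, 1440)")
        age = (freeze_age_at if freeze_age_at is not None
               else _age_years(d, individual.birthdate))
        mean_log = float(true_log_ctx_curve(age, individual.sex, config))
        if d not in day_effects:
            day_effects[d] = rng.normal(0.0, config.day_log_sd)
        resid = float(skewnormal_rvs(0.0, config.resid_log_sd,
                                     config.skew_alpha, None, rng))
        log_ctx = (mean_log
                   + config.diurnal_log_slope * (minutes - MORNING_MINUTES)
                   + ind_effect + site_effect + day_effects[d] + resid)
        # truncated-normal SG, floored just above pure water
        sg = 0.0
        while sg < 1.0005:
            sg = rng.normal(config.sg_mean, config.sg_sd)
        rows.append({
            "id": individual.id, "date": d.isoformat(),
            "time_hhmm": f"{minutes // 60:02d}:{minutes % 60:02d}",
            "ctx_ng_ml": float(np.exp(log_ctx)), "sg": float(sg),
        })
    return pd.DataFrame(rows)


def simulate_cohort_tables(config: CohortConfig):
    """Generate the full cohort: individuals, forearm and urine tables.

    Returns ``(individuals_df, forearm_df, urine_df, truth)`` where
    ``truth`` records every latent quantity (curve parameters, random
    effects, schedules' seeds) needed by recovery tests.
    """
    cohort = generate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    site_ids = sorted({ind.site_id for ind in cohort})
    site_eff_ctx = {s: rng.normal(0.0, config.site_sd_ctx) for s in site_ids}
    site_eff_fgv = {s: rng.normal(0.0, config.site_sd_fgv) for s in site_ids}
    ind_eff_ctx = {ind.id: rng.normal(0.0, config.ind_sd_ctx) for ind in cohort}
    ind_eff_fgv = {ind.id: rng.normal(0.0, config.ind_sd_fgv) for ind in cohort}

    # forearm measurements for every individual
    fore_counts = _allocate_counts(config.n_forearm_measurements,
                                   config.n_individuals, 1, 10, rng)
    forearm_frames = []
    for ind, cnt in zip(cohort, fore_counts):
        age_now = min(_age_years(config.reference_date, ind.birthdate),
                      config.max_age)
        lo = min(0.25, 0.9 * age_now)
        gap_years = config.min_gap_days / DAYS_PER_YEAR
        max_fit = max(int((age_now - lo) / gap_years) + 1, 1)
        cnt = min(int(cnt), max_fit)
        # sorted draws over the gap-shrunk span, then re-inflate: spacing
        # >= the minimum re-measurement gap, all within [lo, age_now]
        span_hi = age_now - (cnt - 1) * gap_years
        base = np.sort(rng.uniform(lo, max(span_hi, lo + 1e-6), size=cnt))
        ages = base + gap_years * np.arange(cnt)
        dates = [ind.birthdate + dt.timedelta(days=float(a) * DAYS_PER_YEAR)
                 for a in ages]
        lengths = simulate_forearm_series(
            ind, dates, config.forearm_noise_sd,
            rng.integers(0, 2**31 - 1),
            params=config.fgv_curve_params,
            birth_length_cm=config.birth_length_cm,
            ind_log_scale=ind_eff_fgv[ind.id] + site_eff_fgv[ind.site_id])
        for d, length in zip(dates, lengths):
            forearm_frames.append({"id": ind.id, "date": d.isoformat(),
                                   "length_cm": float(length)})
    forearm_df = pd.DataFrame(forearm_frames)

    # urine samples for a subset of individuals
    urine_subset = list(rng.choice(config.n_individuals,
                                   size=config.n_urine_individuals,
                                   replace=False))
    urine_inds = [cohort[i] for i in sorted(urine_subset)]
    urine_counts = _allocate_counts(config.n_urine_samples,
                                    config.n_urine_individuals, 1, 18, rng,
                                    concentration=1.5)
    urine_frames = []
    for ind, cnt in zip(urine_inds, urine_counts):
        age_now = min(_age_years(config.reference_date, ind.birthdate),
                      config.max_age)
        ages = rng.uniform(min(0.05, age_now / 2), age_now, size=cnt)
        minutes = rng.integers(MORNING_MINUTES, EVENING_MINUTES + 1, size=cnt)
        schedule = [(ind.birthdate + dt.timedelta(days=float(a) * DAYS_PER_YEAR),
                     int(m)) for a, m in zip(ages, minutes)]
        urine_frames.append(simulate_urine_series(
            ind, schedule, config, rng.integers(0, 2**31 - 1),
            ind_effect=ind_eff_ctx[ind.id],
            site_effect=site_eff_ctx[ind.site_id]))
    urine_df = pd.concat(urine_frames, ignore_index=True)

    individuals_df = pd.DataFrame([
        {"id": ind.id, "sex": ind.sex, "birthdate": ind.birthdate.isoformat(),
         "site_id": ind.site_id} for ind in cohort])
    truth = {
        "config": _config_to_jsonable(config),
        "site_effect_ctx": site_eff_ctx, "site_effect_fgv": site_eff_fgv,
        "ind_effect_ctx": ind_eff_ctx, "ind_effect_fgv": ind_eff_fgv,
    }
    return individuals_df, forearm_df, urine_df, truth


def _config_to_jsonable(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["reference_date"] = config.reference_date.isoformat()
    for key in ("fgv_curve_params", "ctx_curve_params"):
        d[key] = {sex: dataclasses.asdict(p) if dataclasses.is_dataclass(p)
                  else dict(p) for sex, p in getattr(config, key).items()}
    return d


def write_cohort(config: CohortConfig, outdir) -> dict:
    """Write individuals.csv, forearm.csv, urine.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    individuals, forearm, urine, truth = simulate_cohort_tables(config)
    individuals.to_csv(outdir / "individuals.csv", index=False)
    forearm.to_csv(outdir / "forearm.csv", index=False)
    urine.to_csv(outdir / "urine.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=float)
    return {"individuals": len(individuals), "forearm": len(forearm),
            "urine": len(urine)}
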