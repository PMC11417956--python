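"""Synthetic cohort generator: curve contracts, calibration, determinism."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import shapiro, skew, spearmanr

from ctxgrowth.synthetic import (CohortConfig, IndividualRecord,
                                 generate_cohort, mean_fgv_curve,
                                 mean_log_ctx_curve, simulate_cohort_tables,
                                 simulate_forearm_series,
                                 simulate_urine_series, true_log_ctx_curve,
                                 write_cohort)

GRID = np.arange(0.0, 20.0001, 0.1)


# --- cohort assembly -------------------------------------------------------

def test_default_cohort_emulates_study_sizes(cohort_tables, default_config):
    individuals, forearm, urine, truth = cohort_tables
    assert len(individuals) == 81
    assert len(forearm) == 364
    assert len(urine) == 187
    assert urine["id"].nunique() == 48
    counts = forearm.groupby("id").size()
    assert counts.min() >= 1 and counts.max() <= 10


def test_sex_split_matches_ratio():
    cohort = generate_cohort(CohortConfig(n_individuals=48, sex_ratio=0.46,
                                          seed=1))
    sexes = pd.Series([c.sex for c in cohort]).value_counts()
    assert sexes["F"] == 22 and sexes["M"] == 26


def test_empty_cohort():
    assert generate_cohort(CohortConfig(n_individuals=0,
                                        n_urine_individuals=0,
                                        n_urine_samples=0,
                                        n_forearm_measurements=0)) == []


def test_seed_determinism(tmp_path):
    cfg = CohortConfig(seed=7, n_individuals=20, n_urine_individuals=10,
                       n_urine_samples=40, n_forearm_measurements=60)
    write_cohort(cfg, tmp_path / "a")
    write_cohort(cfg, tmp_path / "b")
    for name in ("individuals.csv", "forearm.csv", "urine.csv"):
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes()
    other = generate_cohort(CohortConfig(seed=8))
    assert [c.sex for c in other] != [c.sex for c in generate_cohort(cfg)]


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        CohortConfig(sex_ratio=1.2)
    with pytest.raises(ValueError):
        CohortConfig(day_cv=0.0)
    with pytest.raises(ValueError):
        CohortConfig(sg_mean=0.999)
    with pytest.raises(ValueError):
        CohortConfig(coupling={"F": 1.5, "M": 0.0})


# --- mean curves -----------------------------------------------------------

def test_female_velocity_peak_age(default_config):
    v = mean_fgv_curve(GRID, "F", default_config.fgv_curve_params)
    peak = GRID[np.argmax(v)]
    assert 4.5 <= peak <= 7.0
    assert np.all(v >= 0)


def test_velocity_zero_at_cessation(default_config):
    cess = default_config.fgv_curve_params["F"].cessation_age
    assert mean_fgv_curve(cess, "F", default_config.fgv_curve_params) <= 1e-6


def test_male_velocity_high_early(default_config):
    p = default_config.fgv_curve_params
    assert mean_fgv_curve(1.0, "M", p) > mean_fgv_curve(15.0, "M", p)


def test_female_peaks_before_male(default_config):
    p = default_config.fgv_curve_params
    f_peak = GRID[np.argmax(mean_fgv_curve(GRID, "F", p))]
    m_peak = GRID[np.argmax(mean_fgv_curve(GRID, "M", p))]
    assert f_peak < m_peak
    assert f_peak < 11.0      # female spurt precedes the male decline onset


def test_age_domain_enforced(default_config):
    with pytest.raises(ValueError):
        mean_fgv_curve(21.0, "F", default_config.fgv_curve_params)
    with pytest.raises(ValueError):
        mean_log_ctx_curve(-0.1, "F", default_config.ctx_curve_params)


def test_female_ctx_peaks_near_four_years(default_config):
    c = mean_log_ctx_curve(GRID, "F", default_config.ctx_curve_params)
    assert 3.0 <= GRID[np.argmax(c)] <= 5.0


@pytest.mark.parametrize("sex", ["F", "M"])
def test_ctx_declines_after_ten_years(default_config, sex):
    c = mean_log_ctx_curve(GRID, sex, default_config.ctx_curve_params)
    over_ten = c[GRID >= 10.0]
    assert np.all(np.diff(over_ten) < 0)
    assert c[GRID == 10.0] > c[GRID == 20.0]


def test_full_coupling_makes_ctx_track_velocity(default_config):
    v = mean_fgv_curve(GRID, "F", default_config.fgv_curve_params)
    ctx = np.exp(true_log_ctx_curve(GRID, "F", default_config))
    assert spearmanr(v, ctx).statistic > 0.8


def test_zero_coupling_ignores_velocity_params(default_config):
    import dataclasses
    cfg0 = dataclasses.replace(default_config,
                               coupling={"F": 0.0, "M": 0.0})
    base = true_log_ctx_curve(GRID, "F", cfg0)
    from ctxgrowth.synthetic import FGVParams
    cfg_alt = dataclasses.replace(
        cfg0, fgv_curve_params={"F": FGVParams(3.0, 1.0, 0.02, 15.0, 0.1),
                                "M": cfg0.fgv_curve_params["M"]})
    assert np.array_equal(base, true_log_ctx_curve(GRID, "F", cfg_alt))


# --- forearm series --------------------------------------------------------

@pytest.fixture()
def individual():
    return IndividualRecord("T01", "F", dt.date(2005, 6, 1), "Z01")


def test_noiseless_velocities_equal_interval_average(individual,
                                                     default_config):
    """With zero noise, (L2-L1)/days equals the quadrature average of the
    velocity curve over the interval."""
    dates = [individual.birthdate + dt.timedelta(days=d)
             for d in (400, 1100, 2500)]
    lengths = simulate_forearm_series(individual, dates, 0.0, seed=1,
                                      params=default_config.fgv_curve_params)
    params = default_config.fgv_curve_params
    for (d1, L1), (d2, L2) in zip(zip(dates, lengths),
                                  zip(dates[1:], lengths[1:])):
        days = (d2 - d1).days
        velocity = (L2 - L1) / days
        a1 = (d1 - individual.birthdate).days / 365.25
        a2 = (d2 - individual.birthdate).days / 365.25
        avg, _ = quad(lambda a: mean_fgv_curve(a, "F", params), a1, a2,
                      epsabs=1e-13, epsrel=1e-13)
        avg /= (a2 - a1)
        assert abs(velocity - avg) < 1e-9


def test_forearm_series_reproducible(individual):
    dates = [individual.birthdate + dt.timedelta(days=d)
             for d in (300, 900, 1500)]
    a = simulate_forearm_series(individual, dates, 0.05, seed=42)
    b = simulate_forearm_series(individual, dates, 0.05, seed=42)
    assert np.array_equal(a, b)


def test_measurement_before_birth_rejected(individual):
    with pytest.raises(ValueError):
        simulate_forearm_series(
            individual, [individual.birthdate - dt.timedelta(days=1)], 0.0, 1)


def test_negative_velocities_are_a_small_minority(cohort_tables):
    """Default measurement noise yields some small negative velocities."""
    individuals, forearm, _, _ = cohort_tables
    vels = []
    for iid, g in forearm.groupby("id"):
        g = g.sort_values("date")
        days = pd.to_datetime(g["date"]).diff().dt.days.iloc[1:].to_numpy()
        vels.extend(np.diff(g["length_cm"].to_numpy()) / days)
    vels = np.asarray(vels)
    assert len(vels) > 250
    n_neg = (vels < 0).sum()
    assert 0 < n_neg < 0.5 * len(vels)
    assert np.all(vels[vels < 0] > -0.01)     # small in magnitude


# --- urine series ----------------------------------------------------------

def test_empty_schedule_returns_empty(individual, default_config):
    df = simulate_urine_series(individual, [], default_config, 1)
    assert len(df) == 0


def test_invalid_minutes_rejected(individual, default_config):
    with pytest.raises(ValueError):
        simulate_urine_series(individual, [(dt.date(2010, 1, 1), 1500)],
                              default_config, 1)


def test_urine_series_reproducible(individual, default_config):
    sched = [(dt.date(2010, 1, 1 + i), 480 + 10 * i) for i in range(5)]
    a = simulate_urine_series(individual, sched, default_config, 9)
    b = simulate_urine_series(individual, sched, default_config, 9)
    pd.testing.assert_frame_equal(a, b)


def test_some_samples_fall_below_sg_threshold(cohort_tables):
    _, _, urine, _ = cohort_tables
    assert (urine["sg"] < 1.003).sum() >= 1
    assert (urine["sg"] >= 1.0005).all()


def test_day_to_day_cv_matches_target(individual, default_config):
    """Frozen age and time of day: realized CV of repeated samples sits
    in the calibration band around the 25% target."""
    sched = [(dt.date(2015, 1, 1) + dt.timedelta(days=i), 480)
             for i in range(1000)]
    df = simulate_urine_series(individual, sched, default_config, seed=21,
                               freeze_age_at=15.0)
    cv = 100 * df["ctx_ng_ml"].std(ddof=1) / df["ctx_ng_ml"].mean()
    assert 22.0 <= cv <= 28.0


def test_diurnal_slope_targets_evening_morning_ratio(individual,
                                                     default_config):
    """Monte-Carlo over 2,000 paired 07:00/18:00 samples: the realized
    mean concentration ratio is within 0.05 of the 0.55 target."""
    rng = np.random.default_rng(17)
    ratios = np.empty(2000)
    base = dt.date(2014, 1, 1)
    for i in range(2000):
        day = base + dt.timedelta(days=int(rng.integers(0, 400)))
        df = simulate_urine_series(
            individual, [(day, 420), (day, 1080)], default_config,
            seed=int(rng.integers(0, 2**31)), freeze_age_at=10.0)
        ratios[i] = df["ctx_ng_ml"].iloc[1] / df["ctx_ng_ml"].iloc[0]
    assert abs(ratios.mean() - 0.55) < 0.05


def test_residual_normality_and_skewness_switches():
    """skew_alpha = 0 gives normal residuals (Shapiro p > 0.01 at
    n = 500); skew_alpha = 5 gives sample skewness > 0.5."""
    import dataclasses
    ind = IndividualRecord("T02", "M", dt.date(2000, 1, 1), "Z01")
    base = CohortConfig(seed=0, day_effect_share=0.0)
    sched = [(dt.date(2015, 1, 1) + dt.timedelta(days=i), 600)
             for i in range(500)]
    cfg0 = dataclasses.replace(base, skew_alpha=0.0)
    df0 = simulate_urine_series(ind, sched, cfg0, seed=3, freeze_age_at=14.0)
    assert shapiro(np.log(df0["ctx_ng_ml"])).pvalue > 0.01
    cfg5 = dataclasses.replace(base, skew_alpha=5.0)
    df5 = simulate_urine_series(ind, sched, cfg5, seed=3, freeze_age_at=14.0)
    assert skew(np.log(df5["ctx_ng_ml"])) > 0.5


def test_truth_sidecar_written(tmp_path):
    cfg = CohortConfig(seed=5, n_individuals=10, n_urine_individuals=5,
                       n_urine_samples=20, n_forearm_measurements=30,
                       n_sites=2)
    counts = write_cohort(cfg, tmp_path)
    assert counts == {"individuals": 10, "forearm": 30, "urine": 20}
    import json
    truth = json.loads((tmp_path / "truth.json").read_text())
    assert truth["config"]["day_cv"] == 0.25
    assert len(truth["ind_effect_ctx"]) == 10
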