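"""Preprocessing: SG correction, QC, velocities, 2-SD standardization."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctxgrowth.preprocess import (compute_velocities, enforce_positive,
                                  invert_standardization,
                                  preprocess_forearm, preprocess_urine,
                                  qc_filter, sg_correct, standardize_2sd,
                                  standardize_age_pooled, time_to_minutes)


# --- SG correction ---------------------------------------------------------

def test_sg_correction_identity_at_reference():
    assert sg_correct(5.0, 1.010, 1.010) == pytest.approx(5.0)


def test_sg_correction_arithmetic():
    assert sg_correct(2.0, 1.005, 1.010) == pytest.approx(4.0)


def test_sg_correction_degenerate_denominator():
    with pytest.raises(ValueError):
        sg_correct(2.0, 1.000, 1.010)


@given(st.floats(0.01, 100.0), st.floats(1.001, 1.05), st.floats(0.1, 10.0))
@settings(max_examples=50, deadline=None)
def test_sg_correction_homogeneity(ctx, sg, c):
    scaled = sg_correct(c * ctx, sg, 1.010)
    assert scaled == pytest.approx(c * sg_correct(ctx, sg, 1.010), rel=1e-12)


def test_sg_correction_dilution_invariance():
    """Adding water dilutes the analyte and shrinks sg-1 by the same
    factor; the corrected concentration is unchanged."""
    ctx, sg, ref = 3.7, 1.020, 1.010
    for factor in (2.0, 5.0, 10.0):
        diluted_ctx = ctx / factor
        diluted_sg = 1.0 + (sg - 1.0) / factor
        assert abs(sg_correct(diluted_ctx, diluted_sg, ref)
                   - sg_correct(ctx, sg, ref)) < 1e-9


# --- QC filter -------------------------------------------------------------

def test_qc_filter_strict_below_threshold():
    df = pd.DataFrame({"sg": [1.001, 1.002, 1.0025, 1.0029, 1.003, 1.010],
                       "ctx_ng_ml": np.arange(6.0)})
    kept, dropped = qc_filter(df)
    assert len(dropped) == 4 and len(kept) == 2
    assert (dropped["reason"] == "sg below 1.003").all()
    assert 1.003 in kept["sg"].values      # boundary value retained


def test_qc_filter_empty():
    empty = pd.DataFrame({"sg": [], "ctx_ng_ml": []})
    kept, dropped = qc_filter(empty)
    assert len(kept) == 0 and len(dropped) == 0


# --- time parsing ----------------------------------------------------------

@pytest.mark.parametrize("hhmm,minutes", [("07:00", 420), ("18:00", 1080),
                                          ("00:00", 0), ("23:59", 1439)])
def test_time_to_minutes(hhmm, minutes):
    assert time_to_minutes(hhmm) == minutes


@pytest.mark.parametrize("bad", ["24:01", "7h30", "12:60", "xx:yy", "1230"])
def test_time_to_minutes_rejects_invalid(bad):
    with pytest.raises(ValueError):
        time_to_minutes(bad)


# --- velocities ------------------------------------------------------------

def test_velocity_arithmetic_and_midpoint():
    m = pd.DataFrame({"date": ["2010-01-01", "2010-04-11"],   # 100 days
                      "length_cm": [30.0, 30.5]})
    rec = compute_velocities(m, "2005-01-01")
    assert rec["fgv"].iloc[0] == pytest.approx(0.005)
    assert rec["velocity_date"].iloc[0] == pd.Timestamp("2010-02-20")


def test_equal_lengths_give_zero_velocity():
    m = pd.DataFrame({"date": ["2010-01-01", "2010-04-11"],
                      "length_cm": [30.0, 30.0]})
    assert compute_velocities(m, "2005-01-01")["fgv"].iloc[0] == 0.0


def test_single_measurement_yields_no_records():
    m = pd.DataFrame({"date": ["2010-01-01"], "length_cm": [30.0]})
    assert len(compute_velocities(m, "2005-01-01")) == 0


def test_duplicate_dates_rejected():
    m = pd.DataFrame({"date": ["2010-01-01", "2010-01-01"],
                      "length_cm": [30.0, 30.5]})
    with pytest.raises(ValueError):
        compute_velocities(m, "2005-01-01")


def test_velocity_telescoping(cohort_tables):
    """Sum of fgv x interval days equals total length change per series."""
    individuals, forearm, _, _ = cohort_tables
    birth = individuals.set_index("id")["birthdate"]
    for iid, g in forearm.groupby("id"):
        if len(g) < 2:
            continue
        g = g.sort_values("date")
        rec = compute_velocities(g, birth[iid])
        days = pd.to_datetime(g["date"]).diff().dt.days.iloc[1:].to_numpy()
        total = (rec["fgv"].to_numpy() * days).sum()
        change = g["length_cm"].iloc[-1] - g["length_cm"].iloc[0]
        assert abs(total - change) < 1e-9


# --- positivity ------------------------------------------------------------

def test_enforce_positive_passes_positives_through():
    out, eps, n = enforce_positive(np.array([0.004, 0.001]))
    assert np.array_equal(out, [0.004, 0.001]) and n == 0


def test_enforce_positive_clamps_to_half_smallest_positive():
    out, eps, n = enforce_positive(np.array([0.004, -0.003, 0.002]))
    assert eps == pytest.approx(0.001)
    assert out[1] == pytest.approx(0.001) and n == 1


def test_enforce_positive_all_negative_uses_fallback(caplog):
    import logging
    with caplog.at_level(logging.WARNING, logger="ctxgrowth.preprocess"):
        out, eps, n = enforce_positive(np.array([-0.1, -0.2]))
    assert eps == pytest.approx(1e-6)
    assert np.all(out == 1e-6) and n == 2
    assert any("fallback" in r.message for r in caplog.records)


# --- standardization -------------------------------------------------------

def test_standardize_2sd_defining_property(rng):
    x = rng.normal(3.0, 2.0, 500)
    z, params = standardize_2sd(x)
    assert abs(z.mean()) < 1e-12
    assert abs(z.std(ddof=1) - 0.5) < 1e-12
    assert np.max(np.abs(invert_standardization(z, params) - x)) < 1e-12


def test_standardize_balanced_binary_gives_half():
    n = 20
    z, _ = standardize_2sd(np.array([0.0, 1.0] * (n // 2)))
    # sample-SD convention: sd = 0.5*sqrt(n/(n-1)), so values are
    # +-0.5*sqrt((n-1)/n) -> +-0.5 as n grows
    expected = 0.5 * np.sqrt((n - 1) / n)
    assert np.allclose(np.sort(np.unique(z)), [-expected, expected],
                       atol=1e-12)


def test_standardize_constant_rejected():
    with pytest.raises(ValueError):
        standardize_2sd(np.ones(10))


def test_age_standardized_on_pooled_gradient(processed):
    """Both datasets share one age center/scale ("across both datasets")."""
    urine, velocity = processed["urine"], processed["velocity"]
    params = processed["params"]["age_years"]
    pooled = np.concatenate([urine["age_years"], velocity["age_years"]])
    assert params.center == pytest.approx(pooled.mean())
    assert params.scale == pytest.approx(2 * pooled.std(ddof=1))
    for df in (urine, velocity):
        back = df["age_std"] * params.scale + params.center
        assert np.max(np.abs(back - df["age_years"])) < 1e-9


# --- table-level wrappers --------------------------------------------------

def test_preprocess_urine_outputs(cohort_tables):
    individuals, _, urine, _ = cohort_tables
    out, excl, sg_ref = preprocess_urine(urine, individuals)
    assert len(out) + len(excl) == len(urine)
    assert (out["ctx_sg"] > 0).all()
    assert np.allclose(out["log_ctx"], np.log(out["ctx_sg"]))
    assert (out["age_years"] >= 0).all()
    assert sg_ref == pytest.approx(1.013, abs=0.005)


def test_preprocess_urine_unknown_individual_raises(cohort_tables):
    individuals, _, urine, _ = cohort_tables
    bad = urine.copy()
    bad.loc[0, "id"] = "NOPE"
    with pytest.raises(KeyError):
        preprocess_urine(bad, individuals)


def test_preprocess_forearm_outputs(cohort_tables):
    individuals, forearm, _, _ = cohort_tables
    vel, eps, n_clamped = preprocess_forearm(forearm, individuals)
    assert (vel["fgv_pos"] > 0).all()
    assert np.allclose(vel["log_fgv"], np.log(vel["fgv_pos"]))
    assert n_clamped == (vel["fgv"] <= 0).sum()
    # velocity dates sit strictly between the source measurement dates
    g = forearm[forearm["id"] == vel["individual_id"].iloc[0]].sort_values("date")
    first = vel[vel["individual_id"] == vel["individual_id"].iloc[0]]
    d0 = pd.to_datetime(g["date"]).iloc[0]
    d1 = pd.to_datetime(g["date"]).iloc[-1]
    assert ((first["velocity_date"] > d0) & (first["velocity_date"] < d1)).all()
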