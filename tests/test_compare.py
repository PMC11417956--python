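"""Spline-estimate tables, additive male derivation, rank correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctxgrowth.compare import (SplineEstimateTable, compare_sexwise,
                               diurnal_effect, extract_sex_spline_table,
                               load_printed_table, male_from_differences,
                               male_from_draws, spearman)


# --- spearman --------------------------------------------------------------

def test_identity_gives_rho_one():
    x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
    r = spearman(x, x)
    assert r.rho == pytest.approx(1.0)
    assert r.df == 3


def test_printed_female_columns_reproduce_headline_rho():
    fgv = [1.52, 1.18, 2.02, 1.03, -0.15, -0.24, 0.96, -1.20, 0.76]
    ctx = [1.85, 0.27, 0.21, 0.11, -0.05, 0.10, 0.08, -3.09, -0.64]
    r = spearman(fgv, ctx)
    assert r.rho == pytest.approx(0.83, abs=0.005)
    assert r.p_value == pytest.approx(0.008, abs=0.002)
    assert r.method == "exact permutation"
    assert r.n == 9 and r.df == 7


def _brute_force_rho(x, y):
    """Independent oracle: Pearson correlation of rank vectors computed
    from first principles (argsort-based ranks, no ties)."""
    rx = np.empty(len(x))
    rx[np.argsort(x)] = np.arange(1, len(x) + 1)
    ry = np.empty(len(y))
    ry[np.argsort(y)] = np.arange(1, len(y) + 1)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    return float((rxc * ryc).sum()
                 / np.sqrt((rxc**2).sum() * (ryc**2).sum()))


def test_matches_brute_force_over_all_orderings_n5():
    x = np.array([0.3, 1.2, 2.7, 3.1, 4.9])
    for perm in itertools.permutations([10.0, 20.0, 30.0, 40.0, 50.0]):
        y = np.array(perm)
        assert spearman(x, y).rho == pytest.approx(_brute_force_rho(x, y),
                                                   abs=1e-12)


def test_exact_p_matches_subsampled_permutations(rng):
    x = rng.normal(size=9)
    y = rng.normal(size=9)
    r = spearman(x, y)
    hits = 0
    n_mc = 10000
    for _ in range(n_mc):
        rho_perm = _brute_force_rho(x, rng.permutation(y))
        if abs(rho_perm) >= abs(r.rho) - 1e-12:
            hits += 1
    mc_p = hits / n_mc
    assert abs(mc_p - r.p_value) < 4 * np.sqrt(r.p_value * (1 - r.p_value)
                                               / n_mc) + 0.005


def test_exact_and_t_approximation_agree_within_factor_three():
    fgv = [1.52, 1.18, 2.02, 1.03, -0.15, -0.24, 0.96, -1.20, 0.76]
    ctx = [1.85, 0.27, 0.21, 0.11, -0.05, 0.10, 0.08, -3.09, -0.64]
    exact = spearman(fgv, ctx)
    from scipy.stats import t as t_dist
    rho = exact.rho
    t_stat = rho * np.sqrt(7 / (1 - rho**2))
    p_t = 2 * t_dist.sf(abs(t_stat), df=7)
    assert exact.p_value / 3 < p_t < exact.p_value * 3


def test_constant_vector_rejected():
    with pytest.raises(ValueError):
        spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@given(st.permutations(list(range(8))))
@settings(max_examples=40, deadline=None)
def test_monotone_transform_invariance(perm):
    x = np.array(perm, dtype=float)
    y = np.sin(np.arange(8.0))
    base = spearman(x, y).rho
    assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
    assert spearman(x, 3 * y - 7).rho == pytest.approx(base, abs=1e-12)


# --- printed-table arithmetic ---------------------------------------------

@pytest.fixture(scope="module")
def printed():
    t2 = load_printed_table("table2_printed")
    t3 = load_printed_table("table3_printed")
    return t2[t2["sex"] == "F"].reset_index(drop=True), \
        t2[t2["sex"] == "M"].reset_index(drop=True), t3


@pytest.mark.parametrize("spline", list(range(1, 10)))
@pytest.mark.parametrize("outcome", ["fgv", "ctx"])
def test_additive_rule_reproduces_printed_male_estimates(printed, spline,
                                                         outcome):
    """Every printed male estimate equals female + difference (posterior
    means of sums add exactly; interval bounds do not in general)."""
    female, male, diff = printed
    i = spline - 1
    derived = female[f"{outcome}_beta"][i] + diff[f"{outcome}_beta"][i]
    assert derived == pytest.approx(male[f"{outcome}_beta"][i], abs=0.011)


def test_additive_rule_reproduces_quoted_interval_cells(printed):
    """The worked interval cells: FGV spline 1 male bounds are the sums
    of the printed female and difference bounds."""
    female, male, diff = printed
    assert female["fgv_lci"][0] + diff["fgv_lci"][0] == pytest.approx(
        male["fgv_lci"][0], abs=0.011)          # -1.38 + -3.89 = -5.27
    assert female["fgv_uci"][0] + diff["fgv_uci"][0] == pytest.approx(
        male["fgv_uci"][0], abs=0.011)          # 3.91 + -0.23 = 3.68


def test_male_from_differences_additive(printed):
    female, male, diff = printed

    def as_table(df, outcome, sex):
        return SplineEstimateTable(sex=sex, table=pd.DataFrame({
            "spline": df["spline"], "window": df["window"],
            "beta": df[f"{outcome}_beta"], "lci": df[f"{outcome}_lci"],
            "uci": df[f"{outcome}_uci"]}))

    main = as_table(female, "fgv", "F")
    d = as_table(diff.assign(sex="diff"), "fgv", "diff")
    derived = male_from_differences(main, d)
    assert np.allclose(derived.table["beta"],
                       male["fgv_beta"], atol=0.011)
    assert np.allclose(derived.table["lci"],
                       main.table["lci"] + d.table["lci"], atol=1e-12)
    # all-zero differences leave the main table unchanged
    zero = SplineEstimateTable("diff", d.table.assign(beta=0.0, lci=0.0,
                                                      uci=0.0))
    same = male_from_differences(main, zero)
    pd.testing.assert_frame_equal(same.table, main.table)


def test_index_mismatch_rejected(printed):
    female, _, diff = printed
    main = SplineEstimateTable("F", pd.DataFrame({
        "spline": [1, 2], "window": ["a", "b"], "beta": [0.0, 0.0],
        "lci": [0, 0], "uci": [0, 0]}))
    other = SplineEstimateTable("diff", main.table.assign(spline=[2, 3]))
    with pytest.raises(ValueError):
        male_from_differences(main, other)


# --- extraction from fits --------------------------------------------------

def test_extracted_intervals_are_ordered(small_ctx_fit):
    for sex in ("F", "diff"):
        t = extract_sex_spline_table(small_ctx_fit, sex).table
        assert (t["lci"] <= t["beta"]).all()
        assert (t["beta"] <= t["uci"]).all()
        assert list(t["spline"]) == list(range(1, 10))


def test_extraction_deterministic(small_ctx_fit):
    a = extract_sex_spline_table(small_ctx_fit, "F").table
    b = extract_sex_spline_table(small_ctx_fit, "F").table
    pd.testing.assert_frame_equal(a, b)


def test_posterior_sum_male_has_proper_intervals(small_ctx_fit):
    t = male_from_draws(small_ctx_fit).table
    assert (t["lci"] < t["beta"]).all() and (t["beta"] < t["uci"]).all()


def test_unknown_sex_rejected(small_ctx_fit):
    with pytest.raises(KeyError):
        extract_sex_spline_table(small_ctx_fit, "X")


def test_diurnal_effect_format(small_ctx_fit):
    est, se, lci, uci = diurnal_effect(small_ctx_fit)
    assert lci < est < uci
    assert se > 0


def test_compare_sexwise_identical_tables(printed):
    female, _, _ = printed
    t = SplineEstimateTable("F", pd.DataFrame({
        "spline": female["spline"], "window": female["window"],
        "beta": female["fgv_beta"], "lci": female["fgv_lci"],
        "uci": female["fgv_uci"]}))
    res = compare_sexwise({"F": t, "M": t}, {"F": t, "M": t})
    assert res["F"].rho == pytest.approx(1.0)
    assert res["M"].rho == pytest.approx(1.0)
    with pytest.raises(KeyError):
        compare_sexwise({"F": t}, {"F": t, "M": t})
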