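"""Per-sex spline-estimate tables and cross-model rank correlations.

The validation question is whether the age pattern of urinary CTX-I
mirrors the age pattern of forearm growth velocity within each sex.  It
is answered by extracting, from each fitted model, the nine age-spline
coefficient estimates per sex and Spearman-rank-correlating the velocity
estimates against the CTX estimates across the nine age windows.

The female curve is the model's reference (main-effect) smooth; male
estimates are derived by adding the male-deviation coefficients to the
main effects.  Two male interval constructions are produced: the additive
rule that simply sums the female and deviation interval endpoints (the
convention some published tables use — statistically improper, since interval
bounds do not add), and a proper posterior-sum interval from quantiles of
the summed draws.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist

from .model import PosteriorFit

__all__ = [
    "SplineEstimateTable", "CorrelationResult", "extract_sex_spline_table",
    "male_from_differences", "male_from_draws", "spearman",
    "compare_sexwise", "diurnal_effect", "load_printed_table",
]


@dataclass
class SplineEstimateTable:
    """Nine (beta, lci, uci) rows labeled by age window, for one sex
    (or for the male-minus-female differences)."""
    sex: str                      # "F", "M", or "diff"
    table: pd.DataFrame           # columns: spline, window, beta, lci, uci
    derivation: str = "posterior"  # how intervals were obtained

    def betas(self) -> np.ndarray:
        return self.table["beta"].to_numpy(dtype=float)


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p_value: float
    method: str                   # "exact permutation" | "t approximation"
    ties: bool

    @property
    def df(self) -> int:
        return self.n - 2


def extract_sex_spline_table(fit: PosteriorFit, sex: str = "F",
                             estimate: str = "mean") -> SplineEstimateTable:
    """Posterior estimate and central 95% interval of the nine age-spline
    coefficients: ``sex="F"`` reads the main-effect smooth (female is the
    reference category), ``sex="diff"`` the male-deviation coefficients.
    """
    prefix = {"F": "spline", "diff": "sexdiff"}.get(sex)
    if prefix is None:
        raise KeyError(f"no directly sampled coefficients for sex {sex!r}; "
                       "derive males via male_from_differences")
    basis = fit.design.basis
    rows = []
    for j in range(basis.n_coef):
        name = f"b_{prefix}_{j + 1}"
        if name not in fit.draws:
            raise KeyError(f"fit has no coefficient {name}")
        d = fit.stacked(name)
        point = float(d.mean()) if estimate == "mean" else float(np.median(d))
        lo, hi = np.percentile(d, [2.5, 97.5])
        rows.append({"spline": j + 1, "window": basis.labels[j],
                     "beta": point, "lci": float(lo), "uci": float(hi)})
    return SplineEstimateTable(sex=sex, table=pd.DataFrame(rows))


def male_from_differences(main: SplineEstimateTable,
                          diff: SplineEstimateTable) -> SplineEstimateTable:
    """Male rows by elementwise addition of main and deviation cells —
    including the interval bounds, exactly as the source convention adds
    them.  (Adding interval endpoints is not a valid interval for the
    sum; see :func:`male_from_draws` for the proper construction.)"""
    if list(main.table["spline"]) != list(diff.table["spline"]):
        raise ValueError("spline indexing differs between tables")
    out = main.table.copy()
    for col in ("beta", "lci", "uci"):
        out[col] = main.table[col].to_numpy() + diff.table[col].to_numpy()
    return SplineEstimateTable(sex="M", table=out,
                               derivation="additive bounds")


def male_from_draws(fit: PosteriorFit,
                    estimate: str = "mean") -> SplineEstimateTable:
    """Male rows from quantiles of the summed posterior draws
    (main + deviation), the statistically proper interval."""
    basis = fit.design.basis
    rows = []
    for j in range(basis.n_coef):
        d = fit.stacked(f"b_spline_{j + 1}") + fit.stacked(f"b_sexdiff_{j + 1}")
        point = float(d.mean()) if estimate == "mean" else float(np.median(d))
        lo, hi = np.percentile(d, [2.5, 97.5])
        rows.append({"spline": j + 1, "window": basis.labels[j],
                     "beta": point, "lci": float(lo), "uci": float(hi)})
    return SplineEstimateTable(sex="M", table=pd.DataFrame(rows),
                               derivation="posterior sum")


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray,
                         rho_obs: float) -> float:
    """Two-sided exact p-value by enumerating all orderings of one rank
    vector (feasible for n <= 9; 9! = 362,880)."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]                      # (n!, n)
    d2 = ((rx[None, :] - ry_perm) ** 2).sum(axis=1)
    rho_all = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    return float((np.abs(rho_all) >= abs(rho_obs) - 1e-12).mean())


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    p-value: exact permutation when n <= 9 and neither vector has ties,
    otherwise the t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    rx, ry = rankdata(x), rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if n <= 9 and not ties:
        p = _exact_permutation_p(rx, ry, rho)
        method = "exact permutation"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t_stat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * t_dist.sf(abs(t_stat), df=n - 2))
        method = "t approximation"
    return CorrelationResult(rho=rho, n=n, p_value=p, method=method,
                             ties=ties)


def compare_sexwise(vel_tables: dict, ctx_tables: dict) -> dict:
    """Spearman correlation of velocity vs CTX spline estimates per sex.

    ``vel_tables`` and ``ctx_tables`` map sex ("F"/"M") to
    :class:`SplineEstimateTable`.  Returns sex -> CorrelationResult.
    """
    out = {}
    for sex in ("F", "M"):
        if sex not in vel_tables or sex not in ctx_tables:
            raise KeyError(f"missing sex {sex!r} in the estimate tables")
        out[sex] = spearman(vel_tables[sex].betas(), ctx_tables[sex].betas())
    return out


def diurnal_effect(fit: PosteriorFit):
    """(estimate, SE, lCI, uCI) of the standardized time-of-day
    coefficient from a CTX fit; errors on a velocity fit."""
    if "b_time_std" not in fit.draws:
        raise KeyError("fit has no time-of-day coefficient "
                       "(velocity model?); diurnal effect undefined")
    d = fit.stacked("b_time_std")
    lo, hi = np.percentile(d, [2.5, 97.5])
    return float(d.mean()), float(d.std(ddof=1)), float(lo), float(hi)


def load_printed_table(name: str) -> pd.DataFrame:
    """Load one of the packaged printed-table fixtures
    (``table1_printed``, ``table2_printed``, ``table3_printed``)."""
    ref = resources.files("ctxgrowth") / "fixtures" / f"{name}.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
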