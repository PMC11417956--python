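"""Hierarchical Bayesian skew-normal spline regression.

Both study outcomes (log growth velocity; log SG-corrected CTX-I) are
modeled as skew-normal with the mean regressed on

* an intercept,
* a 9-coefficient cubic B-spline age smooth (10-knot basis, sum-to-zero
  constrained; reference sex = female),
* 9 male-deviation spline coefficients (male indicator x basis column),
* a 2-SD-standardized sex main effect,
* a 2-SD-standardized time-of-day covariate (CTX outcome only), and
* random intercepts per individual and per housing site plus a random
  age slope per individual (non-centered parametrization).

The scale ``sigma`` and shape ``alpha`` of the skew-normal are scalar free
parameters (identity links).  Sampling is NUTS over the joint posterior
with analytic gradients; an adaptive random-walk Metropolis fallback is
available for gradient-free runs.  Priors are zero-centered normals on
coefficients, with tighter, sign-informative priors on the male-deviation
coefficients whose age windows fall in the 5-11-year span where the sexes
are expected to differ (females having the earlier, shorter growth
spurt); scale parameters get half-normal priors.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .diagnostics import ess, rhat
from .sampler import adaptive_metropolis, nuts_sample
from .skewnormal import (skewnormal_logpdf, skewnormal_logpdf_grads,
                         skewnormal_rvs)
from .splines import SplineBasis, build_bspline_basis

__all__ = ["ModelSpec", "Design", "Priors", "PosteriorFit",
           "assemble_design", "default_priors", "fit", "fit_model",
           "posterior_predictive_check"]

INFORMATIVE_SPAN = (5.0, 11.0)   # years: expected sex-difference window


@dataclass
class ModelSpec:
    """What to fit and how to sample it.

    Defaults mirror the headline analysis: five chains of 10,000 NUTS
    iterations (2,000 warmup) at adapt-delta 0.99.  Tests and desk runs
    reduce ``n_chains``/``n_iter``.
    """
    response: str = "log_ctx"          # "log_ctx" or "log_fgv"
    n_knots: int = 10
    degree: int = 3
    n_chains: int = 5
    n_iter: int = 10000
    n_warmup: int = 2000
    adapt_delta: float = 0.99
    max_treedepth: int = 10
    method: str = "nuts"               # or "metropolis" (gradient-free)
    seed: int = 0
    prior_scale_default: float = 1.0
    prior_scale_informative: float = 0.5
    store_random_effects: bool = False

    @property
    def include_time(self) -> bool:
        return self.response == "log_ctx"

    def reduced(self, n_chains=2, n_iter=1500, n_warmup=500, **kw):
        """A cheap desk/test configuration of the same model."""
        return replace(self, n_chains=n_chains, n_iter=n_iter,
                       n_warmup=n_warmup, **kw)


@dataclass
class Design:
    X: np.ndarray                 # fixed-effect matrix, n x K
    colnames: list
    y: np.ndarray
    age_std: np.ndarray
    ind_idx: np.ndarray           # individual index per row
    site_idx: np.ndarray
    ind_ids: list
    site_ids: list
    basis: SplineBasis
    spec: ModelSpec

    @property
    def n_obs(self) -> int:
        return len(self.y)


@dataclass
class Priors:
    centers: np.ndarray           # per fixed-effect coefficient
    scales: np.ndarray
    alpha_scale: float = 5.0      # normal prior SD on skewness
    sd_scale: float = 1.0         # half-normal SD on all scale parameters
    info: dict = field(default_factory=dict)  # colname -> why


def _windows_overlap(window, span) -> bool:
    lo, hi = window
    return lo < span[1] and hi > span[0]   # open-interval overlap


def assemble_design(dataset: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build fixed-effect matrix and grouping indices from a processed
    table (needs ``age_std``, ``sex_std``, ``male``, the response column,
    ``individual_id``, ``site_id``; plus ``time_std`` for the CTX model).
    """
    required = {"age_std", "sex_std", "male", "individual_id", "site_id",
                spec.response}
    missing = required - set(dataset.columns)
    if missing:
        raise KeyError(f"dataset is missing columns: {sorted(missing)}")
    age = dataset["age_std"].to_numpy(dtype=float)
    basis = build_bspline_basis(age, n_knots=spec.n_knots, degree=spec.degree)
    n = len(dataset)
    male = dataset["male"].to_numpy(dtype=float)
    if male.min() == male.max():
        warnings.warn("single-sex dataset: sex-deviation columns are all "
                      "zero and the sex effect is unidentified")
    cols = [np.ones(n)]
    names = ["Intercept"]
    for j in range(basis.n_coef):
        cols.append(basis.matrix[:, j])
        names.append(f"spline_{j + 1}")
    for j in range(basis.n_coef):
        cols.append(male * basis.matrix[:, j])
        names.append(f"sexdiff_{j + 1}")
    cols.append(dataset["sex_std"].to_numpy(dtype=float))
    names.append("sex_std")
    if spec.include_time:
        if "time_std" not in dataset.columns:
            raise KeyError("CTX model requires a 'time_std' column")
        cols.append(dataset["time_std"].to_numpy(dtype=float))
        names.append("time_std")
    X = np.column_stack(cols)
    ind_ids = sorted(dataset["individual_id"].unique())
    site_ids = sorted(dataset["site_id"].unique())
    ind_map = {v: i for i, v in enumerate(ind_ids)}
    site_map = {v: i for i, v in enumerate(site_ids)}
    return Design(
        X=X, colnames=names, y=dataset[spec.response].to_numpy(dtype=float),
        age_std=age,
        ind_idx=dataset["individual_id"].map(ind_map).to_numpy(),
        site_idx=dataset["site_id"].map(site_map).to_numpy(),
        ind_ids=ind_ids, site_ids=site_ids, basis=basis, spec=spec)


def default_priors(design: Design) -> Priors:
    """Zero-centered weakly informative priors, except the male-deviation
    spline coefficients whose age windows overlap 5-11 years: those
    encode the expected earlier, shorter female spurt (male-minus-female
    deviation negative while the female spurt peaks, positive once only
    males are still growing), tightly in the velocity model and at twice
    the scale (less informative) in the CTX model."""
    spec = design.spec
    K = design.X.shape[1]
    # prior scales are expressed in units of the response SD so that
    # "scale 1" means one response-SD per coefficient whatever the outcome
    y_sd = float(np.std(design.y, ddof=1)) or 1.0
    centers = np.zeros(K)
    scales = np.full(K, spec.prior_scale_default * y_sd)
    info = {}
    informative_scale = y_sd * (
        spec.prior_scale_informative if spec.response == "log_fgv"
        else 2.0 * spec.prior_scale_informative)
    windows = design.basis.windows
    for j, window in enumerate(windows):
        col = design.colnames.index(f"sexdiff_{j + 1}")
        if _windows_overlap(window, INFORMATIVE_SPAN):
            scales[col] = informative_scale
            # sign: female spurt earlier -> male-minus-female negative
            # before ~9 y, positive in the 9-11 window
            centers[col] = (-0.5 if window[1] <= 9.0 else 0.5) * y_sd
            info[design.colnames[col]] = (
                f"informative (window {window[0]:g}-{window[1]:g} y in "
                f"{INFORMATIVE_SPAN[0]:g}-{INFORMATIVE_SPAN[1]:g})")
        else:
            info[design.colnames[col]] = "default weak prior"
    return Priors(centers=centers, scales=scales, info=info)


@dataclass
class PosteriorFit:
    """Posterior draws with convergence diagnostics.

    ``draws`` maps parameter name -> array (n_chains, n_kept).
    """
    draws: dict
    rhat: dict
    ess: dict
    n_divergent: int
    design: Design
    priors: Priors
    runtime_s: float
    sampler_info: dict = field(default_factory=dict)

    def stacked(self, name) -> np.ndarray:
        return np.concatenate(self.draws[name])

    def summary(self, names=None) -> pd.DataFrame:
        names = names or list(self.draws)
        rows = []
        for nm in names:
            d = self.stacked(nm)
            lo, med, hi = np.percentile(d, [2.5, 50.0, 97.5])
            rows.append({"param": nm, "mean": d.mean(), "sd": d.std(ddof=1),
                         "median": med, "lci": lo, "uci": hi,
                         "rhat": self.rhat.get(nm, np.nan),
                         "ess": self.ess.get(nm, np.nan)})
        return pd.DataFrame(rows).set_index("param")

    def to_frame(self) -> pd.DataFrame:
        """Draws as one column per parameter plus chain/iteration columns."""
        n_chains = next(iter(self.draws.values())).shape[0]
        n_kept = next(iter(self.draws.values())).shape[1]
        out = {"chain": np.repeat(np.arange(n_chains), n_kept),
               "iteration": np.tile(np.arange(n_kept), n_chains)}
        for nm, d in self.draws.items():
            out[nm] = d.reshape(-1)
        return pd.DataFrame(out)


def _pack_info(design: Design):
    n_ind = len(design.ind_ids)
    n_site = len(design.site_ids)
    K = design.X.shape[1]
    # layout: beta (K), log_sigma, alpha, log_sd_ind, log_sd_slope,
    # log_sd_site, u_raw (n_ind), v_raw (n_ind), w_raw (n_site)
    sl_beta = slice(0, K)
    i_lsig, i_alpha = K, K + 1
    i_lsd_u, i_lsd_v, i_lsd_w = K + 2, K + 3, K + 4
    sl_u = slice(K + 5, K + 5 + n_ind)
    sl_v = slice(K + 5 + n_ind, K + 5 + 2 * n_ind)
    sl_w = slice(K + 5 + 2 * n_ind, K + 5 + 2 * n_ind + n_site)
    dim = K + 5 + 2 * n_ind + n_site
    return (sl_beta, i_lsig, i_alpha, i_lsd_u, i_lsd_v, i_lsd_w,
            sl_u, sl_v, sl_w, dim)


def _make_logp_grad(design: Design, priors: Priors):
    X, y = design.X, design.y
    age = design.age_std
    ind, site = design.ind_idx, design.site_idx
    (sl_beta, i_lsig, i_alpha, i_lsd_u, i_lsd_v, i_lsd_w,
     sl_u, sl_v, sl_w, dim) = _pack_info(design)
    n_ind, n_site = len(design.ind_ids), len(design.site_ids)
    pc, ps = priors.centers, priors.scales
    a_sc, sd_sc = priors.alpha_scale, priors.sd_scale

    def logp_grad(theta):
        # transient warmup excursions can produce non-finite intermediate
        # values; they surface as divergences, not warnings
        with np.errstate(over="ignore", invalid="ignore"):
            return _logp_grad_impl(theta)

    def _logp_grad_impl(theta):
        beta = theta[sl_beta]
        # clip log-scales so transient warmup excursions cannot overflow
        sigma = np.exp(min(theta[i_lsig], 50.0))
        alpha = theta[i_alpha]
        sd_u, sd_v, sd_w = np.exp(np.minimum(
            theta[[i_lsd_u, i_lsd_v, i_lsd_w]], 50.0))
        u, v, w = theta[sl_u], theta[sl_v], theta[sl_w]
        mu = X @ beta + sd_u * u[ind] + sd_v * v[ind] * age + sd_w * w[site]
        ll = skewnormal_logpdf(y, mu, sigma, alpha)
        gmu, gsig, galp = skewnormal_logpdf_grads(y, mu, sigma, alpha)
        lp = float(ll.sum())
        # priors (unnormalized)
        lp += float(-0.5 * (((beta - pc) / ps) ** 2).sum())
        lp += -0.5 * (alpha / a_sc) ** 2
        for sd_val, idx in ((sd_u, i_lsd_u), (sd_v, i_lsd_v), (sd_w, i_lsd_w),
                            (sigma, i_lsig)):
            lp += -0.5 * (sd_val / sd_sc) ** 2 + theta[idx]  # + log-Jacobian
        lp += float(-0.5 * (u @ u + v @ v + w @ w))

        g = np.empty(dim)
        g[sl_beta] = X.T @ gmu - (beta - pc) / ps**2
        g[i_lsig] = float(gsig.sum()) * sigma - sigma**2 / sd_sc**2 + 1.0
        g[i_alpha] = float(galp.sum()) - alpha / a_sc**2
        gu = np.bincount(ind, weights=gmu, minlength=n_ind)
        gv = np.bincount(ind, weights=gmu * age, minlength=n_ind)
        gw = np.bincount(site, weights=gmu, minlength=n_site)
        g[sl_u] = sd_u * gu - u
        g[sl_v] = sd_v * gv - v
        g[sl_w] = sd_w * gw - w
        g[i_lsd_u] = sd_u * float(gu @ u) - sd_u**2 / sd_sc**2 + 1.0
        g[i_lsd_v] = sd_v * float(gv @ v) - sd_v**2 / sd_sc**2 + 1.0
        g[i_lsd_w] = sd_w * float(gw @ w) - sd_w**2 / sd_sc**2 + 1.0
        return lp, g

    return logp_grad, dim


def _initial_position(design: Design, rng, dim, jitter=0.05):
    (sl_beta, i_lsig, i_alpha, i_lsd_u, i_lsd_v, i_lsd_w,
     sl_u, sl_v, sl_w, _) = _pack_info(design)
    X, y = design.X, design.y
    K = X.shape[1]
    beta0 = np.linalg.solve(X.T @ X + np.eye(K), X.T @ y)
    resid_sd = float(np.std(y - X @ beta0, ddof=1))
    theta = np.zeros(dim)
    theta[sl_beta] = beta0
    theta[i_lsig] = np.log(max(resid_sd, 1e-3))
    theta[[i_lsd_u, i_lsd_v, i_lsd_w]] = np.log(0.3)
    theta += jitter * rng.standard_normal(dim)
    return theta


def fit(design: Design, priors: Priors | None = None,
        spec: ModelSpec | None = None) -> PosteriorFit:
    """Sample the posterior of the skew-normal spline model.

    Chains are seeded independently from ``spec.seed``.  Raises if the
    log posterior is not finite at initialization; warns (rather than
    failing silently) when every parameter's R-hat exceeds 1.1.
    """
    spec = spec or design.spec
    priors = priors or default_priors(design)
    logp_grad, dim = _make_logp_grad(design, priors)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_chains)
    t0 = time.time()
    chains = []
    n_div = 0
    info = {"step_size": [], "mean_accept": [], "method": spec.method}
    for c in range(spec.n_chains):
        rng = np.random.default_rng(seeds[c])
        x0 = _initial_position(design, rng, dim)
        lp0, _ = logp_grad(x0)
        if not np.isfinite(lp0):
            raise ValueError(
                f"non-finite log density at initialization (chain {c}): "
                f"logp={lp0}; response range "
                f"[{design.y.min():.3g}, {design.y.max():.3g}]")
        if spec.method == "nuts":
            res = nuts_sample(logp_grad, x0, spec.n_iter, spec.n_warmup, rng,
                              target_accept=spec.adapt_delta,
                              max_treedepth=spec.max_treedepth)
        elif spec.method == "metropolis":
            res = adaptive_metropolis(lambda t: logp_grad(t)[0], x0,
                                      5 * spec.n_iter, 5 * spec.n_warmup, rng)
        else:
            raise ValueError(f"unknown sampler method {spec.method!r}")
        chains.append(res.draws)
        n_div += res.n_divergent
        info["step_size"].append(res.step_size)
        info["mean_accept"].append(res.mean_accept)
    runtime = time.time() - t0

    all_draws = np.array(chains)   # (n_chains, n_kept, dim)
    (sl_beta, i_lsig, i_alpha, i_lsd_u, i_lsd_v, i_lsd_w,
     sl_u, sl_v, sl_w, _) = _pack_info(design)
    draws = {}
    for j, name in enumerate(design.colnames):
        draws[f"b_{name}"] = all_draws[:, :, j]
    draws["sigma"] = np.exp(all_draws[:, :, i_lsig])
    draws["alpha"] = all_draws[:, :, i_alpha]
    draws["sd_individual"] = np.exp(all_draws[:, :, i_lsd_u])
    draws["sd_individual_age"] = np.exp(all_draws[:, :, i_lsd_v])
    draws["sd_site"] = np.exp(all_draws[:, :, i_lsd_w])
    if spec.store_random_effects:
        sd_u = np.exp(all_draws[:, :, i_lsd_u])[..., None]
        sd_v = np.exp(all_draws[:, :, i_lsd_v])[..., None]
        sd_w = np.exp(all_draws[:, :, i_lsd_w])[..., None]
        for k, iid in enumerate(design.ind_ids):
            draws[f"r_ind[{iid}]"] = sd_u[:, :, 0] * all_draws[:, :, sl_u][:, :, k]
            draws[f"r_slope[{iid}]"] = sd_v[:, :, 0] * all_draws[:, :, sl_v][:, :, k]
        for k, sid in enumerate(design.site_ids):
            draws[f"r_site[{sid}]"] = sd_w[:, :, 0] * all_draws[:, :, sl_w][:, :, k]

    rhats = {}
    esss = {}
    for nm, d in draws.items():
        if spec.n_chains >= 2 and d.shape[1] >= 4:
            rhats[nm] = rhat(d)
            esss[nm] = ess(d)
    if rhats and all(v > 1.1 for v in rhats.values()):
        warnings.warn("all parameters have R-hat > 1.1: chains have not "
                      "converged; increase iterations or warmup")
    fitted = PosteriorFit(draws=draws, rhat=rhats, ess=esss,
                          n_divergent=n_div, design=design, priors=priors,
                          runtime_s=runtime, sampler_info=info)
    # keep raw state for posterior-predictive replication
    fitted.sampler_info["raw_draws"] = all_draws
    return fitted


def fit_model(dataset: pd.DataFrame, spec: ModelSpec) -> PosteriorFit:
    """Convenience: assemble design, build default priors, sample."""
    design = assemble_design(dataset, spec)
    return fit(design, default_priors(design), spec)


def _mu_from_theta(design: Design, theta):
    (sl_beta, i_lsig, i_alpha, i_lsd_u, i_lsd_v, i_lsd_w,
     sl_u, sl_v, sl_w, _) = _pack_info(design)
    sd_u, sd_v, sd_w = np.exp(theta[[i_lsd_u, i_lsd_v, i_lsd_w]])
    return (design.X @ theta[sl_beta]
            + sd_u * theta[sl_u][design.ind_idx]
            + sd_v * theta[sl_v][design.ind_idx] * design.age_std
            + sd_w * theta[sl_w][design.site_idx])


def posterior_predictive_check(fit_result: PosteriorFit, y=None,
                               n_rep: int = 200, seed: int = 0) -> pd.DataFrame:
    """Compare observed summary statistics with posterior-predictive
    replicates.

    Draws ``n_rep`` replicated datasets (one per posterior draw, evenly
    thinned), computes mean, SD, skewness, min and max of each, and
    reports the tail probability P(T_rep >= T_obs) per statistic.
    Extreme tail probabilities (< 0.05 or > 0.95) flag misfit.
    """
    from scipy.stats import skew as sample_skew

    design = fit_result.design
    y = design.y if y is None else np.asarray(y, dtype=float)
    raw = fit_result.sampler_info["raw_draws"]
    n_chains, n_kept, dim = raw.shape
    flat = raw.reshape(-1, dim)
    idx = np.linspace(0, len(flat) - 1, min(n_rep, len(flat))).astype(int)
    rng = np.random.default_rng(seed)
    stats = {"mean": np.mean, "sd": lambda a: np.std(a, ddof=1),
             "skewness": sample_skew, "min": np.min, "max": np.max}
    obs = {k: float(f(y)) for k, f in stats.items()}
    reps = {k: [] for k in stats}
    for i in idx:
        theta = flat[i]
        mu = _mu_from_theta(design, theta)
        sigma = float(np.exp(theta[design.X.shape[1]]))
        alpha = float(theta[design.X.shape[1] + 1])
        y_rep = skewnormal_rvs(mu, sigma, alpha, mu.shape, rng)
        for k, f in stats.items():
            reps[k].append(float(f(y_rep)))
    rows = []
    for k in stats:
        arr = np.asarray(reps[k])
        rows.append({"statistic": k, "observed": obs[k],
                     "rep_mean": arr.mean(),
                     "tail_prob": float((arr >= obs[k]).mean())})
    return pd.DataFrame(rows).set_index("statistic")
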