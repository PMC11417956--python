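"""Convergence diagnostics for multi-chain MCMC output.

`rhat` is the split-chain Gelman-Rubin potential scale reduction factor:
each chain is split in half, and the between-(half-)chain variance is
compared with the within-chain variance.  We use the conservative form

    R-hat = sqrt( (W + B/h) / W )

with ``W`` the mean within-sequence variance, ``B`` the between-sequence
variance (``h`` draws per split sequence), so R-hat >= 1 always and equals
1 exactly when all split sequences have identical means.

`ess` is the effective sample size from Geyer-style initial positive
sequence truncation of the chain-averaged autocorrelations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rhat", "ess", "split_chains"]


def split_chains(draws: np.ndarray) -> np.ndarray:
    """(m, n) chains -> (2m, n//2) half chains (odd trailing draw dropped)."""
    draws = np.asarray(draws, dtype=float)
    m, n = draws.shape
    h = n // 2
    return np.concatenate([draws[:, :h], draws[:, n - h:]], axis=0)


def rhat(draws, split: bool = True) -> float:
    """Potential scale reduction factor for one parameter.

    Parameters
    ----------
    draws : array (n_chains, n_draws)
        Posterior draws, one row per chain.
    split : bool
        Split each chain in half first (recommended; detects trending
        chains that agree only in their overall means).
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] < 2:
        raise ValueError("rhat requires at least two chains")
    if draws.shape[1] < 2:
        raise ValueError("rhat requires at least two draws per chain")
    seq = split_chains(draws) if split else draws
    m, h = seq.shape
    means = seq.mean(axis=1)
    w = seq.var(axis=1, ddof=1).mean()
    b = h * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else float("inf")
    return float(np.sqrt((w + b / h) / w))


def _autocov(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one sequence via FFT."""
    n = x.size
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real
    return acov / n


def ess(draws) -> float:
    """Effective sample size for one parameter across chains.

    Combines per-chain autocovariances with the multi-chain variance
    estimate, truncating the autocorrelation sum at the first negative
    pair (initial positive sequence).
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    m, n = draws.shape
    if n < 4:
        raise ValueError("ess requires at least four draws per chain")
    acovs = np.array([_autocov(c) for c in draws])
    mean_acov = acovs.mean(axis=0)
    chain_var = draws.var(axis=1, ddof=1).mean()
    between = draws.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = chain_var * (n - 1) / n + between
    if var_plus == 0:
        return float(m * n)
    rho = 1.0 - (chain_var - mean_acov) / var_plus
    # Geyer initial positive sequence on paired sums
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(m * n / tau)
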