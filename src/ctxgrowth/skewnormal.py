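"""Skew-normal distribution in the mean ("centered moment") parametrization.

The regression models in this package put covariates on ``mu``, the *mean*
of a skew-normal response, with ``sigma`` its standard deviation and
``alpha`` the shape (skewness) parameter.  Internally the classic direct
parameters are used::

    delta = alpha / sqrt(1 + alpha**2)
    omega = sigma / sqrt(1 - 2 * delta**2 / pi)     # scale
    xi    = mu - omega * delta * sqrt(2 / pi)        # location

so that ``E[Y] = mu`` and ``SD[Y] = sigma`` hold exactly for every alpha.
The density is ``f(y) = (2/omega) * phi(z) * Phi(alpha * z)`` with
``z = (y - xi)/omega``.  ``alpha = 0`` recovers the normal distribution;
negative alpha gives a left-skewed (long lower tail) distribution, which is
what log-transformed growth-velocity and biomarker data typically show.

Log-densities use :func:`scipy.special.log_ndtr` so the lower tail of
``Phi`` never underflows; analytic derivatives with respect to
``(mu, sigma, alpha)`` are provided for gradient-based MCMC.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr

__all__ = [
    "to_direct_params",
    "skewnormal_logpdf",
    "skewnormal_rvs",
    "skewnormal_logpdf_grads",
]

_B = np.sqrt(2.0 / np.pi)
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def to_direct_params(mu, sigma, alpha):
    """Convert mean-parametrization ``(mu, sigma, alpha)`` to direct
    ``(xi, omega, alpha)`` (location, scale, shape).

    Raises ``ValueError`` for non-positive sigma.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma (scale) must be > 0")
    delta = alpha / np.sqrt(1.0 + alpha**2)
    c = np.sqrt(1.0 - _B**2 * delta**2)
    omega = sigma / c
    xi = mu - omega * delta * _B
    return xi, omega, np.broadcast_to(alpha, xi.shape).copy() if xi.shape else alpha


def skewnormal_logpdf(y, mu, sigma, alpha):
    """Log density of the mean-parametrized skew-normal, elementwise."""
    y = np.asarray(y, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma (scale) must be > 0")
    alpha = np.asarray(alpha, dtype=float)
    delta = alpha / np.sqrt(1.0 + alpha**2)
    c = np.sqrt(1.0 - _B**2 * delta**2)
    # z in terms of mean parameters: z = c*(y - mu)/sigma + b*delta
    z = c * (y - mu) / sigma + _B * delta
    log_omega = np.log(sigma) - np.log(c)
    return np.log(2.0) - log_omega - 0.5 * z**2 - _LOG_SQRT_2PI + log_ndtr(alpha * z)


def skewnormal_rvs(mu, sigma, alpha, size, rng):
    """Draw variates via the convolution construction
    ``X = delta*|U0| + sqrt(1-delta^2)*U1`` with U0, U1 iid standard normal,
    then affine-map to the requested mean/sd."""
    xi, omega, _ = to_direct_params(mu, sigma, alpha)
    delta = alpha / np.sqrt(1.0 + alpha**2)
    u0 = rng.standard_normal(size)
    u1 = rng.standard_normal(size)
    x = delta * np.abs(u0) + np.sqrt(1.0 - delta**2) * u1
    return xi + omega * x


def _phi_over_Phi(x):
    # exp(log phi - log Phi); stable for very negative x where both tails shrink
    return np.exp(-0.5 * x**2 - _LOG_SQRT_2PI - log_ndtr(x))


def skewnormal_logpdf_grads(y, mu, sigma, alpha):
    """Elementwise partial derivatives of :func:`skewnormal_logpdf`.

    Returns ``(dmu, dsigma, dalpha)`` arrays shaped like ``y``.  The mu
    derivative is what regression designs chain through; sigma and alpha
    derivatives are summed by the sampler for the scalar likelihood
    parameters.
    """
    y = np.asarray(y, dtype=float)
    sigma = float(sigma)
    alpha = float(alpha)
    if sigma <= 0:
        raise ValueError("sigma (scale) must be > 0")
    delta = alpha / np.sqrt(1.0 + alpha**2)
    dprime = (1.0 + alpha**2) ** -1.5  # d delta / d alpha
    c2 = 1.0 - _B**2 * delta**2
    c = np.sqrt(c2)
    z = c * (y - mu) / sigma + _B * delta
    T = _phi_over_Phi(alpha * z)

    dL_dz = -z + alpha * T
    dmu = -dL_dz * c / sigma
    dsigma = (-1.0 + (z - alpha * T) * (z - _B * delta)) / sigma
    # alpha enters through log(omega), z, and the Phi argument
    dlogomega_da = _B**2 * delta * dprime / c2
    dz_da = _B * dprime - _B**2 * delta * dprime * (z - _B * delta) / c2
    dalpha = -dlogomega_da + T * z + dL_dz * dz_da
    return dmu, dsigma, dalpha
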