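"""B-spline age-smooth basis.

The age smooths use a cubic B-spline basis of dimension ``n_knots`` (the
field's loose "number of knots": interior knots sit at equally spaced
quantiles of the observed ages, boundary knots at the range ends).  The raw
basis is a partition of unity; an identifiability (sum-to-zero) constraint
— centering every column at its sample mean and dropping the final,
oldest-age column, which is minus the sum of the centered others — leaves
``n_knots - 1`` coefficient columns that can sit alongside a model
intercept at full rank.

Each retained coefficient is a local bump in age and is labeled with the
approximate age window (in years) where that bump carries most of its
mass; with the default 10-dimensional basis on ages 0-20 these are the nine
windows 0-2.5, 2.5-4.5, 4.5-7, 7-9, 9-11, 11-13, 13-15, 15-17.5, 17.5-20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "build_bspline_basis", "DEFAULT_AGE_WINDOWS"]

#: Approximate age windows (years) labeling the nine default coefficients.
DEFAULT_AGE_WINDOWS = [
    (0.0, 2.5), (2.5, 4.5), (4.5, 7.0), (7.0, 9.0), (9.0, 11.0),
    (11.0, 13.0), (13.0, 15.0), (15.0, 17.5), (17.5, 20.0),
]


@dataclass
class SplineBasis:
    """A fitted (constrained) spline basis, re-evaluable on new points."""

    degree: int
    knots: np.ndarray            # full knot vector, input scale
    col_center: np.ndarray       # column means removed (length n_knots)
    matrix: np.ndarray           # n_obs x n_coef constrained design
    windows: list = field(default_factory=list)  # (lo, hi) years per coef

    @property
    def n_coef(self) -> int:
        return len(self.col_center) - 1

    @property
    def labels(self) -> list:
        return [f"{i + 1}: {lo:g}-{hi:g}" for i, (lo, hi) in enumerate(self.windows)]

    def raw(self, x) -> np.ndarray:
        """Unconstrained basis (partition of unity) at points ``x``."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.knots[0], self.knots[-1]
        xc = np.clip(x, lo, hi)  # basis is constant-extrapolated at the ends
        return BSpline.design_matrix(xc, self.knots, self.degree).toarray()

    def evaluate(self, x) -> np.ndarray:
        """Constrained design at new points, using the stored centering."""
        raw = self.raw(x)
        return (raw - self.col_center)[:, :-1]


def build_bspline_basis(x_std, n_knots: int = 10, degree: int = 3,
                        windows=None) -> SplineBasis:
    """Build the constrained age-smooth basis from observed (standardized)
    ages.

    Parameters
    ----------
    x_std : array
        Observed ages (any affine scale); interior knots go at its
        equally spaced quantiles.
    n_knots : int
        Basis dimension before the constraint; ``n_knots - 1`` coefficients
        remain after it.
    degree : int
        Spline degree (cubic by default).
    windows : list of (lo, hi), optional
        Age-window labels for the coefficients; defaults to the nine
        standard windows when ``n_knots`` is 10.
    """
    x = np.asarray(x_std, dtype=float)
    if x.ndim != 1:
        raise ValueError("x_std must be one-dimensional")
    n_unique = np.unique(x).size
    if n_unique < n_knots:
        raise ValueError(
            f"need at least {n_knots} distinct x values, got {n_unique}")
    n_interior = n_knots - degree - 1
    if n_interior < 0:
        raise ValueError("n_knots must exceed degree + 1")
    probs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, probs)
    lo, hi = x.min(), x.max()
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    raw = BSpline.design_matrix(x, knots, degree).toarray()
    center = raw.mean(axis=0)
    matrix = (raw - center)[:, :-1]
    if windows is None:
        windows = (list(DEFAULT_AGE_WINDOWS) if n_knots == 10
                   else [(np.nan, np.nan)] * (n_knots - 1))
    if len(windows) != n_knots - 1:
        raise ValueError("one age window is required per coefficient")
    return SplineBasis(degree=degree, knots=knots, col_center=center,
                       matrix=matrix, windows=list(windows))
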