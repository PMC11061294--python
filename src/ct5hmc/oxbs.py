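"""Maximum-likelihood inference of 5mC and 5hmC from paired BS/oxBS betas.

The measurement model: bisulfite conversion leaves both 5mC and 5hmC
protected, so a BS beta value estimates m + h; oxidative bisulfite converts
5hmC back to the unprotected state, so an oxBS beta estimates m alone. With
binomial pseudo-count likelihoods of effective depth (n_bs, n_ox),

    L(m, h) = n_bs [b_bs log(m+h) + (1-b_bs) log(1-m-h)]
            + n_ox [b_ox log m    + (1-b_ox) log(1-m)]

maximized over the simplex m >= 0, h >= 0, m + h <= 1. The MLE has a closed
form: when b_bs >= b_ox the interior solution m = b_ox, h = b_bs - b_ox;
otherwise the constraint h >= 0 binds and m is the depth-weighted average
(n_bs b_bs + n_ox b_ox) / (n_bs + n_ox) with h = 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._errors import ValidationError
from ._utils import check_beta_matrix


class OxBSMLE(BaseEstimator):
    """Estimator inferring (5mC, 5hmC) from paired BS and oxBS beta matrices.

    Parameters
    ----------
    n_bs, n_ox : float
        Binomial pseudo-counts (effective depths) of the BS and oxBS assays.
        They only matter on the boundary branch (b_bs < b_ox), where the
        noisier assay gets less weight in the pooled 5mC estimate.
    """

    def __init__(self, n_bs: float = 100.0, n_ox: float = 100.0):
        self.n_bs = n_bs
        self.n_ox = n_ox

    def fit(self, bs=None, ox=None):
        if self.n_bs <= 0 or self.n_ox <= 0:
            raise ValidationError("pseudo-counts n_bs and n_ox must be positive")
        return self

    def transform(
        self, bs: pd.DataFrame, ox: pd.DataFrame
    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        """Return (5mC, 5hmC, boundary_flag) matrices aligned with the inputs.

        Missing entries in either input propagate to missing outputs. The
        boundary flag marks entries where the h >= 0 constraint was active.
        """
        self.fit()
        if not bs.index.equals(ox.index) or not bs.columns.equals(ox.columns):
            raise ValidationError("BS and oxBS matrices must share probe and sample indexing")
        check_beta_matrix(bs, "bs")
        check_beta_matrix(ox, "ox")

        b_bs = bs.to_numpy(dtype=float)
        b_ox = ox.to_numpy(dtype=float)
        missing = ~np.isfinite(b_bs) | ~np.isfinite(b_ox)

        interior = b_bs >= b_ox
        m = np.where(
            interior,
            b_ox,
            (self.n_bs * b_bs + self.n_ox * b_ox) / (self.n_bs + self.n_ox),
        )
        h = np.where(interior, b_bs - b_ox, 0.0)
        m = np.where(missing, np.nan, m)
        h = np.where(missing, np.nan, h)
        boundary = pd.DataFrame(~interior & ~missing, index=bs.index, columns=bs.columns)
        return (
            pd.DataFrame(m, index=bs.index, columns=bs.columns),
            pd.DataFrame(h, index=bs.index, columns=bs.columns),
            boundary,
        )


def estimate_modifications(
    bs: pd.DataFrame,
    ox: pd.DataFrame,
    n_bs: float = 100.0,
    n_ox: float = 100.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Functional wrapper over :class:`OxBSMLE`."""
    return OxBSMLE(n_bs=n_bs, n_ox=n_ox).transform(bs, ox)


def loglik(m, h, b_bs, b_ox, n_bs: float, n_ox: float):
    """Constrained binomial log-likelihood, with the 0 log 0 = 0 convention.

    Exposed so tests and the grid-search oracle evaluate exactly the
    objective the closed form maximizes.
    """
    def xlogy(x, y):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(x == 0.0, 0.0, x * np.log(np.maximum(y, 1e-300)))
        return out

    u = m + h
    return n_bs * (xlogy(b_bs, u) + xlogy(1.0 - b_bs, 1.0 - u)) + n_ox * (
        xlogy(b_ox, m) + xlogy(1.0 - b_ox, 1.0 - m)
    )


def grid_search_mle(
    b_bs: float, b_ox: float, n_bs: float, n_ox: float, step: float = 1e-4
) -> tuple[float, float]:
    """Brute-force likelihood maximization used as an independent oracle.

    For each m on a grid, the optimal h has closed form h = clip(b_bs - m,
    0, 1 - m) because the BS term depends on (m, h) only through m + h; the
    search is therefore one-dimensional without loss of exactness on the
    grid.
    """
    m_grid = np.arange(0.0, 1.0 + step / 2, step)
    h_grid = np.clip(b_bs - m_grid, 0.0, 1.0 - m_grid)
    ll = loglik(m_grid, h_grid, b_bs, b_ox, n_bs, n_ox)
    best = int(np.argmax(ll))
    return float(m_grid[best]), float(h_grid[best])
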