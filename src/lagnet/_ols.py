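"""Small ordinary-least-squares core shared by the inference steps.

Fits are tiny (tens of observations, a handful of coefficients) but very
numerous, so this sticks to plain normal-equation linear algebra instead of
a model-fitting framework.  Two-sided coefficient p-values come from the
Student t distribution with ``n - k`` degrees of freedom.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

__all__ = ["ols_coef_pvalues"]

# Relative tolerance below which a residual sum of squares counts as an
# exact fit (noise-free synthetic data hits this).
_PERFECT_FIT_RTOL = 1e-12


def ols_coef_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS fit of ``y`` on design ``X`` (including any intercept column).

    Returns ``(beta, pvalues)`` where ``pvalues[k]`` is the two-sided
    t-test p-value for coefficient ``k``.  An exact fit (zero residual)
    yields p-value 0 for nonzero coefficients and 1 for zero ones; a
    rank-deficient design falls back to the pseudoinverse.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    df = n - k
    if df < 1:
        raise InsufficientDataError(
            f"{n} observations cannot support {k} regression parameters"
        )
    xtx = X.T @ X
    xty = X.T @ y
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        xtx_inv = np.linalg.pinv(xtx)
    beta = xtx_inv @ xty
    resid = y - X @ beta
    rss = float(resid @ resid)
    yty = float(y @ y)
    scale = max(yty, 1.0e-300)
    if rss <= _PERFECT_FIT_RTOL * scale:
        pvals = np.where(np.abs(beta) > np.sqrt(_PERFECT_FIT_RTOL * scale), 0.0, 1.0)
        return beta, pvals
    sigma2 = rss / df
    se = np.sqrt(sigma2 * np.clip(np.diag(xtx_inv), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    return beta, pvals
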