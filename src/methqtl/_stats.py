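"""Vectorized simple-regression kernel shared by the association scans."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["paired_ols"]


def paired_ols(x: np.ndarray, y: np.ndarray):
    """Column-wise OLS of y on x with intercept, one fit per column pair.

    Parameters
    ----------
    x, y
        Arrays of shape (n_samples, n_pairs); fit j regresses ``y[:, j]`` on
        ``x[:, j]``.

    Returns
    -------
    slope, se, t, p : arrays of shape (n_pairs,)
        Two-sided p-values from the t distribution with n - 2 df. Pairs with
        zero predictor variance get NaN in all four outputs; degenerate
        perfect fits (zero residual variance) get p = 0 and t = +/-inf.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have matching shapes")
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for the regression scan")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = np.einsum("ij,ij->j", xc, yc)
    syy = np.einsum("ij,ij->j", yc, yc)

    # exact constant-predictor detection: centering alone can leave O(eps)
    # residue that masquerades as variance
    ok = (sxx > 0) & (np.ptp(x, axis=0) > 0)
    slope = np.full(x.shape[1], np.nan)
    se = np.full(x.shape[1], np.nan)
    t = np.full(x.shape[1], np.nan)
    p = np.full(x.shape[1], np.nan)

    slope[ok] = sxy[ok] / sxx[ok]
    rss = syy[ok] - slope[ok] * sxy[ok]
    rss = np.maximum(rss, 0.0)  # guard tiny negative round-off
    with np.errstate(divide="ignore", invalid="ignore"):
        se_ok = np.sqrt(rss / (n - 2) / sxx[ok])
        t_ok = slope[ok] / se_ok
    # perfect fit: zero residual -> infinite t, p exactly 0
    t_ok = np.where(se_ok == 0, np.sign(slope[ok]) * np.inf, t_ok)
    se[ok] = se_ok
    t[ok] = t_ok
    p[ok] = 2.0 * stats.t.sf(np.abs(t_ok), df=n - 2)
    return slope, se, t, p
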