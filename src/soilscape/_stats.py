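"""Small shared statistical helpers (HDI, KDE mode, mixed-model summaries)."""

from __future__ import annotations

import numpy as np
from scipy import stats


def hdi(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty draw set")
    m = max(int(np.ceil(prob * n)), 1)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def kde_map(draws: np.ndarray) -> float:
    """Posterior mode estimated from draws via a Gaussian KDE (Scott rule)."""
    x = np.asarray(draws, dtype=float)
    if x.std() == 0:
        return float(x[0])
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])


def standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Scale to mean 0, SD 1; returns (scaled, mean, sd). Constant -> sd=1."""
    x = np.asarray(x, dtype=float)
    mu = float(np.nanmean(x))
    sd = float(np.nanstd(x, ddof=0))
    if sd == 0:
        sd = 1.0
    return (x - mu) / sd, mu, sd


def mixedlm_r2(result, X: np.ndarray) -> tuple[float, float]:
    """Marginal/conditional R-squared of a fitted statsmodels MixedLM.

    Variance-partition definition: fixed-effect variance over total
    (marginal) and fixed + random-intercept variance over total
    (conditional), total = fixed + random + residual.
    """
    fe = np.asarray(result.fe_params)
    fixed = X @ fe
    var_f = float(np.var(fixed))
    var_re = float(np.asarray(result.cov_re).ravel()[0]) if result.cov_re.size else 0.0
    var_resid = float(result.scale)
    total = var_f + var_re + var_resid
    if total == 0:
        return 0.0, 0.0
    return var_f / total, (var_f + var_re) / total


def wald_f(result, term_indices: list[int], den_df: float) -> tuple[float, float, int]:
    """Wald F-test that a set of fixed-effect coefficients is zero.

    Returns (F, p, num_df) with the given denominator degrees of freedom
    (the nested within-group convention: N - n_groups - #within terms).
    """
    fe = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[: len(fe), : len(fe)]
    idx = np.asarray(term_indices)
    b = fe[idx]
    v = cov[np.ix_(idx, idx)]
    q = len(idx)
    f_stat = float(b @ np.linalg.solve(v, b) / q)
    p = float(stats.f.sf(f_stat, q, den_df))
    return f_stat, p, q
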