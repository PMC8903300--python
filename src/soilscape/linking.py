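"""Linking ACI around soil-sampling events to community attributes.

For every sampling event the ACI is summarised at three temporal
resolutions — the last valid value directly before sampling, the mean over
+-30 min, and the mean over +-12 h — and each standardized community
attribute (abundance, 0D/1D/2D, the first two NMDS axes) is related to it
with a linear mixed model (random sensor/plot intercept).  The closer the
acoustic window is to the sampling moment, the stronger the association is
expected to be; ``resolution_contrast`` reports that ordering.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

from ._stats import mixedlm_r2

__all__ = [
    "align_aci",
    "standardize_attributes",
    "fit_link_lmm",
    "resolution_contrast",
    "RESOLUTIONS",
]

RESOLUTIONS = ("aci_before", "aci_1h", "aci_24h")


def align_aci(series: pd.DataFrame, sampling_times: pd.DataFrame) -> pd.DataFrame:
    """ACI at three resolutions around each sampling event.

    ``series``: sensor_id, time, aci, valid.  ``sampling_times``: sensor,
    time (one row per sampling event; extra columns carried through).
    ``aci_before`` is the most recent valid value strictly preceding the
    event; ``aci_1h``/``aci_24h`` are means of valid values over centred
    +-30-min / +-12-h windows.  Events with no valid value in a window get
    a missing value at that resolution.
    """
    s = series.copy()
    s["time"] = pd.to_datetime(s["time"])
    if "valid" in s.columns:
        s = s[s["valid"]]
    s = s.sort_values("time")
    rows = []
    for _, ev in sampling_times.iterrows():
        t = pd.Timestamp(ev["time"])
        sensor = ev["sensor"]
        sub = s[s["sensor_id"] == sensor]
        before = sub[sub["time"] < t]
        rec = dict(ev)
        rec["aci_before"] = float(before["aci"].iloc[-1]) if len(before) else np.nan
        for name, half in (("aci_1h", pd.Timedelta(minutes=30)),
                           ("aci_24h", pd.Timedelta(hours=12))):
            win = sub[(sub["time"] >= t - half) & (sub["time"] <= t + half)]
            rec[name] = float(win["aci"].mean()) if len(win) else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def standardize_attributes(linked: pd.DataFrame,
                           attributes: list[str]) -> pd.DataFrame:
    """Scale each attribute to mean 0, SD 1 across the linked set."""
    out = linked.copy()
    for a in attributes:
        x = out[a].to_numpy(dtype=float)
        sd = np.nanstd(x)
        out[a] = (x - np.nanmean(x)) / (sd if sd > 0 else 1.0)
    return out


def fit_link_lmm(linked: pd.DataFrame, attribute: str,
                 resolution: str = "aci_before",
                 n_grid: int = 50) -> dict:
    """ACI at one resolution regressed on one standardized attribute.

    Random plot (= sensor) intercept; returns slope, its p-value, marginal
    and conditional R-squared, and a prediction curve over the attribute
    range with a pointwise 95 % confidence band (fixed-effects only).
    """
    if resolution not in RESOLUTIONS:
        raise ValueError(f"resolution must be one of {RESOLUTIONS}")
    df = linked.dropna(subset=[attribute, resolution]).copy()
    if len(df) < 10:
        raise ValueError("need at least 10 linked samples")
    if df["sensor"].nunique() < 2:
        raise ValueError("need at least 2 plots")
    x = df[attribute].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("attribute is constant")
    y = df[resolution].to_numpy(dtype=float)
    exog = np.column_stack([np.ones(len(x)), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MixedLM(y, exog, groups=df["sensor"].to_numpy()).fit(reml=True)
    slope = float(res.fe_params[1])
    p = float(res.pvalues[1])
    r2m, r2c = mixedlm_r2(res, exog)
    if not np.isfinite(p):
        # random-intercept variance on the boundary: the mixed fit
        # degenerates to ordinary least squares, so use its inference
        import statsmodels.api as sm
        ols = sm.OLS(y, exog).fit()
        slope, p = float(ols.params[1]), float(ols.pvalues[1])
        r2m = r2c = float(ols.rsquared)
        res = ols
    grid = np.linspace(x.min(), x.max(), n_grid)
    gx = np.column_stack([np.ones(n_grid), grid])
    coefs = np.asarray(getattr(res, "fe_params", res.params))
    pred = gx @ coefs[:2]
    cov = np.asarray(res.cov_params())[:2, :2]
    se = np.sqrt(np.einsum("ij,jk,ik->i", gx, cov, gx))
    return {"attribute": attribute, "resolution": resolution,
            "slope": slope, "p": p,
            "marginal_R2": r2m, "conditional_R2": r2c,
            "n": len(df),
            "curve": pd.DataFrame({"x": grid, "fit": pred,
                                   "lo": pred - 1.96 * se,
                                   "hi": pred + 1.96 * se})}


def resolution_contrast(results: dict[str, dict]) -> dict:
    """Marginal R-squared per resolution and whether it decays with window size.

    ``results`` maps resolution name -> ``fit_link_lmm`` output for one
    attribute.  A descriptive diagnostic, not a test: reports whether
    R2(before) >= R2(1h) >= R2(24h) over the resolutions available.
    """
    r2 = {res: results[res]["marginal_R2"]
          for res in RESOLUTIONS if res in results}
    vals = [r2[r] for r in RESOLUTIONS if r in r2]
    ordered = all(a >= b for a, b in zip(vals, vals[1:])) if len(vals) >= 2 else None
    return {"marginal_R2": r2, "ordered": ordered,
            "n_resolutions": len(vals)}
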