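"""Hierarchical gamma autoregressive Bayesian model for ACI time series.

The response is the ACI with the 0.55 noise floor subtracted (so it is
strictly positive).  For sensor ``i`` at time ``t`` the linear predictor is

    eta_it = alpha_i + X_it beta + sum_{l=1}^{L} phi_l * g(y_{i,t-l})

with ``g`` the AR transform (``ln`` by default, so lags act on the same log
scale as the predictor) and the likelihood a gamma law, either the literal
shape-rate reading ``y ~ Gamma(shape=k, rate=e^eta)`` or a mean
parameterisation ``E[y] = e^eta`` with shape ``k``.  Sensor intercepts are
hierarchical, ``alpha_i ~ N(mu_alpha, sigma_alpha^2)``, and coefficients
shrink through ``beta_j ~ N(0, sigma_beta^2)``.  Weakly informative priors:
``mu_alpha ~ N(0, 5)``, half-normal(0, 1) on the standard deviations,
``phi_l ~ N(0, 0.5)``, ``k ~ Exponential(1)``.

Sampling uses an affine-invariant ensemble MCMC; independent ensembles play
the role of chains and split R-hat is reported for every parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import emcee
import arviz as az
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tsa.ar_model import AutoReg, ar_select_order
from statsmodels.tsa.stattools import acf as sm_acf

from ._stats import hdi, kde_map, standardize

__all__ = [
    "ModelData",
    "GammaAutoregression",
    "build_seasonal_design",
    "build_microclimate_design",
    "cross_correlation_lags",
    "select_max_lag",
    "residual_acf",
    "fit_auxiliary_lmm",
    "fit_gamma_ar",
    "predict_scenarios",
]

ACI_OFFSET = 0.55

DAYTIME_LEVELS = ("night", "morning", "afternoon", "evening")  # 00-06 ... 18-24
SEASON_LEVELS = ("winter", "spring", "summer", "fall")


def season_of(ts: pd.Timestamp) -> str:
    """Meteorological quarters: Dec-Feb winter, Mar-May spring, etc."""
    return SEASON_LEVELS[(pd.Timestamp(ts).month % 12) // 3]


def daytime_of(ts: pd.Timestamp) -> str:
    return DAYTIME_LEVELS[pd.Timestamp(ts).hour // 6]


@dataclass
class ModelData:
    """Design-matrix bundle for the gamma AR model.

    ``y`` is the offset response (ACI - 0.55, all > 0); ``X`` has numeric
    columns scaled to mean 0 / SD 1 (dummies unscaled); ``lagged_y`` row t
    holds the L raw responses preceding t within the same sensor.
    """

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    sensor_index: np.ndarray
    sensor_ids: list[str]
    lagged_y: np.ndarray
    time_index: np.ndarray
    scaler: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.y) == 0:
            raise ValueError("no usable rows after filtering/lag trimming")
        if (self.y <= 0).any():
            raise ValueError("all responses must be positive after the offset")
        if self.X.shape[0] != len(self.y):
            raise ValueError("X rows must match y")

    @property
    def L(self) -> int:
        return self.lagged_y.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "y", self.y)
        df.insert(0, "sensor_id", [self.sensor_ids[i] for i in self.sensor_index])
        df.insert(0, "time", self.time_index)
        for l in range(self.L):
            df[f"y_lag{l+1}"] = self.lagged_y[:, l]
        return df


def _infer_step(df: pd.DataFrame, default: pd.Timedelta) -> pd.Timedelta:
    """Modal within-sensor time spacing (falls back to ``default``)."""
    diffs = (df.sort_values(["sensor_id", "time"])
               .groupby("sensor_id")["time"].diff().dropna())
    if len(diffs) == 0:
        return default
    return diffs.mode().iloc[0]


def _attach_lags(df: pd.DataFrame, L: int, step: pd.Timedelta) -> pd.DataFrame:
    """Add y_lag1..L within sensors, requiring consecutive time steps."""
    out = []
    for _, g in df.groupby("sensor_id", sort=False):
        g = g.sort_values("time").reset_index(drop=True)
        for l in range(1, L + 1):
            lagged = g["y"].shift(l)
            gap_ok = (g["time"] - g["time"].shift(l)) == l * step
            g[f"y_lag{l}"] = lagged.where(gap_ok)
        out.append(g)
    res = pd.concat(out, ignore_index=True)
    if L > 0:
        res = res.dropna(subset=[f"y_lag{l}" for l in range(1, L + 1)])
    return res.reset_index(drop=True)


def _finalize(df: pd.DataFrame, numeric_cols: list[str],
              dummy_cols: list[str], L: int) -> ModelData:
    scaler: dict[str, tuple[float, float]] = {}
    X_cols = []
    columns = []
    for c in numeric_cols:
        scaled, mu, sd = standardize(df[c].to_numpy())
        scaler[c] = (mu, sd)
        X_cols.append(scaled)
        columns.append(c)
    for c in dummy_cols:
        X_cols.append(df[c].to_numpy(dtype=float))
        columns.append(c)
    X = np.column_stack(X_cols) if X_cols else np.zeros((len(df), 0))
    sensor_ids = sorted(df["sensor_id"].unique())
    sensor_index = df["sensor_id"].map({s: i for i, s in enumerate(sensor_ids)}).to_numpy()
    lagged = (df[[f"y_lag{l}" for l in range(1, L + 1)]].to_numpy()
              if L > 0 else np.zeros((len(df), 0)))
    return ModelData(y=df["y"].to_numpy(), X=X, columns=columns,
                     sensor_index=sensor_index, sensor_ids=sensor_ids,
                     lagged_y=lagged, time_index=df["time"].to_numpy(),
                     scaler=scaler)


def build_seasonal_design(series: pd.DataFrame, L: int = 0,
                          offset: float = ACI_OFFSET) -> ModelData:
    """Daytime x season factorial design from a 6-h aggregated ACI series.

    Daytime levels are [00-06) night, [06-12) morning, [12-18) afternoon,
    [18-24) evening; seasons are meteorological quarters.  Reference cell:
    winter night.  All interaction columns are included (saturated 4x4).
    """
    df = series.copy()
    df["time"] = pd.to_datetime(df["time"])
    if df["time"].isna().any():
        raise ValueError("unmapped timestamps in series")
    df["y"] = df["aci"] - offset
    n_drop = int((df["y"] <= 0).sum())
    if n_drop:
        warnings.warn(f"dropping {n_drop} rows with ACI <= offset", stacklevel=2)
    df = df[df["y"] > 0].copy()
    df["daytime"] = df["time"].map(daytime_of)
    df["season"] = df["time"].map(season_of)
    for lev in ("spring", "summer", "fall"):
        if lev not in set(df["season"]) and df["season"].nunique() == 1:
            warnings.warn("single season present; season columns are degenerate",
                          stacklevel=2)
            break
    dummy_cols = []
    for lev in DAYTIME_LEVELS[1:]:
        col = f"daytime_{lev}"
        df[col] = (df["daytime"] == lev).astype(float)
        dummy_cols.append(col)
    for lev in SEASON_LEVELS[1:]:
        col = f"season_{lev}"
        df[col] = (df["season"] == lev).astype(float)
        dummy_cols.append(col)
    for d in DAYTIME_LEVELS[1:]:
        for s in SEASON_LEVELS[1:]:
            col = f"daytime_{d}:season_{s}"
            df[col] = df[f"daytime_{d}"] * df[f"season_{s}"]
            dummy_cols.append(col)
    df = _attach_lags(df, L, _infer_step(df, pd.Timedelta(hours=6)))
    return _finalize(df, [], dummy_cols, L)


def build_microclimate_design(series: pd.DataFrame, mc: pd.DataFrame,
                              L: int = 0, lag: int = -1,
                              offset: float = ACI_OFFSET) -> ModelData:
    """10-min design with soil moisture (+ quadratic), temperatures, heating.

    ``lag=-1`` pairs each ACI value with the covariates one step *after* it
    (cross-correlation places the peak at lag -1, read as a clock offset of
    the logging chains, not a causal lead).  The positive 30-min heating
    column ``max(0, T_surf(t) - T_surf(t-30min))`` is derived before the
    shift; all numeric columns are scaled after derivation.
    """
    mc = mc.copy()
    mc["time"] = pd.to_datetime(mc["time"])
    series = series.copy()
    series["time"] = pd.to_datetime(series["time"])
    if "valid" in series.columns:
        series = series[series["valid"]]
    has_sensor_mc = "sensor_id" in mc.columns
    covars = ["soil_moisture", "soil_temp", "surface_temp"]
    step = pd.Timedelta(minutes=10)

    def _derive(g: pd.DataFrame) -> pd.DataFrame:
        g = g.sort_values("time").reset_index(drop=True)
        steps30 = int(pd.Timedelta(minutes=30) / step)
        prev = g["surface_temp"].shift(steps30)
        g["delta_t30"] = np.maximum(0.0, g["surface_temp"] - prev)
        cols = covars + ["delta_t30"]
        # lag adjustment: row t carries x_{t - lag} (lag=-1 -> next step)
        g[cols] = g[cols].shift(lag)
        return g

    if has_sensor_mc:
        mc = pd.concat([_derive(g) for _, g in mc.groupby("sensor_id", sort=False)],
                       ignore_index=True)
        merged = series.merge(mc, on=["sensor_id", "time"], how="inner")
    else:
        mc = _derive(mc)
        merged = series.merge(mc, on="time", how="inner")
    merged["y"] = merged["aci"] - offset
    merged = merged[merged["y"] > 0].copy()
    merged["soil_moisture_sq"] = merged["soil_moisture"] ** 2
    numeric = ["soil_moisture", "soil_moisture_sq", "soil_temp",
               "surface_temp", "delta_t30"]
    before = len(merged)
    merged = merged.dropna(subset=numeric)
    if len(merged) < before:
        warnings.warn(f"dropped {before - len(merged)} rows with missing "
                      "covariates", stacklevel=2)
    merged = _attach_lags(merged, L, _infer_step(merged, step))
    return _finalize(merged, numeric, [], L)


# ---------------------------------------------------------------------------
# Lag identification


def _prewhiten(x: np.ndarray, y: np.ndarray,
               max_order: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Filter both series with an AR model fitted to ``x`` (order by AIC)."""
    n = len(x)
    if max_order is None:
        max_order = max(1, min(int(10 * np.log10(n)), n // 5))
    sel = ar_select_order(x, maxlag=max_order, ic="aic", old_names=False)
    order = max(sel.ar_lags) if sel.ar_lags else 1
    fit = AutoReg(x, lags=order, old_names=False).fit()
    params = fit.params  # const, ar coefficients

    def apply(series: np.ndarray) -> np.ndarray:
        out = series[order:] - params[0]
        for i in range(1, order + 1):
            out = out - params[i] * series[order - i: len(series) - i]
        return out

    return apply(x), apply(y)


def cross_correlation_lags(x: np.ndarray, y: np.ndarray,
                           max_lag: int) -> pd.DataFrame:
    """CCF of pre-whitened, first-differenced series per lag.

    Positive lag ``l`` correlates ``y_t`` with ``x_{t-l}`` (covariate in the
    past); negative lag with ``x_{t+|l|}`` (covariate measured after the
    response).  Both series are first-differenced, then filtered with an
    AR model fitted to ``x`` (order by AIC).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must be aligned and equally long")
    if len(x) <= 3 * max_lag:
        raise ValueError("series too short for the requested max_lag")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant series have undefined cross-correlation")
    ex, ey = _prewhiten(np.diff(x), np.diff(y))
    ex = (ex - ex.mean()) / ex.std()
    ey = (ey - ey.mean()) / ey.std()
    n = len(ex)
    rows = []
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = ex[: n - lag], ey[lag:]
        else:
            a, b = ex[-lag:], ey[: n + lag]
        rows.append({"lag": lag, "ccf": float(np.mean(a * b)), "n": len(a)})
    return pd.DataFrame(rows)


def residual_acf(residuals: np.ndarray, nlags: int = 40) -> np.ndarray:
    """Autocorrelation function of model residuals (lags 0..nlags)."""
    return sm_acf(np.asarray(residuals, dtype=float), nlags=nlags, fft=True)


def select_max_lag(acf_values: np.ndarray, candidate_max: int,
                   threshold: float = 0.05,
                   override: int | None = None) -> int:
    """Largest interior local maximum of the ACF below ``candidate_max``.

    ``acf_values[l]`` is the autocorrelation at lag ``l`` (so index 0 is 1).
    The criterion in the field analysis is judgment-based ("a reasonable
    local maximum"), hence the manual ``override``.  Returns 1 with a
    warning when no local maximum exceeds ``threshold``.
    """
    if override is not None:
        return int(override)
    a = np.asarray(acf_values, dtype=float)
    upper = min(candidate_max, len(a) - 2)
    best = None
    for l in range(2, upper + 1):
        if a[l] > threshold and a[l] >= a[l - 1] and a[l] >= a[l + 1]:
            best = l
    if best is None:
        warnings.warn("no qualifying ACF local maximum; falling back to L=1",
                      stacklevel=2)
        return 1
    return best


def fit_auxiliary_lmm(data: ModelData) -> np.ndarray:
    """Residuals of ``log(y) ~ X`` with a random sensor intercept (REML).

    Used only to pick the AR order: the residual ACF of this simpler model
    indicates how much serial structure the gamma AR model must absorb.
    Falls back to plain least squares when the mixed fit is singular.
    """
    ly = np.log(data.y)
    exog = np.column_stack([np.ones(len(ly)), data.X])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(ly, exog, groups=data.sensor_index).fit(reml=True)
        resid = np.asarray(res.resid)
        if not np.all(np.isfinite(resid)):
            raise ValueError("non-finite residuals")
    except (np.linalg.LinAlgError, ValueError) as err:
        warnings.warn(f"mixed fit failed ({err}); using OLS residuals",
                      stacklevel=2)
        coef, *_ = np.linalg.lstsq(exog, ly, rcond=None)
        resid = ly - exog @ coef
    order = np.lexsort((pd.to_datetime(pd.Series(data.time_index)).to_numpy()
                        if data.time_index.dtype.kind == "M"
                        else data.time_index, data.sensor_index))
    return resid[order]


# ---------------------------------------------------------------------------
# The hierarchical gamma AR model


class GammaAutoregression(BaseEstimator):
    """Hierarchical gamma regression with autoregressive lags, fit by MCMC.

    Parameters
    ----------
    L : AR order; must match the width of ``lagged_y`` passed to ``fit``.
    parameterization : "rate" for the literal ``y ~ Gamma(k, e^eta)``
        shape-rate reading, "mean" for ``E[y] = e^eta`` with shape ``k``.
    ar_transform : "log" applies ``phi_l * ln(y_{t-l})``; "identity" uses
        the raw lagged response.
    n_chains, n_draws : independent ensembles and post-warm-up draws kept
        per ensemble (default 4 x 1000).
    warmup_steps : ensemble steps discarded as warm-up.
    n_walkers : walkers per ensemble (default ``max(2*ndim+2, 16)``).

    Fitted attributes: ``posterior_`` (parameter -> (chains, draws) array),
    ``rhat_``, ``converged_``, ``ar_plugin_`` (training mean of ``g(y)``),
    ``sensor_ids_``.
    """

    def __init__(self, L: int = 0, parameterization: str = "rate",
                 ar_transform: str = "log", n_chains: int = 4,
                 n_draws: int = 1000, warmup_steps: int = 1500,
                 thin: int = 10, n_walkers: int | None = None,
                 prior_sd_mu_alpha: float = 5.0,
                 prior_sd_sigma: float = 1.0,
                 prior_sd_phi: float = 0.5,
                 prior_rate_k: float = 1.0,
                 rhat_threshold: float = 1.05,
                 random_state: int | None = None):
        self.L = L
        self.parameterization = parameterization
        self.ar_transform = ar_transform
        self.n_chains = n_chains
        self.n_draws = n_draws
        self.warmup_steps = warmup_steps
        self.thin = thin
        self.n_walkers = n_walkers
        self.prior_sd_mu_alpha = prior_sd_mu_alpha
        self.prior_sd_sigma = prior_sd_sigma
        self.prior_sd_phi = prior_sd_phi
        self.prior_rate_k = prior_rate_k
        self.rhat_threshold = rhat_threshold
        self.random_state = random_state

    # -- parameter vector layout -------------------------------------------
    def _layout(self, S: int, p: int) -> dict[str, slice]:
        idx = {}
        j = 0
        idx["mu_alpha"] = slice(j, j + 1); j += 1
        idx["log_sigma_alpha"] = slice(j, j + 1); j += 1
        idx["alpha"] = slice(j, j + S); j += S
        if p > 0:
            idx["log_sigma_beta"] = slice(j, j + 1); j += 1
            idx["beta"] = slice(j, j + p); j += p
        if self.L > 0:
            idx["phi"] = slice(j, j + self.L); j += self.L
        idx["log_k"] = slice(j, j + 1); j += 1
        idx["_ndim"] = j
        return idx

    def _log_prob(self, theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                  sensor: np.ndarray, G: np.ndarray,
                  layout: Mapping[str, slice]) -> np.ndarray:
        th = np.atleast_2d(theta)
        W = th.shape[0]
        mu_a = th[:, layout["mu_alpha"]][:, 0]
        lsa = th[:, layout["log_sigma_alpha"]][:, 0]
        sa = np.exp(lsa)
        alpha = th[:, layout["alpha"]]
        p = X.shape[1]
        lp = -0.5 * (mu_a / self.prior_sd_mu_alpha) ** 2
        lp = lp - 0.5 * (sa / self.prior_sd_sigma) ** 2 + lsa  # half-normal + Jacobian
        lp = lp - (0.5 * ((alpha - mu_a[:, None]) / sa[:, None]) ** 2
                   + np.log(sa)[:, None]).sum(axis=1)
        eta = np.take_along_axis(alpha, sensor[None, :].repeat(W, axis=0), axis=1)
        if p > 0:
            lsb = th[:, layout["log_sigma_beta"]][:, 0]
            sb = np.exp(lsb)
            beta = th[:, layout["beta"]]
            lp = lp - 0.5 * (sb / self.prior_sd_sigma) ** 2 + lsb
            lp = lp - (0.5 * (beta / sb[:, None]) ** 2
                       + np.log(sb)[:, None]).sum(axis=1)
            eta = eta + beta @ X.T
        if self.L > 0:
            phi = th[:, layout["phi"]]
            lp = lp - (0.5 * (phi / self.prior_sd_phi) ** 2).sum(axis=1)
            eta = eta + phi @ G.T
        lk = th[:, layout["log_k"]][:, 0]
        k = np.exp(lk)
        lp = lp - self.prior_rate_k * k + lk  # Exp(rate) prior + Jacobian
        bad = (np.abs(eta) > 30).any(axis=1) | ~np.isfinite(eta).all(axis=1)
        eta = np.clip(eta, -30, 30)
        n = len(y)
        lny_sum = self._lny_sum
        if self.parameterization == "rate":
            ll = (k * eta.sum(axis=1) - (np.exp(eta) * y).sum(axis=1)
                  - n * gammaln(k) + (k - 1) * lny_sum)
        else:
            ll = (n * (k * lk - gammaln(k)) - k * eta.sum(axis=1)
                  - k * (np.exp(-eta) * y).sum(axis=1) + (k - 1) * lny_sum)
        out = lp + ll
        out[bad | ~np.isfinite(out)] = -np.inf
        return out if theta.ndim == 2 else out[0]

    def _initial_state(self, rng: np.random.Generator, y: np.ndarray,
                       S: int, p: int, layout: Mapping[str, slice],
                       n_walkers: int) -> np.ndarray:
        k0 = max((y.mean() / max(y.std(), 1e-6)) ** 2, 0.5)
        if self.parameterization == "rate":
            eta0 = float(np.log(k0 / y.mean()))
        else:
            eta0 = float(np.log(y.mean()))
        center = np.zeros(layout["_ndim"])
        center[layout["mu_alpha"]] = eta0
        center[layout["log_sigma_alpha"]] = np.log(0.3)
        center[layout["alpha"]] = eta0
        if p > 0:
            center[layout["log_sigma_beta"]] = np.log(0.5)
        center[layout["log_k"]] = np.log(k0)
        return center + 0.05 * rng.standard_normal((n_walkers, layout["_ndim"]))

    def fit(self, X: np.ndarray, y: np.ndarray,
            sensor: np.ndarray | None = None,
            lagged_y: np.ndarray | None = None) -> "GammaAutoregression":
        y = np.asarray(y, dtype=float)
        if (y <= 0).any():
            raise ValueError("response must be strictly positive")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, p = X.shape
        if sensor is None:
            sensor = np.zeros(n, dtype=int)
        sensor = np.asarray(sensor)
        if sensor.dtype.kind not in "iu":
            ids = sorted(pd.unique(sensor))
            sensor = pd.Series(sensor).map({s: i for i, s in enumerate(ids)}).to_numpy()
            self.sensor_ids_ = list(ids)
        else:
            self.sensor_ids_ = list(range(int(sensor.max()) + 1))
        S = int(sensor.max()) + 1
        if lagged_y is None:
            lagged_y = np.zeros((n, 0))
        lagged_y = np.asarray(lagged_y, dtype=float)
        if lagged_y.shape[1] != self.L:
            raise ValueError(f"lagged_y width {lagged_y.shape[1]} != L={self.L}")
        G = np.log(lagged_y) if (self.ar_transform == "log" and self.L > 0) else lagged_y
        self._lny_sum = float(np.log(y).sum())
        layout = self._layout(S, p)
        ndim = layout["_ndim"]
        n_walkers = self.n_walkers or max(2 * ndim + 2, 16)
        if n_walkers % 2:
            n_walkers += 1
        steps_post = int(np.ceil(self.n_draws / n_walkers)) * self.thin
        rng = np.random.default_rng(self.random_state)
        chains = []
        for c in range(self.n_chains):
            chain_rng = np.random.default_rng(rng.integers(2**31))
            sampler = emcee.EnsembleSampler(
                n_walkers, ndim, self._log_prob, vectorize=True,
                args=(y, X, sensor, G, layout))
            sampler._random = np.random.RandomState(chain_rng.integers(2**31))
            state = self._initial_state(chain_rng, y, S, p, layout, n_walkers)
            sampler.run_mcmc(state, self.warmup_steps + steps_post, progress=False)
            tail = sampler.get_chain()[-steps_post::self.thin]  # (steps, W, ndim)
            flat = tail.reshape(-1, ndim)[: self.n_draws]
            chains.append(flat)
        draws = np.stack(chains)                               # (chains, draws, ndim)
        self.posterior_ = self._unpack(draws, layout, S, p)
        self.rhat_ = self._compute_rhat()
        self.converged_ = all(r < self.rhat_threshold for r in self.rhat_.values())
        if not self.converged_:
            warnings.warn("chains not converged (max R-hat "
                          f"{max(self.rhat_.values()):.3f})", stacklevel=2)
        gbar = float(G.mean()) if self.L > 0 else 0.0
        self.ar_plugin_ = gbar
        self.n_features_in_ = p
        self.n_sensors_ = S
        return self

    def _unpack(self, draws: np.ndarray, layout: Mapping[str, slice],
                S: int, p: int) -> dict[str, np.ndarray]:
        post: dict[str, np.ndarray] = {}
        post["mu_alpha"] = draws[:, :, layout["mu_alpha"]][:, :, 0]
        post["sigma_alpha"] = np.exp(draws[:, :, layout["log_sigma_alpha"]][:, :, 0])
        a = draws[:, :, layout["alpha"]]
        for i in range(S):
            post[f"alpha[{i}]"] = a[:, :, i]
        if p > 0:
            post["sigma_beta"] = np.exp(draws[:, :, layout["log_sigma_beta"]][:, :, 0])
            b = draws[:, :, layout["beta"]]
            for j in range(p):
                post[f"beta[{j}]"] = b[:, :, j]
        for l in range(self.L):
            post[f"phi[{l+1}]"] = draws[:, :, layout["phi"]][:, :, l]
        post["k"] = np.exp(draws[:, :, layout["log_k"]][:, :, 0])
        return post

    def _compute_rhat(self) -> dict[str, float]:
        ds = az.convert_to_dataset({k: v for k, v in self.posterior_.items()})
        r = az.rhat(ds)
        return {k: float(r[k].values) for k in self.posterior_}

    def draws_frame(self) -> pd.DataFrame:
        """Posterior draws in long form: chain, iteration, parameter, value."""
        rows = []
        for name, arr in self.posterior_.items():
            n_chains, n_draws = arr.shape
            rows.append(pd.DataFrame({
                "chain": np.repeat(np.arange(n_chains), n_draws),
                "iteration": np.tile(np.arange(n_draws), n_chains),
                "parameter": name,
                "value": arr.reshape(-1)}))
        return pd.concat(rows, ignore_index=True)

    # -- prediction --------------------------------------------------------
    def _flat(self, name: str) -> np.ndarray:
        return self.posterior_[name].reshape(-1)

    def expected_response(self, eta: np.ndarray, k: np.ndarray) -> np.ndarray:
        if self.parameterization == "rate":
            return k * np.exp(-eta)
        return np.exp(eta)

    def predictive_draws(self, x_row: np.ndarray,
                         ar_value: float | None = None) -> np.ndarray:
        """Draws of E[y] for one design row, AR term at the plug-in mean."""
        mu_a = self._flat("mu_alpha")
        eta = mu_a.copy()
        if self.n_features_in_ > 0:
            beta = np.column_stack([self._flat(f"beta[{j}]")
                                    for j in range(self.n_features_in_)])
            eta = eta + beta @ np.asarray(x_row, dtype=float)
        if self.L > 0:
            phi = np.column_stack([self._flat(f"phi[{l+1}]")
                                   for l in range(self.L)])
            g = self.ar_plugin_ if ar_value is None else ar_value
            eta = eta + phi.sum(axis=1) * g
        k = self._flat("k")
        return self.expected_response(eta, k)

    def predict(self, X: np.ndarray,
                sensor: np.ndarray | None = None) -> np.ndarray:
        """Posterior-mean expected response per design row (offset scale)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([float(self.predictive_draws(row).mean()) for row in X])


def fit_gamma_ar(data: ModelData, model: GammaAutoregression | None = None,
                 **mcmc) -> GammaAutoregression:
    """Fit the gamma AR model to a ModelData bundle.

    Extra keyword arguments override MCMC settings (``n_draws``,
    ``warmup_steps``, ``random_state``...).  The returned estimator carries
    ``columns_`` and ``scaler_`` so that scenario predictions can accept
    covariates on their original scales.
    """
    if model is None:
        model = GammaAutoregression(L=data.L)
    if model.L != data.L:
        raise ValueError(f"model L={model.L} but data carries L={data.L} lags")
    model.set_params(**mcmc)
    model.fit(data.X, data.y, sensor=data.sensor_index, lagged_y=data.lagged_y)
    model.columns_ = list(data.columns)
    model.scaler_ = dict(data.scaler)
    return model


def predict_scenarios(model: GammaAutoregression,
                      scenarios: Mapping[str, Mapping[str, float]],
                      offset: float = ACI_OFFSET,
                      scaled: bool = False) -> pd.DataFrame:
    """MAP + 95 % HDI of predicted ACI for named predictor-level scenarios.

    Scenario values are given on original covariate scales (unless
    ``scaled=True``) and pass through the scaler stored at fit time;
    unspecified columns sit at their training means (scaled zero).  The AR
    contribution is fixed at the plug-in mean of ``g(y)`` and the 0.55
    offset is restored.
    """
    if not hasattr(model, "columns_"):
        raise ValueError("model must come from fit_gamma_ar to map column names")
    rows = []
    for name, levels in scenarios.items():
        x = np.zeros(len(model.columns_))
        for col, value in levels.items():
            if col not in model.columns_:
                raise KeyError(f"scenario {name!r} references unknown column {col!r}")
            j = model.columns_.index(col)
            if not scaled and col in model.scaler_:
                mu, sd = model.scaler_[col]
                x[j] = (value - mu) / sd
            else:
                x[j] = value
        draws = model.predictive_draws(x) + offset
        lo, hi = hdi(draws, 0.95)
        rows.append({"scenario": name, "map": kde_map(draws),
                     "hdi_low": lo, "hdi_high": hi,
                     "mean": float(draws.mean())})
    return pd.DataFrame(rows)
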