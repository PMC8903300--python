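"""Soil-community diversity, composition and season effects.

Hill numbers qD express diversity as the effective number of equally
abundant taxa at order q (q=0 richness, q=1 exp Shannon entropy, q=2
inverse Simpson concentration).  Composition is summarised by non-metric
multidimensional scaling (NMDS) of Bray-Curtis distances, and season
effects are tested with sensor-stratified PERMANOVA and linear mixed
models (season fixed, sensor random).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.manifold import smacof
from statsmodels.regression.mixed_linear_model import MixedLM

from ._stats import mixedlm_r2, wald_f

__all__ = [
    "hill_number",
    "diversity_profile",
    "bray_curtis",
    "NMDS",
    "permanova",
    "season_lmm",
    "META_COLS",
]

META_COLS = ("season", "sensor", "date")


def _count_matrix(table: pd.DataFrame) -> np.ndarray:
    taxa = [c for c in table.columns if c not in META_COLS]
    return table[taxa].to_numpy(dtype=float)


def hill_number(counts: np.ndarray, q: float) -> float:
    """Effective number of equally abundant taxa at diversity order ``q``.

    With relative abundances p_i: ``(sum p_i^q)^(1/(1-q))`` for q != 1,
    the entropy limit ``exp(-sum p_i ln p_i)`` at q = 1, and the number of
    taxa present at q = 0.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("empty sample: Hill number undefined")
    if q < 0:
        raise ValueError("q must be nonnegative")
    p = counts / counts.sum()
    p = p[p > 0]
    if q == 0:
        return float(len(p))
    if q == 1:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p ** q).sum() ** (1.0 / (1.0 - q)))


def diversity_profile(table: pd.DataFrame) -> pd.DataFrame:
    """Abundance and 0D/1D/2D per sample, metadata carried through."""
    counts = _count_matrix(table)
    out = pd.DataFrame({
        "abundance": counts.sum(axis=1),
        "D0": [hill_number(r, 0) for r in counts],
        "D1": [hill_number(r, 1) for r in counts],
        "D2": [hill_number(r, 2) for r in counts],
    })
    for c in META_COLS:
        if c in table.columns:
            out[c] = table[c].to_numpy()
    return out


def bray_curtis(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Bray-Curtis distance matrix: d(x,y) = sum|x-y| / sum(x+y)."""
    counts = (_count_matrix(table) if isinstance(table, pd.DataFrame)
              else np.asarray(table, dtype=float))
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if (counts.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("distance between all-zero samples is undefined")
    return squareform(pdist(counts, metric="braycurtis"))


def _classical_mds(dist: np.ndarray, k: int) -> np.ndarray:
    """Torgerson scaling start for the iterative NMDS search."""
    n = dist.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    vals = np.maximum(vals[order], 0.0)
    return vecs[:, order] * np.sqrt(vals)


class NMDS(BaseEstimator):
    """Non-metric multidimensional scaling with Kruskal stress-1.

    Runs ``restarts`` random initialisations plus one metric-scaling
    (Torgerson) start and keeps the lowest-stress configuration.
    Fitted attributes: ``embedding_`` (centred), ``stress_`` (stress-1),
    ``converged_``.
    """

    def __init__(self, k: int = 3, restarts: int = 20, max_iter: int = 300,
                 tol: float = 1e-5, random_state: int | None = None):
        self.k = k
        self.restarts = restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, dist: np.ndarray) -> "NMDS":
        dist = np.asarray(dist, dtype=float)
        n = dist.shape[0]
        if dist.shape != (n, n):
            raise ValueError("dist must be square")
        if self.k >= n - 1:
            raise ValueError("k must be < n - 1")
        best_pos, best_stress = None, np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.restarts > 0:
                pos, stress = smacof(
                    dist, metric=False, n_components=self.k,
                    init=None, n_init=self.restarts, max_iter=self.max_iter,
                    eps=self.tol, random_state=self.random_state,
                    normalized_stress=True)
                best_pos, best_stress = pos, stress
            pos, stress = smacof(
                dist, metric=False, n_components=self.k,
                init=_classical_mds(dist, self.k), n_init=1,
                max_iter=self.max_iter, eps=self.tol,
                random_state=self.random_state, normalized_stress=True)
        if stress < best_stress:
            best_pos, best_stress = pos, stress
        self.embedding_ = best_pos - best_pos.mean(axis=0)
        self.stress_ = float(best_stress)
        self.converged_ = bool(np.isfinite(best_stress))
        return self

    def fit_transform(self, dist: np.ndarray) -> np.ndarray:
        return self.fit(dist).embedding_


def _group_ss(d2: np.ndarray, labels: np.ndarray) -> float:
    """Within-group sum of squared distances, sum_g (1/n_g) sum_{i<j in g} d2."""
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss += sub.sum() / (2.0 * len(idx))
    return ss


def permanova(dist: np.ndarray, groups, strata=None, n_perm: int = 1000,
              seed: int | None = None,
              return_permuted: bool = False) -> dict:
    """One-way PERMANOVA with optional restricted (within-strata) permutation.

    pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)) on squared distances;
    the permutation p-value shuffles group labels only within each stratum
    and includes the observed statistic in numerator and denominator.
    """
    dist = np.asarray(dist, dtype=float)
    groups = np.asarray(groups)
    n = len(groups)
    if dist.shape != (n, n):
        raise ValueError("groups must align with dist")
    levels = np.unique(groups)
    a = len(levels)
    if a < 2:
        raise ValueError("need at least two groups")
    d2 = dist ** 2
    ss_total = d2.sum() / (2.0 * n)

    def pseudo_f(labels: np.ndarray) -> float:
        ss_within = _group_ss(d2, labels)
        ss_between = ss_total - ss_within
        with np.errstate(divide="ignore"):
            return (ss_between / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(groups)
    r2 = 1.0 - _group_ss(d2, groups) / ss_total
    rng = np.random.default_rng(seed)
    if strata is None:
        strata_arr = np.zeros(n, dtype=int)
    else:
        strata_arr = np.asarray(strata)
        for s in np.unique(strata_arr):
            if (strata_arr == s).sum() < 2:
                raise ValueError(f"stratum {s!r} has fewer than 2 samples")
    strata_idx = [np.flatnonzero(strata_arr == s) for s in np.unique(strata_arr)]
    # permuted labels, shuffled only within strata (vectorised over permutations)
    perm_labels = np.tile(groups, (n_perm, 1))
    for idx in strata_idx:
        order = np.argsort(rng.random((n_perm, len(idx))), axis=1)
        perm_labels[:, idx] = groups[idx][order]
    # group sizes are permutation-invariant, so SS_within vectorises per level
    ss_within_perm = np.zeros(n_perm)
    for g in levels:
        mask = (perm_labels == g).astype(float)
        n_g = (groups == g).sum()
        ss_within_perm += np.einsum("pi,ij,pj->p", mask, d2, mask) / (2.0 * n_g)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = ((ss_total - ss_within_perm) / (a - 1)) / (ss_within_perm / (n - a))
    # ties count as >= (float noise from the vectorised path must not drop them)
    ge = (f_perm > f_obs) | np.isclose(f_perm, f_obs, rtol=1e-9, atol=1e-12)
    p = (1.0 + ge.sum()) / (n_perm + 1.0)
    out = {"pseudo_F": float(f_obs), "R2": float(r2), "p": float(p),
           "n_perm": n_perm}
    if return_permuted:
        out["permuted_F"] = f_perm
    return out


def season_lmm(table: pd.DataFrame, attribute: str) -> dict:
    """Season effect on one community attribute, sensor as random intercept.

    ``attribute`` is one of ``abundance, D0, D1, D2``; abundance and
    richness are sqrt-transformed.  Returns the season ANOVA row (Wald F
    with the nested within-group denominator df, N - n_sensors - q) and
    marginal/conditional R-squared.
    """
    div = diversity_profile(table)
    if attribute not in ("abundance", "D0", "D1", "D2"):
        raise ValueError(f"unknown attribute {attribute!r}")
    resp = div[attribute].to_numpy(dtype=float)
    if attribute in ("abundance", "D0"):
        resp = np.sqrt(resp)
    if np.std(resp) == 0:
        raise ValueError("attribute is constant; no model to fit")
    seasons = pd.Categorical(div["season"])
    if len(seasons.categories) < 2:
        raise ValueError("need at least 2 seasons")
    sensors = div["sensor"].to_numpy()
    if len(np.unique(sensors)) < 2:
        raise ValueError("need at least 2 sensors")
    dummies = pd.get_dummies(seasons, drop_first=True, dtype=float)
    exog = np.column_stack([np.ones(len(resp)), dummies.to_numpy()])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MixedLM(resp, exog, groups=sensors).fit(reml=True)
    q = dummies.shape[1]
    den_df = len(resp) - len(np.unique(sensors)) - q
    f_stat, p, num_df = wald_f(res, list(range(1, q + 1)), den_df)
    r2m, r2c = mixedlm_r2(res, exog)
    return {"attribute": attribute, "num_df": num_df, "den_df": den_df,
            "F": f_stat, "p": p, "marginal_R2": r2m, "conditional_R2": r2c}
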