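"""Correlation screening of neuronal trajectories against observer parameters.

Each cell's residual trajectory is Pearson-correlated with each of the 13
hierarchical-Gaussian-filter parameter trajectories (aversive-trial subset);
p-values are pooled and converted to Storey q-values, and cells with
q < 0.05 count as significantly correlated.  Per-parameter summaries give
the percentage of positively and negatively correlated cells, per-level
cumulative percentages, a permutation test for polarity bias, and chi-square
comparisons of significant-cell counts between experimental groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .hgf import PARAM_LEVELS, PARAM_NAMES

__all__ = [
    "correlate",
    "storey_pi0",
    "storey_qvalues",
    "polarity_shuffle_test",
    "level_cumsum",
    "group_chi2",
    "group_chi2_family",
    "CorrelationScreen",
]


def _pearson_with_mask(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson correlation of X (cells x trials) with y, dropping
    trials where either is non-finite (pairwise per cell)."""
    n_cells = X.shape[0]
    r = np.full(n_cells, np.nan)
    n = np.zeros(n_cells, dtype=int)
    yfin = np.isfinite(y)
    Xfin = np.isfinite(X)
    # fast path: identical mask for all cells (e.g. excursion-dropped trials
    # are NaN for the whole population)
    colmask = Xfin.all(axis=0)
    if (Xfin == colmask[None, :]).all():
        m = yfin & colmask
        if m.sum() >= 3:
            Xm = X[:, m]
            ym = y[m]
            Xc = Xm - Xm.mean(axis=1, keepdims=True)
            yc = ym - ym.mean()
            denom = np.sqrt((Xc ** 2).sum(axis=1) * (yc ** 2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, Xc @ yc / denom, np.nan)
            n[:] = m.sum()
        return r, n
    for i in range(n_cells):
        m = yfin & Xfin[i]
        if m.sum() < 3:
            continue
        xi, yi = X[i, m], y[m]
        if xi.std() == 0 or yi.std() == 0:
            continue
        r[i] = stats.pearsonr(xi, yi).statistic
        n[i] = m.sum()
    return r, n


def _r_to_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation via the t transform."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r ** 2, 1e-300, None))
        p = 2 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p = np.where(np.isfinite(r) & (n >= 3), p, np.nan)
    return np.clip(p, 0.0, 1.0)


def storey_pi0(p, lam=None) -> float:
    """Estimated null proportion pi0 (smoother method over a lambda grid,
    or the single-lambda estimator when ``lam`` is a scalar)."""
    p = np.asarray(p, dtype=float)
    pv = p[np.isfinite(p)]
    if pv.size == 0:
        raise ValueError("no finite p-values")
    m = pv.size
    if lam is None:
        lam = np.arange(0.05, 0.96, 0.05)
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if lam.size == 1:
        pi0_est = (pv > lam[0]).sum() / (m * (1.0 - lam[0]))
    else:
        pi0_lam = np.array([(pv > l).sum() / (m * (1.0 - l)) for l in lam])
        coeffs = np.polyfit(lam, pi0_lam, deg=3)
        pi0_est = float(np.polyval(coeffs, lam.max()))
    return float(np.clip(pi0_est, 1.0 / m, 1.0))


def storey_qvalues(p, lam=None, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    ``lam`` may be a grid (default 0.05..0.95 in steps of 0.05; a cubic
    polynomial is fit to pi0(lambda) and evaluated at the largest lambda) or
    a scalar for the fixed-lambda estimator.  NaN p-values pass through as
    NaN and do not enter the estimation.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    finite = np.isfinite(p)
    pv = p[finite]
    if pv.size == 0:
        return np.full_like(p, np.nan)
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size

    if pi0 is None:
        pi0 = storey_pi0(pv, lam=lam)

    order = np.argsort(pv)
    ranked = pv[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.full_like(p, np.nan)
    out[np.flatnonzero(finite)[order]] = q
    return out


def correlate(neural: np.ndarray, hgf: pd.DataFrame,
              params: tuple[str, ...] = PARAM_NAMES,
              q_threshold: float = 0.05,
              pool: str = "all") -> pd.DataFrame:
    """Pearson correlation of every cell with every observer parameter.

    ``neural`` is cells x trials (residual trajectories); ``hgf`` the
    aversive-subset parameter trajectories with matching length.  Missing
    values (excursion-dropped trials, guarded learning rates) are dropped
    pairwise.  Returns a long table (cell, param, level, rho, n, p, q,
    significant, polarity); q-values are Storey, pooled across all
    cell-parameter pairs (``pool="param"`` converts per parameter instead).
    """
    neural = np.atleast_2d(np.asarray(neural, dtype=float))
    if len(hgf) != neural.shape[1]:
        raise ValueError(
            f"length mismatch: {neural.shape[1]} trials vs {len(hgf)} rows")
    frames = []
    for name in params:
        y = hgf[name].to_numpy(dtype=float)
        r, n = _pearson_with_mask(neural, y)
        frames.append(pd.DataFrame({
            "cell": np.arange(neural.shape[0]), "param": name,
            "level": PARAM_LEVELS[name], "rho": r, "n": n,
            "p": _r_to_p(r, n),
        }))
    table = pd.concat(frames, ignore_index=True)
    if pool == "all":
        table["q"] = storey_qvalues(table["p"].to_numpy())
    elif pool == "param":
        table["q"] = np.nan
        for name in params:
            sel = table["param"] == name
            table.loc[sel, "q"] = storey_qvalues(table.loc[sel, "p"].to_numpy())
    else:
        raise ValueError("pool must be 'all' or 'param'")
    table["significant"] = table["q"] < q_threshold
    table["polarity"] = np.sign(table["rho"]).fillna(0).astype(int)
    return table


def population_correlation(neural: np.ndarray, hgf: pd.DataFrame,
                           params: tuple[str, ...] = PARAM_NAMES) -> pd.DataFrame:
    """Correlation of the cell-averaged trajectory with each parameter."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pop = np.nanmean(np.atleast_2d(neural), axis=0)[None, :]
    rows = []
    for name in params:
        r, n = _pearson_with_mask(pop, hgf[name].to_numpy(dtype=float))
        rows.append({"param": name, "level": PARAM_LEVELS[name],
                     "rho": float(r[0]), "n": int(n[0]),
                     "p": float(_r_to_p(r, n)[0])})
    return pd.DataFrame(rows)


def param_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Percentages of positively/negatively significant cells per parameter."""
    n_cells = table["cell"].nunique()
    rows = []
    for name, sub in table.groupby("param", sort=False):
        sig = sub[sub["significant"]]
        pos = int((sig["polarity"] > 0).sum())
        neg = int((sig["polarity"] < 0).sum())
        rows.append({
            "param": name, "level": PARAM_LEVELS[name], "n_cells": n_cells,
            "n_significant": pos + neg,
            "pct_significant": 100.0 * (pos + neg) / n_cells,
            "pct_positive": 100.0 * pos / n_cells,
            "pct_negative": 100.0 * neg / n_cells,
        })
    return pd.DataFrame(rows)


def level_cumsum(summary: pd.DataFrame) -> pd.DataFrame:
    """Cumulative significant-cell percentage per hierarchical level."""
    unknown = set(summary["param"]) - set(PARAM_LEVELS)
    if unknown:
        raise ValueError(f"parameters not mapped to a level: {sorted(unknown)}")
    out = (summary.groupby("level")["pct_significant"].sum()
           .rename("cum_pct_significant").reset_index())
    return out


def polarity_shuffle_test(neural: np.ndarray, hgf: pd.DataFrame,
                          n_shuffles: int = 10_000, seed: int = 0,
                          params: tuple[str, ...] = PARAM_NAMES,
                          q_threshold: float = 0.05) -> pd.DataFrame:
    """Permutation test for a bias of the correlation polarity.

    The observed statistic per parameter is the count of positively minus
    negatively significant cells.  The null permutes every cell's trajectory
    across trials independently (destroying temporal alignment while
    preserving each cell's marginal distribution), recomputes the full
    correlation/q-value pipeline per repetition, and the two-sided p is the
    null exceedance of |statistic|; q across parameters is
    Benjamini-Hochberg.
    """
    neural = np.atleast_2d(np.asarray(neural, dtype=float))
    n_cells, n_trials = neural.shape
    observed = correlate(neural, hgf, params=params, q_threshold=q_threshold)
    obs_stat = {}
    any_sig = {}
    for name, sub in observed.groupby("param", sort=False):
        sig = sub[sub["significant"]]
        obs_stat[name] = int((sig["polarity"] > 0).sum()
                             - (sig["polarity"] < 0).sum())
        any_sig[name] = len(sig) > 0

    Y = np.column_stack([hgf[name].to_numpy(dtype=float) for name in params])
    masks = [np.isfinite(Y[:, j]) for j in range(len(params))]
    ystd = []
    for j, mj in enumerate(masks):
        yv = Y[mj, j]
        yc = yv - yv.mean()
        ystd.append(yc / np.sqrt((yc ** 2).sum()))

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(params), dtype=int)
    base = np.broadcast_to(np.arange(n_trials), (n_cells, n_trials))
    for _ in range(n_shuffles):
        perm = rng.permuted(base, axis=1)
        Xp = np.take_along_axis(neural, perm, axis=1)
        pvals = np.empty((n_cells, len(params)))
        rmat = np.empty((n_cells, len(params)))
        for j, mj in enumerate(masks):
            Xm = Xp[:, mj]
            Xc = Xm - np.nanmean(Xm, axis=1, keepdims=True)
            Xc = np.nan_to_num(Xc)
            norm = np.sqrt((Xc ** 2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (Xc @ ystd[j]) / norm
            nj = mj.sum()
            rmat[:, j] = r
            pvals[:, j] = _r_to_p(r, np.full(n_cells, nj))
        q = storey_qvalues(pvals.ravel()).reshape(pvals.shape)
        sig = q < q_threshold
        stat = (sig & (rmat > 0)).sum(axis=0) - (sig & (rmat < 0)).sum(axis=0)
        for j, name in enumerate(params):
            if abs(stat[j]) >= abs(obs_stat[name]):
                exceed[j] += 1

    rows = []
    for j, name in enumerate(params):
        if not any_sig[name] or obs_stat[name] == 0:
            p = 1.0
        else:
            p = (1 + exceed[j]) / (n_shuffles + 1)
        rows.append({"param": name, "level": PARAM_LEVELS[name],
                     "statistic": obs_stat[name], "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def group_chi2(counts_a: tuple[int, int], counts_b: tuple[int, int]) -> dict:
    """Chi-square comparison of (significant, not-significant) counts."""
    obs = np.array([counts_a, counts_b], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError(
            "a margin of the 2x2 table is zero; use an exact test instead")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    if (expected == 0).any():
        raise ValueError("expected cell count of zero; use an exact test")
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof)}


def group_chi2_family(pairs: dict[str, tuple[tuple[int, int], tuple[int, int]]]
                      ) -> pd.DataFrame:
    """Chi-square tests over a family of comparisons with BH FDR q-values."""
    rows = []
    for name, (a, b) in pairs.items():
        res = group_chi2(a, b)
        rows.append({"comparison": name, **res})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


class CorrelationScreen(BaseEstimator):
    """Estimator bundling the correlation table and its summaries.

    ``fit(neural, hgf)`` computes the long correlation table (``table_``),
    per-parameter summary (``summary_``), per-level cumulative percentages
    (``level_summary_``), the population-average correlation
    (``population_``), and the parameter collinearity matrix
    (``param_corr_``).
    """

    def __init__(self, q_threshold: float = 0.05, pool: str = "all",
                 params: tuple[str, ...] = PARAM_NAMES):
        self.q_threshold = q_threshold
        self.pool = pool
        self.params = params

    def fit(self, neural: np.ndarray, hgf: pd.DataFrame) -> "CorrelationScreen":
        self.table_ = correlate(neural, hgf, params=self.params,
                                q_threshold=self.q_threshold, pool=self.pool)
        self.summary_ = param_summary(self.table_)
        self.level_summary_ = level_cumsum(self.summary_)
        self.population_ = population_correlation(neural, hgf,
                                                  params=self.params)
        sub = hgf[list(self.params)]
        self.param_corr_ = sub.corr()
        return self
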