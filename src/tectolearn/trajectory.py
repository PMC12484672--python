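"""Per-cell trial-by-trial aversive-response trajectories.

Two normalization steps turn raw per-trial responses into trajectories
comparable with the Bayesian-observer parameter series:

1. *Stimulus-type normalization*: each aversive-stimulus subtype drives
   cells with its own latency and strength, so the per-type mean (over that
   type's 18 trials across the three analysis epochs) is subtracted,
   leaving trial-to-trial variation independent of stimulus identity.
2. *Non-stationarity elimination*: photobleaching produces a slow decay
   over trials.  A power function f(k) = a*k^b + c is fit to the
   epoch-averaged population mean trajectory (within-epoch trial index k),
   and each cell's trajectory has a scaled, epoch-tiled copy d*f(k)
   subtracted, with a single scalar d per cell so the context-dependent
   epoch contrasts are untouched.  d is the least-squares projection
   coefficient, which makes the residual's Pearson correlation with the
   tiled decay curve exactly zero (well inside the +/-0.05 requirement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic_data import Recording
from .response_analysis import (EXCURSION_THRESHOLD_MM, epoch_zscores)
from .task_design import ANALYSIS_EPOCHS, SessionDesign

__all__ = [
    "aversive_trial_responses",
    "stimulus_normalized_trajectory",
    "fit_decay",
    "remove_decay",
    "DecayRemover",
    "power_law",
]


def power_law(k, a, b, c):
    return a * np.asarray(k, dtype=float) ** b + c


class MissingTypeError(ValueError):
    pass


def aversive_trial_responses(recording: Recording, window_s: float = 2.0,
                             scope: str = "epoch") -> tuple[np.ndarray, pd.DataFrame]:
    """Per-trial outcome-window mean z-scores for the analyzed aversive trials.

    Returns (cells x n_aversive matrix of zbar_k, trial metadata).  Trials
    with excessive platform excursion are kept in the matrix as NaN so the
    trajectory retains its trial alignment; downstream correlations drop
    them pairwise.
    """
    ev = recording.events
    wlen = int(round(window_s * recording.frame_rate))
    cols = []
    meta = []
    for epoch in ANALYSIS_EPOCHS:
        z, offset, _ = epoch_zscores(recording, epoch, scope=scope)
        sel = (ev["epoch"] == epoch) & (ev["outcome"] == "aversive")
        idx = np.flatnonzero(sel.to_numpy())
        onsets = ev.loc[sel, "outcome_onset_frame"].to_numpy() - offset
        for j, (i, o) in enumerate(zip(idx, onsets)):
            resp = z[:, o:o + wlen].mean(axis=1)
            if recording.excursion is not None and \
                    recording.excursion[i] > EXCURSION_THRESHOLD_MM:
                resp = np.full_like(resp, np.nan)
            cols.append(resp)
            meta.append({"k": int(ev["k"].iloc[i]), "epoch": epoch,
                         "aversive_type": ev["aversive_type"].iloc[i],
                         "within_epoch_index": j + 1})
    zbar_k = np.stack(cols, axis=1)
    return zbar_k, pd.DataFrame(meta)


def stimulus_normalized_trajectory(zbar_k: np.ndarray,
                                   types: np.ndarray | pd.Series,
                                   expected_types: tuple[str, ...] | None = None,
                                   ) -> np.ndarray:
    """Subtract the per-stimulus-type mean from each cell's trial responses.

    ``zbar_k`` is cells x trials; ``types`` labels each trial's aversive
    subtype.  The per-type mean is taken over all of that type's trials
    (across epochs), so the output has exactly zero mean per type.
    """
    zbar_k = np.atleast_2d(np.asarray(zbar_k, dtype=float))
    types = np.asarray(types)
    if types.shape[0] != zbar_k.shape[1]:
        raise ValueError("types must label every trial column")
    present = set(types.tolist())
    if expected_types is not None:
        missing = sorted(set(expected_types) - present)
        if missing:
            raise MissingTypeError(f"missing aversive types: {missing}")
    dz = np.empty_like(zbar_k)
    for t in present:
        sel = types == t
        with np.errstate(invalid="ignore"):
            dz[:, sel] = zbar_k[:, sel] - np.nanmean(zbar_k[:, sel], axis=1,
                                                     keepdims=True)
    return dz


def fit_decay(dz: np.ndarray, n_epochs: int = 3,
              b_starts: tuple[float, ...] = (-1.0, -0.5, -0.1),
              ) -> tuple[tuple[float, float, float], dict]:
    """Fit f(k) = a*k^b + c to the epoch-averaged population mean trajectory.

    ``dz`` is cells x trials with the trials ordered epoch-by-epoch; the
    population mean is folded over the ``n_epochs`` equal segments so a
    single within-epoch curve (k = 1..trials_per_epoch) is fit.  The
    nonlinear fit is multi-started over exponents and the best
    sum-of-squares kept.
    """
    dz = np.atleast_2d(dz)
    if dz.shape[0] < 2:
        raise ValueError("need >= 2 cells to estimate the population decay")
    n_trials = dz.shape[1]
    if n_trials % n_epochs:
        raise ValueError(f"{n_trials} trials not divisible into {n_epochs} epochs")
    per = n_trials // n_epochs
    import warnings
    with warnings.catch_warnings():
        # excursion-dropped trials are NaN columns; fold epochs NaN-aware
        warnings.simplefilter("ignore", RuntimeWarning)
        pop = np.nanmean(np.nanmean(dz, axis=0).reshape(n_epochs, per), axis=0)
    k = np.arange(1, per + 1, dtype=float)
    ok = np.isfinite(pop)
    if ok.sum() < 4:
        raise ValueError("too few finite trials to fit the decay curve")
    k, pop = k[ok], pop[ok]

    best = None
    tried = []
    for b0 in b_starts:
        a0 = pop[0] - pop[-1]
        c0 = pop[-1]
        try:
            params, _ = curve_fit(power_law, k, pop, p0=(a0, b0, c0),
                                  maxfev=20000)
        except (RuntimeError, ValueError):
            tried.append(b0)
            continue
        sse = float(((power_law(k, *params) - pop) ** 2).sum())
        if best is None or sse < best[1]:
            best = (params, sse)
    if best is None:
        raise RuntimeError(
            f"power-law fit failed to converge from initial exponents {tried}")
    params, sse = best
    resid_sd = float(np.sqrt(sse / len(pop)))
    diagnostics = {"sse": sse, "residual_sd": resid_sd, "converged": True,
                   "trials_per_epoch": per, "population_mean": pop}
    return tuple(float(p) for p in params), diagnostics


def remove_decay(dz: np.ndarray, decay_params: tuple[float, float, float],
                 n_epochs: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Subtract each cell's least-squares projection onto the tiled decay.

    Returns (d, residuals) where ``residuals = dz - d[:, None] * f_tiled``
    and f restarts at k = 1 in each epoch.  A constant (zero-variance) f
    yields d = 0 and the input unchanged.
    """
    dz = np.atleast_2d(np.asarray(dz, dtype=float))
    n_trials = dz.shape[1]
    per = n_trials // n_epochs
    f = np.tile(power_law(np.arange(1, per + 1), *decay_params), n_epochs)
    fc = f - f.mean()
    denom = float((fc ** 2).sum())
    if denom <= 0:
        import warnings
        warnings.warn("decay curve has zero variance; d set to 0", stacklevel=2)
        return np.zeros(dz.shape[0]), dz.copy()
    # per-cell OLS slope, centering f within each cell's valid trials so the
    # residual correlation with the tiled curve is exactly zero
    valid = np.isfinite(dz)
    d = np.empty(dz.shape[0])
    resid = dz.copy()
    for i in range(dz.shape[0]):
        v = valid[i]
        fv = f[v]
        fvc = fv - fv.mean()
        den = float((fvc ** 2).sum())
        if den <= 0 or v.sum() < 3:
            d[i] = 0.0
            continue
        d[i] = float(fvc @ (dz[i, v] - dz[i, v].mean())) / den
        resid[i] = dz[i] - d[i] * f
    return d, resid


class DecayRemover(BaseEstimator, TransformerMixin):
    """Fit the population photobleaching curve and residualize trajectories.

    ``fit`` estimates the shared power-law decay from the epoch-averaged
    population mean; ``transform`` subtracts each cell's scaled tiled copy.
    Fitted attributes: ``decay_params_`` (a, b, c), ``decay_curve_`` (tiled
    over epochs), ``diagnostics_``; ``coef_`` holds the per-cell scalars
    from the last transform.
    """

    def __init__(self, n_epochs: int = 3,
                 b_starts: tuple[float, ...] = (-1.0, -0.5, -0.1)):
        self.n_epochs = n_epochs
        self.b_starts = b_starts

    def fit(self, X: np.ndarray, y=None) -> "DecayRemover":
        self.decay_params_, self.diagnostics_ = fit_decay(
            X, n_epochs=self.n_epochs, b_starts=self.b_starts)
        per = np.atleast_2d(X).shape[1] // self.n_epochs
        self.decay_curve_ = np.tile(
            power_law(np.arange(1, per + 1), *self.decay_params_), self.n_epochs)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "decay_params_"):
            raise AttributeError("DecayRemover is not fitted")
        self.coef_, resid = remove_decay(X, self.decay_params_,
                                         n_epochs=self.n_epochs)
        return resid


@dataclass
class NeuronalTrajectories:
    """Bundle of the per-cell trajectory stages for one cohort."""

    zbar_k: np.ndarray        # cells x aversive trials
    dz_k: np.ndarray          # stimulus-type normalized
    dz_res: np.ndarray        # decay-removed residual
    d: np.ndarray             # per-cell decay scalar
    decay_params: tuple[float, float, float]
    meta: pd.DataFrame        # per-trial metadata (k, epoch, type)

    def to_frame(self, cells: np.ndarray | None = None) -> pd.DataFrame:
        cells = np.arange(self.zbar_k.shape[0]) if cells is None else cells
        frames = []
        for row, cell in enumerate(cells):
            f = self.meta.copy()
            f.insert(0, "cell", cell)
            f["zbar_k"] = self.zbar_k[row]
            f["dz_k"] = self.dz_k[row]
            f["dz_res"] = self.dz_res[row]
            f["d"] = self.d[row]
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def neuronal_trajectories(recording: Recording, session: SessionDesign | None = None,
                          cell_mask: np.ndarray | None = None,
                          window_s: float = 2.0) -> NeuronalTrajectories:
    """Full trajectory pipeline for one recording: zbar_k -> dz_k -> residual."""
    zbar_k, meta = aversive_trial_responses(recording, window_s=window_s)
    if cell_mask is not None:
        zbar_k = zbar_k[cell_mask]
    expected = tuple(sorted(meta["aversive_type"].unique()))
    dz = stimulus_normalized_trajectory(zbar_k, meta["aversive_type"].to_numpy(),
                                        expected_types=expected)
    remover = DecayRemover().fit(dz)
    resid = remover.transform(dz)
    return NeuronalTrajectories(
        zbar_k=zbar_k, dz_k=dz, dz_res=resid, d=remover.coef_,
        decay_params=remover.decay_params_, meta=meta)
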