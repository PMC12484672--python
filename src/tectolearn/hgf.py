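"""Three-level binary hierarchical Gaussian filter (HGF), forward pass.

The HGF is an ideal Bayesian observer of a binary sequence ``u``.  Level 1
tracks the outcome itself, level 2 the tendency (log-odds) of the
cue-outcome contingency, and level 3 the environmental volatility, i.e. how
quickly the level-2 tendency drifts.  Two tonic parameters control the
filter: ``omega2`` scales the (volatility-modulated) diffusion of the
tendency and ``omega3`` the diffusion of the volatility itself.

The forward pass emits, per trial, 13 named quantities in five classes:
learning rates (alpha1-3), prior predictions (muhat1-3), belief variances
(sigma2hat, sigma3hat), uncertainties (unc1-3), and precision-weighted
prediction errors (epsilon2, epsilon3).  These trajectories serve as
regressors for neuronal-trajectory correlation; no inversion (fitting to
behavior) is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .task_design import SessionDesign

__all__ = [
    "HGFConfig",
    "HGFState",
    "HGFFilter",
    "PARAM_NAMES",
    "PARAM_LEVELS",
    "sigmoid",
    "hgf_step",
    "run_hgf",
    "subset_aversive",
]

#: the 13 per-trial observer parameters, by class
PARAM_NAMES = (
    "alpha1", "alpha2", "alpha3",
    "muhat1", "muhat2", "muhat3",
    "sigma2hat", "sigma3hat",
    "unc1", "unc2", "unc3",
    "epsilon2", "epsilon3",
)

#: hierarchical level of each parameter
PARAM_LEVELS = {
    "alpha1": 1, "muhat1": 1, "unc1": 1,
    "alpha2": 2, "muhat2": 2, "sigma2hat": 2, "unc2": 2, "epsilon2": 2,
    "alpha3": 3, "muhat3": 3, "sigma3hat": 3, "unc3": 3, "epsilon3": 3,
}

_STATE_COLS = ("mu2", "mu3", "sigma2", "sigma3", "delta1", "delta2", "delta3",
               "w2", "r2")


class TrajectoryInvalidError(RuntimeError):
    """A variance became non-positive during filtering."""


@dataclass(frozen=True)
class HGFConfig:
    """Tonic parameters and initial state of the binary HGF.

    Defaults are the canonical binary-HGF priors; the correlation analysis
    downstream is insensitive to affine rescaling of the trajectories.
    """

    omega2: float = -2.0
    omega3: float = -6.0
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0
    #: tolerance around the alpha1 singularity at u = s(mu2)
    alpha1_guard: float = 1e-8
    #: "printed" uses sigma2hat*delta3/sigma3; "canonical" uses the mu3
    #: update increment sigma3*w2*delta2/2
    epsilon3_form: str = "printed"

    def __post_init__(self) -> None:
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("initial variances must be positive")
        if self.alpha1_guard <= 0:
            raise ValueError("alpha1_guard must be positive")
        if self.epsilon3_form not in ("printed", "canonical"):
            raise ValueError("epsilon3_form must be 'printed' or 'canonical'")


@dataclass
class HGFState:
    """Posterior state carried between trials."""

    mu2: float
    mu3: float
    sigma2: float
    sigma3: float
    k: int = 0

    @classmethod
    def initial(cls, config: HGFConfig) -> "HGFState":
        return cls(mu2=config.mu2_0, mu3=config.mu3_0,
                   sigma2=config.sigma2_0, sigma3=config.sigma3_0, k=0)


def sigmoid(x):
    """Logistic link s(x) = 1 / (1 + exp(-x)), numerically stable."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def hgf_step(state: HGFState, u_k: int, config: HGFConfig) -> tuple[HGFState, dict]:
    """Advance the filter by one trial and return the trial record.

    The update order follows the generative hierarchy: priors and predicted
    variances from the previous posterior, then the level-1/2 posterior
    update driven by the prediction error, then the level-3 volatility
    update driven by the precision-weighted level-2 squared surprise.
    """
    u = float(u_k)
    mu2_prev, mu3_prev = state.mu2, state.mu3
    sig2_prev, sig3_prev = state.sigma2, state.sigma3

    # prior predictions
    muhat1 = sigmoid(mu2_prev)
    muhat2 = mu2_prev
    muhat3 = mu3_prev

    # predicted variances
    sigma1hat = muhat1 * (1.0 - muhat1)
    exp_m3w2 = np.exp(mu3_prev + config.omega2)
    sigma2hat = sig2_prev + exp_m3w2
    sigma3hat = sig3_prev + np.exp(config.omega3)

    # level 1-2 posterior update
    mu1 = u
    delta1 = mu1 - muhat1
    sigma2 = 1.0 / (sigma1hat + 1.0 / sigma2hat)
    mu2 = mu2_prev + sigma2 * delta1

    # level 3 volatility update
    w2 = exp_m3w2 / sigma2hat
    r2 = (exp_m3w2 - sig2_prev) / sigma2hat
    delta2 = (sigma2 + (mu2 - mu2_prev) ** 2) / sigma2hat - 1.0
    sigma3 = sigma3hat / (1.0 + sigma3hat * w2 * (w2 + r2 * delta2) / 2.0)
    if sigma3 <= 0 or not np.isfinite(sigma3):
        raise TrajectoryInvalidError(
            f"sigma3 = {sigma3:.3g} <= 0 after update at trial {state.k + 1}"
        )
    mu3 = mu3_prev + sigma3 * w2 * delta2 / 2.0

    # generic prediction error at level 3
    delta3 = (sigma3 + (mu3 - muhat3) ** 2) / sigma3hat - 1.0

    # precision-weighted prediction errors
    epsilon2 = sigma2 * delta1
    if config.epsilon3_form == "printed":
        epsilon3 = sigma2hat * delta3 / sigma3
    else:
        epsilon3 = sigma3 * w2 * delta2 / 2.0

    # uncertainties
    s_mu2 = sigmoid(mu2)
    unc1 = sigma1hat
    unc2 = s_mu2 * (1.0 - s_mu2) * sigma2
    unc3 = exp_m3w2

    # learning rates; alpha1 is undefined where u = s(mu2) (guarded)
    if abs(delta1) < config.alpha1_guard:
        alpha1 = np.nan
    else:
        alpha1 = (s_mu2 - muhat1) / delta1
    alpha2 = sigma2
    alpha3 = sigma3 * exp_m3w2 / (2.0 * sigma2hat)

    record = {
        "u": u_k,
        "alpha1": alpha1, "alpha2": alpha2, "alpha3": alpha3,
        "muhat1": muhat1, "muhat2": muhat2, "muhat3": muhat3,
        "sigma2hat": sigma2hat, "sigma3hat": sigma3hat,
        "unc1": unc1, "unc2": unc2, "unc3": unc3,
        "epsilon2": epsilon2, "epsilon3": epsilon3,
        # intermediates for diagnostics and oracle comparison
        "mu2": mu2, "mu3": mu3, "sigma2": sigma2, "sigma3": sigma3,
        "delta1": delta1, "delta2": delta2, "delta3": delta3,
        "w2": w2, "r2": r2,
    }
    new_state = HGFState(mu2=mu2, mu3=mu3, sigma2=sigma2, sigma3=sigma3,
                         k=state.k + 1)
    return new_state, record


class HGFFilter(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping a binary sequence to HGF trajectories.

    Parameters mirror :class:`HGFConfig`.  ``transform`` returns a wide
    DataFrame with one row per trial (1-based index ``k``), the 13 observer
    parameters, and the posterior-state intermediates.
    """

    def __init__(self, omega2: float = -2.0, omega3: float = -6.0,
                 mu2_0: float = 0.0, sigma2_0: float = 1.0,
                 mu3_0: float = 1.0, sigma3_0: float = 1.0,
                 alpha1_guard: float = 1e-8, epsilon3_form: str = "printed"):
        self.omega2 = omega2
        self.omega3 = omega3
        self.mu2_0 = mu2_0
        self.sigma2_0 = sigma2_0
        self.mu3_0 = mu3_0
        self.sigma3_0 = sigma3_0
        self.alpha1_guard = alpha1_guard
        self.epsilon3_form = epsilon3_form

    def _config(self) -> HGFConfig:
        return HGFConfig(
            omega2=self.omega2, omega3=self.omega3,
            mu2_0=self.mu2_0, sigma2_0=self.sigma2_0,
            mu3_0=self.mu3_0, sigma3_0=self.sigma3_0,
            alpha1_guard=self.alpha1_guard, epsilon3_form=self.epsilon3_form,
        )

    def fit(self, X=None, y=None) -> "HGFFilter":
        self._config()  # validate
        self.n_params_ = len(PARAM_NAMES)
        return self

    def transform(self, u: Iterable[int]) -> pd.DataFrame:
        u = np.asarray(list(u) if not isinstance(u, np.ndarray) else u)
        if u.size == 0:
            raise ValueError("empty contingency vector")
        config = self._config()
        state = HGFState.initial(config)
        records = []
        for k, uk in enumerate(u, start=1):
            try:
                state, rec = hgf_step(state, int(uk), config)
            except TrajectoryInvalidError as err:
                raise TrajectoryInvalidError(f"trial {k}: {err}") from err
            rec["k"] = k
            records.append(rec)
        df = pd.DataFrame.from_records(records)
        cols = ["k", "u", *PARAM_NAMES, *_STATE_COLS]
        return df[cols]


def run_hgf(u: Iterable[int], config: HGFConfig | None = None) -> pd.DataFrame:
    """Run the forward pass over a contingency vector."""
    config = config or HGFConfig()
    return HGFFilter(**{k: getattr(config, k) for k in (
        "omega2", "omega3", "mu2_0", "sigma2_0", "mu3_0", "sigma3_0",
        "alpha1_guard", "epsilon3_form")}).transform(u)


def subset_aversive(trajectories: pd.DataFrame, session: SessionDesign) -> pd.DataFrame:
    """Restrict trajectories to aversive-outcome trials, order preserved.

    Cue/omitted trials are removed so the model trajectories align with the
    neuronal trajectories, which exist for aversive outcomes only.
    """
    analyzed = session.analyzed
    if len(trajectories) != len(analyzed):
        raise ValueError(
            f"length mismatch: {len(trajectories)} trajectory rows vs "
            f"{len(analyzed)} analyzed trials"
        )
    mask = (analyzed["outcome"] == "aversive").to_numpy()
    out = trajectories.loc[mask].reset_index(drop=True)
    out = out.copy()
    out["epoch"] = analyzed.loc[mask, "epoch"].to_numpy()
    out["outcome"] = "aversive"
    return out
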