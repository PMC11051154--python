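"""Lognormal response-time model: person speed, item time intensity, residuals.

Observed log response times are modeled as an additive two-way layout,

    lnRT_ij ~ Normal(mu_ij, sigma^2),    mu_ij = tau_j − gamma_i,

with tau_j a person-level effect, gamma_i an item-level time-intensity
effect, and sigma^2 the residual variance after both are removed.  With the
identifiability constraint mean(gamma) = 0, tau_j is the person's expected
log RT (higher = slower).  Residuals e_ij = lnRT_ij − (tau_j − gamma_i) with
large magnitude in either direction flag erratic responding: unexpectedly
fast (guessing) or unexpectedly slow (strategy search, attentional lapse).

The two-state extension replaces sigma^2 with a state-specific pair
(sigma_1^2 < sigma_2^2); fitting that mixture is the job of
:mod:`respshift.joint_state_model` — here only the homoscedastic fit and the
residual bookkeeping live.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import lsqr

from .data_model import LogRTMatrix

__all__ = ["LognormalRTParams", "ResidualMatrix", "fit_lognormal_rt", "residuals"]


@dataclass(frozen=True)
class LognormalRTParams:
    """Speed/time-intensity/residual-variance estimates.

    ``residual_variance`` is a scalar for the homoscedastic model or a
    length-2 array (state 1 construct-driven, state 2 erratic) for the
    two-state model, in which case sigma2_1 < sigma2_2.
    """

    speed: np.ndarray  # tau_j, person vector
    time_intensity: np.ndarray  # gamma_i, item vector, mean 0
    residual_variance: float | np.ndarray

    def __post_init__(self):
        var = np.asarray(self.residual_variance, dtype=float)
        if np.any(var < 0):
            raise ValueError("residual variance must be non-negative")
        if var.ndim == 1 and var.size == 2 and not var[0] < var[1]:
            raise ValueError("state variances must satisfy sigma2_1 < sigma2_2")

    @property
    def base_sd(self) -> float:
        """Residual SD of the construct-driven state (or the single state)."""
        var = np.atleast_1d(np.asarray(self.residual_variance, float))
        return float(np.sqrt(var[0]))


@dataclass(frozen=True)
class ResidualMatrix:
    """Raw and standardized lognormal-model residuals."""

    values: np.ndarray
    standardized: np.ndarray


def fit_lognormal_rt(lnrt: LogRTMatrix | np.ndarray) -> LognormalRTParams:
    """Gaussian-ML fit of the additive person + item model on log RTs.

    Missing cells are simply excluded. The normal equations of the two-way
    layout are solved by sparse least squares on the observed-cell design
    matrix; the one-dimensional null space (constant shift between tau and
    gamma) is resolved by centering gamma to mean zero.  sigma^2 is the mean
    squared residual over observed cells (the ML estimate).
    """
    values = lnrt.values if isinstance(lnrt, LogRTMatrix) else np.asarray(lnrt, float)
    if values.ndim != 2:
        raise ValueError("lnrt must be a 2-D person × item matrix")
    n_persons, n_items = values.shape
    obs = ~np.isnan(values)
    empty_rows = np.flatnonzero(obs.sum(axis=1) == 0)
    empty_cols = np.flatnonzero(obs.sum(axis=0) == 0)
    if empty_rows.size or empty_cols.size:
        raise ValueError(
            f"cannot fit: empty person rows {empty_rows.tolist()} / "
            f"empty item columns {empty_cols.tolist()}"
        )
    if n_persons < 2 or n_items < 2:
        raise ValueError("need at least 2 persons and 2 items")

    rows, cols = np.nonzero(obs)
    n_obs = rows.size
    # design: lnRT = tau_j - gamma_i  ->  columns [tau (J) | gamma (I)]
    data = np.concatenate([np.ones(n_obs), -np.ones(n_obs)])
    rind = np.concatenate([np.arange(n_obs), np.arange(n_obs)])
    cind = np.concatenate([rows, n_persons + cols])
    A = coo_matrix((data, (rind, cind)), shape=(n_obs, n_persons + n_items)).tocsr()
    y = values[obs]
    sol = lsqr(A, y, atol=1e-12, btol=1e-12, iter_lim=10_000)[0]
    tau = sol[:n_persons]
    gamma = sol[n_persons:]
    shift = gamma.mean()
    gamma = gamma - shift
    tau = tau - shift

    resid = values - (tau[:, None] - gamma[None, :])
    sigma2 = float(np.nanmean(resid[obs] ** 2)) if n_obs else 0.0
    return LognormalRTParams(speed=tau, time_intensity=gamma, residual_variance=sigma2)


def residuals(
    lnrt: LogRTMatrix | np.ndarray, params: LognormalRTParams
) -> ResidualMatrix:
    """e_ij = lnRT_ij − tau_j + gamma_i, plus the standardized version.

    Standardization divides by the construct-driven-state residual SD when
    the parameters carry two state variances, else by the single SD.
    """
    values = lnrt.values if isinstance(lnrt, LogRTMatrix) else np.asarray(lnrt, float)
    tau = np.asarray(params.speed, float)
    gamma = np.asarray(params.time_intensity, float)
    if values.shape != (tau.size, gamma.size):
        raise ValueError(
            f"shape mismatch: lnrt {values.shape} vs params ({tau.size}, {gamma.size})"
        )
    e = values - (tau[:, None] - gamma[None, :])
    sd = params.base_sd
    std = e / sd if sd > 0 else np.where(e == 0, 0.0, np.inf * np.sign(e))
    return ResidualMatrix(values=e, standardized=std)
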