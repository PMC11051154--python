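"""Joint accuracy + response-time model with latent response-style states.

Each response is emitted from one of two latent states: a construct-driven
state, in which accuracy follows a Rasch model and log RTs scatter tightly
(residual variance sigma2_1) around the person-speed minus item-intensity
expectation, and an erratic state with its own ability/difficulty parameters
and a much larger residual variance sigma2_2.  Two transition structures are
supported:

* **Markov** — the state at item i depends only on the state at item i−1
  (lag-1), with a time-homogeneous 2 × 2 transition matrix and Dirichlet(1,1)
  priors on the initial and transition rows.  States are drawn by per-person
  forward filtering / backward sampling.
* **Change point** — each person occupies state 1 through item k_j and
  state 2 after it (k_j = n_items means no transition), with a uniform prior
  on k_j; k_j is drawn from its enumerated discrete full conditional.  In
  ``residual`` mode the states switch the residual variance; in ``speed``
  mode they switch the person-speed parameter at a single variance.

Estimation is MCMC: conjugate Gibbs updates for speed, time intensity,
residual precisions and transition probabilities; random-walk
Metropolis-within-Gibbs for the logistic ability/difficulty parameters.
Identification: item difficulties are centered within state, time
intensities centered overall, and (Markov structure) sigma2_1 < sigma2_2 is
enforced per draw by relabeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import log_expit

from .data_model import TestDataset, log_transform

__all__ = [
    "GibbsConfig",
    "StateMatrix",
    "TransitionModel",
    "ChangePointParams",
    "JointModelPosterior",
    "gibbs_fit_markov",
    "gibbs_fit_changepoint",
    "stationary_distribution",
    "occupancy_curve",
    "convergence_diagnostics",
    "characterize_states",
]

_LN_2PI = float(np.log(2 * np.pi))


@dataclass
class GibbsConfig:
    """Sampler settings. Defaults are the full-scale protocol (2 chains,
    10,000 burn-in + 10,000 kept); pass reduced values for desk-scale runs."""

    n_chains: int = 2
    burn_in: int = 10_000
    n_iter: int = 10_000
    seed: int = 0
    prior_var: float = 100.0  # normal prior variance for theta, beta, tau, gamma
    precision_shape: float = 0.001  # gamma prior on RT residual precisions
    precision_rate: float = 0.001
    mh_step: float = 0.5  # random-walk proposal SD for theta/beta
    max_state_samples: int = 200  # thinned state matrices kept per chain
    rhat_threshold: float = 1.1


@dataclass(frozen=True)
class StateMatrix:
    """Person × item state labels, 1 = construct-driven, 2 = erratic."""

    states: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.states)
        if not np.isin(s, (1, 2)).all():
            raise ValueError("states must be 1 or 2")
        object.__setattr__(self, "states", s.astype(int))


@dataclass(frozen=True)
class TransitionModel:
    initial_probs: np.ndarray  # (p_state1, p_state2) at the first item
    transition_matrix: np.ndarray  # 2x2 row-stochastic

    def __post_init__(self):
        P = np.asarray(self.transition_matrix, float)
        if P.shape != (2, 2) or not np.allclose(P.sum(axis=1), 1.0) or (P < 0).any():
            raise ValueError("transition_matrix must be 2x2 row-stochastic")
        object.__setattr__(self, "transition_matrix", P)
        object.__setattr__(self, "initial_probs", np.asarray(self.initial_probs, float))


@dataclass(frozen=True)
class ChangePointParams:
    k: np.ndarray  # per-person change point in 1..n_items (n_items = none)
    mode: str  # residual | speed


@dataclass
class JointModelPosterior:
    """MCMC draws and summaries of the joint state model."""

    structure: str  # markov | cp-residual | cp-speed
    draws: dict = field(repr=False)  # name -> array with leading (chain, draw)
    state_mean: np.ndarray  # (n_persons, n_items) posterior P(erratic)
    state_samples: np.ndarray = field(repr=False)  # thinned (m, n, I) in {1,2}
    correct_by_state: np.ndarray  # (chain, draw, 2) proportion correct per state
    diagnostics: pd.DataFrame
    converged: bool
    config: GibbsConfig
    n_persons: int
    n_items: int

    def eap(self, name: str) -> np.ndarray:
        """Posterior mean over chains and draws."""
        return self.draws[name].mean(axis=(0, 1))

    def credible_interval(self, name: str, prob: float = 0.95) -> np.ndarray:
        lo = (1 - prob) / 2
        return np.quantile(self.draws[name], [lo, 1 - lo], axis=(0, 1))

    def modal_states(self) -> StateMatrix:
        return StateMatrix(states=np.where(self.state_mean > 0.5, 2, 1))

    @property
    def mean_deviance(self) -> float:
        return float(self.draws["deviance"].mean())

    def transition_model(self) -> TransitionModel:
        if self.structure != "markov":
            raise ValueError("transition model only defined for the Markov structure")
        return TransitionModel(
            initial_probs=self.eap("initial"),
            transition_matrix=_normalize_rows(self.eap("transition")),
        )

    def changepoint_params(self) -> ChangePointParams:
        if not self.structure.startswith("cp-"):
            raise ValueError("change points only defined for change-point structures")
        k_draws = self.draws["k"]  # (chain, draw, n)
        flat = k_draws.reshape(-1, k_draws.shape[-1]).astype(int)
        modes = np.empty(flat.shape[1], dtype=int)
        for j in range(flat.shape[1]):
            modes[j] = np.bincount(flat[:, j], minlength=self.n_items + 1).argmax()
        return ChangePointParams(k=modes, mode=self.structure.split("-", 1)[1])


def _normalize_rows(P):
    return P / P.sum(axis=1, keepdims=True)


def _bernoulli_loglik(x, eta, obs):
    """log p(x | logistic(eta)) with missing cells contributing 0."""
    ll = np.where(x == 1, log_expit(eta), log_expit(-eta))
    return np.where(obs, ll, 0.0)


class _Sampler:
    """One-chain Gibbs sampler shared by the Markov and change-point models."""

    def __init__(self, dataset: TestDataset, config: GibbsConfig, structure: str,
                 rng: np.random.Generator):
        self.cfg = config
        self.structure = structure
        self.rng = rng
        self.X = dataset.responses
        self.lnrt = log_transform(dataset).values
        self.obs_x = ~np.isnan(self.X)
        self.obs_rt = ~np.isnan(self.lnrt)
        self.X0 = np.nan_to_num(self.X)
        self.lnrt0 = np.nan_to_num(self.lnrt)
        self.n, self.I = self.X.shape
        if (self.obs_x.sum(axis=1) < 5).any():
            warnings.warn("some persons have <5 observed items; state estimates "
                          "for them will be prior-dominated", stacklevel=3)
        # initial values
        self.theta = np.tile(rng.normal(0, 0.5, self.n)[:, None], (1, 2))
        self.beta = np.tile(rng.normal(0, 0.5, self.I)[:, None], (1, 2))
        rowmean = np.where(self.obs_rt.sum(axis=1) > 0,
                           np.nanmean(np.where(self.obs_rt, self.lnrt, np.nan), axis=1), 0.0)
        self.tau = np.tile(rowmean[:, None], (1, 2))  # column 0 used unless cp-speed
        self.gamma = np.zeros(self.I)
        self.sigma2 = np.array([0.2, 1.0])
        self.initial = np.array([0.9, 0.1])
        self.P = np.array([[0.95, 0.05], [0.1, 0.9]])
        self.states = np.zeros((self.n, self.I), dtype=int)  # 0-based internally
        self.k = np.full(self.n, self.I, dtype=int)

    # ----- emission log-likelihoods -------------------------------------
    def _emissions(self) -> np.ndarray:
        """(n, I, 2) per-cell log-likelihood under each state."""
        L = np.zeros((self.n, self.I, 2))
        for s in range(2):
            eta = self.theta[:, s][:, None] - self.beta[:, s][None, :]
            L[:, :, s] += _bernoulli_loglik(self.X0, eta, self.obs_x)
            mu = self._rt_mean(s)
            var = self._rt_var(s)
            rt_ll = -0.5 * (_LN_2PI + np.log(var) + (self.lnrt0 - mu) ** 2 / var)
            L[:, :, s] += np.where(self.obs_rt, rt_ll, 0.0)
        return L

    def _rt_mean(self, s: int) -> np.ndarray:
        t = self.tau[:, s] if self.structure == "cp-speed" else self.tau[:, 0]
        return t[:, None] - self.gamma[None, :]

    def _rt_var(self, s: int) -> float:
        return self.sigma2[0] if self.structure == "cp-speed" else self.sigma2[s]

    # ----- state updates -------------------------------------------------
    def _sample_states_markov(self):
        L = self._emissions()
        e = np.exp(L - L.max(axis=2, keepdims=True))
        alpha = np.empty((self.n, self.I, 2))
        a = self.initial[None, :] * e[:, 0, :]
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, 0] = a
        for t in range(1, self.I):
            a = (a @ self.P) * e[:, t, :]
            a /= a.sum(axis=1, keepdims=True)
            alpha[:, t] = a
        # backward sampling
        u = self.rng.random((self.n, self.I))
        s = (u[:, -1] < alpha[:, -1, 1]).astype(int)
        self.states[:, -1] = s
        for t in range(self.I - 2, -1, -1):
            w = alpha[:, t, :] * self.P[:, s].T  # (n, 2)
            p2 = w[:, 1] / w.sum(axis=1)
            s = (u[:, t] < p2).astype(int)
            self.states[:, t] = s

    def _sample_states_cp(self):
        L = self._emissions()
        c1 = np.concatenate(
            [np.zeros((self.n, 1)), np.cumsum(L[:, :, 0], axis=1)], axis=1
        )  # c1[:, k] = sum of state-1 lls over items 1..k
        c2 = np.concatenate(
            [np.zeros((self.n, 1)), np.cumsum(L[:, :, 1], axis=1)], axis=1
        )
        tot2 = c2[:, -1][:, None]
        ll_k = c1[:, 1:] + (tot2 - c2[:, 1:])  # k = 1..I, uniform prior
        g = self.rng.gumbel(size=ll_k.shape)
        self.k = 1 + np.argmax(ll_k + g, axis=1)
        pos = np.arange(1, self.I + 1)
        self.states = (pos[None, :] > self.k[:, None]).astype(int)

    def _update_transition(self):
        first = self.states[:, 0]
        n2 = int(first.sum())
        self.initial = self.rng.dirichlet([1 + (self.n - n2), 1 + n2])
        a = self.states[:, :-1].ravel()
        b = self.states[:, 1:].ravel()
        counts = np.bincount(2 * a + b, minlength=4).reshape(2, 2)
        self.P = np.vstack([self.rng.dirichlet(1 + counts[r]) for r in range(2)])

    # ----- conjugate RT updates ------------------------------------------
    def _cell_precisions(self) -> np.ndarray:
        if self.structure == "cp-speed":
            return np.where(self.obs_rt, 1.0 / self.sigma2[0], 0.0)
        var = np.where(self.states == 1, self.sigma2[1], self.sigma2[0])
        return np.where(self.obs_rt, 1.0 / var, 0.0)

    def _update_tau(self):
        w = self._cell_precisions()
        v0 = self.cfg.prior_var
        target = self.lnrt0 + self.gamma[None, :]
        if self.structure == "cp-speed":
            for s in range(2):
                in_s = (self.states == s).astype(float)
                prec = (w * in_s).sum(axis=1) + 1.0 / v0
                mean = (w * in_s * target).sum(axis=1) / prec
                self.tau[:, s] = self.rng.normal(mean, 1.0 / np.sqrt(prec))
        else:
            prec = w.sum(axis=1) + 1.0 / v0
            mean = (w * target).sum(axis=1) / prec
            self.tau[:, 0] = self.rng.normal(mean, 1.0 / np.sqrt(prec))
            self.tau[:, 1] = self.tau[:, 0]

    def _tau_eff(self) -> np.ndarray:
        """(n, I) person-speed expectation per cell under the current states."""
        if self.structure == "cp-speed":
            return np.where(self.states == 1, self.tau[:, 1][:, None],
                            self.tau[:, 0][:, None])
        return np.tile(self.tau[:, 0][:, None], (1, self.I))

    def _update_gamma(self):
        w = self._cell_precisions()
        v0 = self.cfg.prior_var
        target = self._tau_eff() - self.lnrt0
        prec = w.sum(axis=0) + 1.0 / v0
        mean = (w * target).sum(axis=0) / prec
        self.gamma = self.rng.normal(mean, 1.0 / np.sqrt(prec))
        shift = self.gamma.mean()
        self.gamma -= shift
        self.tau -= shift

    def _update_sigma2(self):
        resid = self.lnrt0 - (self._tau_eff() - self.gamma[None, :])
        a0, b0 = self.cfg.precision_shape, self.cfg.precision_rate
        if self.structure == "cp-speed":
            mask = self.obs_rt
            n_s = mask.sum()
            sse = float((resid[mask] ** 2).sum())
            lam = self.rng.gamma(a0 + n_s / 2.0, 1.0 / (b0 + sse / 2.0))
            self.sigma2[:] = 1.0 / lam
        else:
            for s in range(2):
                mask = self.obs_rt & (self.states == s)
                n_s = int(mask.sum())
                sse = float((resid[mask] ** 2).sum()) if n_s else 0.0
                lam = self.rng.gamma(a0 + n_s / 2.0, 1.0 / (b0 + sse / 2.0))
                self.sigma2[s] = 1.0 / lam

    # ----- Metropolis updates for logistic parameters ---------------------
    def _update_theta(self):
        v0 = self.cfg.prior_var
        for s in range(2):
            in_s = self.obs_x & (self.states == s)
            cur = self.theta[:, s]
            prop = cur + self.rng.normal(0, self.cfg.mh_step, self.n)
            ll_cur = np.where(in_s, _bernoulli_loglik(
                self.X0, cur[:, None] - self.beta[:, s][None, :], self.obs_x), 0.0
            ).sum(axis=1)
            ll_prop = np.where(in_s, _bernoulli_loglik(
                self.X0, prop[:, None] - self.beta[:, s][None, :], self.obs_x), 0.0
            ).sum(axis=1)
            logr = (ll_prop - ll_cur) - (prop**2 - cur**2) / (2 * v0)
            accept = np.log(self.rng.random(self.n)) < logr
            none_in_state = in_s.sum(axis=1) == 0
            cur = np.where(accept, prop, cur)
            if none_in_state.any():  # posterior = prior: draw exactly
                cur[none_in_state] = self.rng.normal(
                    0, np.sqrt(v0), int(none_in_state.sum())
                )
            self.theta[:, s] = cur

    def _update_beta(self):
        v0 = self.cfg.prior_var
        for s in range(2):
            in_s = self.obs_x & (self.states == s)
            cur = self.beta[:, s]
            prop = cur + self.rng.normal(0, self.cfg.mh_step, self.I)
            ll_cur = np.where(in_s, _bernoulli_loglik(
                self.X0, self.theta[:, s][:, None] - cur[None, :], self.obs_x), 0.0
            ).sum(axis=0)
            ll_prop = np.where(in_s, _bernoulli_loglik(
                self.X0, self.theta[:, s][:, None] - prop[None, :], self.obs_x), 0.0
            ).sum(axis=0)
            logr = (ll_prop - ll_cur) - (prop**2 - cur**2) / (2 * v0)
            accept = np.log(self.rng.random(self.I)) < logr
            none_in_state = in_s.sum(axis=0) == 0
            cur = np.where(accept, prop, cur)
            if none_in_state.any():
                cur[none_in_state] = self.rng.normal(
                    0, np.sqrt(v0), int(none_in_state.sum())
                )
            # identify: center difficulties within state, absorb into abilities
            shift = cur.mean()
            self.beta[:, s] = cur - shift
            self.theta[:, s] -= shift

    def _relabel_if_needed(self):
        """Markov structure: enforce sigma2_1 < sigma2_2 by swapping labels."""
        if self.structure != "markov" or self.sigma2[0] < self.sigma2[1]:
            return
        self.sigma2 = self.sigma2[::-1].copy()
        self.states = 1 - self.states
        self.theta = self.theta[:, ::-1].copy()
        self.beta = self.beta[:, ::-1].copy()
        self.initial = self.initial[::-1].copy()
        self.P = self.P[::-1, ::-1].copy()

    def _deviance(self) -> float:
        L = self._emissions()
        s = self.states
        ll = np.take_along_axis(L, s[:, :, None], axis=2)[:, :, 0].sum()
        return float(-2.0 * ll)

    # ----- main loop -------------------------------------------------------
    def run(self):
        cfg = self.cfg
        keep = cfg.n_iter
        store = {
            "theta": np.empty((keep, self.n, 2)),
            "beta": np.empty((keep, self.I, 2)),
            "tau": np.empty((keep, self.n, 2)),
            "gamma": np.empty((keep, self.I)),
            "sigma2": np.empty((keep, 2)),
            "deviance": np.empty(keep),
        }
        if self.structure == "markov":
            store["initial"] = np.empty((keep, 2))
            store["transition"] = np.empty((keep, 2, 2))
        else:
            store["k"] = np.empty((keep, self.n), dtype=np.int32)
        state_sum = np.zeros((self.n, self.I))
        correct_by_state = np.empty((keep, 2))
        thin = max(1, keep // cfg.max_state_samples)
        state_samples = []

        for it in range(cfg.burn_in + keep):
            if self.structure == "markov":
                self._sample_states_markov()
                self._update_transition()
            else:
                self._sample_states_cp()
            self._update_tau()
            self._update_gamma()
            self._update_sigma2()
            self._update_theta()
            self._update_beta()
            self._relabel_if_needed()

            j = it - cfg.burn_in
            if j < 0:
                continue
            store["theta"][j] = self.theta
            store["beta"][j] = self.beta
            store["tau"][j] = self.tau
            store["gamma"][j] = self.gamma
            store["sigma2"][j] = self.sigma2
            store["deviance"][j] = self._deviance()
            if self.structure == "markov":
                store["initial"][j] = self.initial
                store["transition"][j] = self.P
            else:
                store["k"][j] = self.k
            state_sum += self.states
            for s in range(2):
                cells = self.obs_x & (self.states == s)
                correct_by_state[j, s] = (
                    self.X0[cells].mean() if cells.any() else np.nan
                )
            if j % thin == 0 and len(state_samples) < cfg.max_state_samples:
                state_samples.append(self.states.astype(np.uint8) + 1)

        return store, state_sum / keep, correct_by_state, np.array(state_samples)


def _fit(dataset: TestDataset, config: GibbsConfig, structure: str) -> JointModelPosterior:
    config = config or GibbsConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chain_draws, state_means, cbs, samples = [], [], [], []
    for c in range(config.n_chains):
        sampler = _Sampler(dataset, config, structure, np.random.default_rng(seeds[c]))
        store, smean, corr, ssamp = sampler.run()
        chain_draws.append(store)
        state_means.append(smean)
        cbs.append(corr)
        samples.append(ssamp)
    draws = {
        name: np.stack([cd[name] for cd in chain_draws])
        for name in chain_draws[0]
    }
    state_mean = np.mean(state_means, axis=0)
    correct_by_state = np.stack(cbs)
    state_samples = np.concatenate(samples, axis=0)

    diag = _fit_diagnostics(draws, structure)
    converged = bool((diag["rhat"].dropna() <= config.rhat_threshold).all())
    post = JointModelPosterior(
        structure=structure,
        draws=draws,
        state_mean=state_mean,
        state_samples=state_samples,
        correct_by_state=correct_by_state,
        diagnostics=diag,
        converged=converged,
        config=config,
        n_persons=dataset.n_persons,
        n_items=dataset.n_items,
    )
    if not converged:
        warnings.warn(
            f"Gelman-Rubin R-hat above {config.rhat_threshold} for some monitored "
            "parameters; treat the posterior as non-converged", stacklevel=2)
    if state_mean.mean() < 0.005:
        warnings.warn("single-state data: erratic-state occupancy is ~0", stacklevel=2)
    return post


def _fit_diagnostics(draws: dict, structure: str) -> pd.DataFrame:
    """Split-chain R-hat and ESS for the monitored (well-identified) scalars."""
    monitored: dict[str, np.ndarray] = {
        "sigma2_1": draws["sigma2"][:, :, 0],
        "sigma2_2": draws["sigma2"][:, :, 1],
        "deviance": draws["deviance"],
        "gamma_mean_abs": np.abs(draws["gamma"]).mean(axis=2),
        "tau_mean": draws["tau"][:, :, 0].mean(axis=2),
    }
    if structure == "markov":
        monitored["p11"] = draws["transition"][:, :, 0, 0]
        monitored["p22"] = draws["transition"][:, :, 1, 1]
        monitored["initial_2"] = draws["initial"][:, :, 1]
    if structure == "cp-speed":
        monitored.pop("sigma2_2")
    rows = []
    for name, arr in monitored.items():
        rows.append({
            "parameter": name,
            "rhat": _rhat(arr),
            "ess": _ess(arr),
            "lag1_autocorr": _lag_autocorr(arr, 1),
        })
    return pd.DataFrame(rows)


def _rhat(arr: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.asarray(az.rhat(az.convert_to_dataset(arr))["x"].values))


def _ess(arr: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.asarray(az.ess(az.convert_to_dataset(arr))["x"].values))


def _lag_autocorr(arr: np.ndarray, lag: int) -> float:
    vals = []
    for chain in np.atleast_2d(arr.reshape(arr.shape[0], -1)):
        c = chain - chain.mean()
        denom = float(c @ c)
        if denom == 0:
            vals.append(0.0)
        else:
            vals.append(float(c[:-lag] @ c[lag:]) / denom)
    return float(np.mean(vals))


def gibbs_fit_markov(dataset: TestDataset, config: GibbsConfig | None = None) -> JointModelPosterior:
    """Fit the lag-1 Markov-switching joint model by Gibbs sampling."""
    return _fit(dataset, config or GibbsConfig(), "markov")


def gibbs_fit_changepoint(
    dataset: TestDataset,
    config: GibbsConfig | None = None,
    mode: str = "residual",
) -> JointModelPosterior:
    """Fit the single-change-point joint model (residual or speed mode)."""
    if mode not in ("residual", "speed"):
        raise ValueError("mode must be 'residual' or 'speed'")
    return _fit(dataset, config or GibbsConfig(), f"cp-{mode}")


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Long-run state occupancy pi with pi P = pi, sum(pi) = 1."""
    P = np.asarray(transition_matrix, float)
    if P.shape != (2, 2) or not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("need a 2x2 row-stochastic matrix")
    p12, p21 = P[0, 1], P[1, 0]
    if p12 == 0 and p21 == 0:
        raise ValueError("no unique stationary distribution: chain is reducible")
    pi = np.array([p21, p12]) / (p12 + p21)
    return pi


def occupancy_curve(posterior: JointModelPosterior) -> pd.DataFrame:
    """Posterior proportion of examinees in the erratic state by item position."""
    prop = posterior.state_mean.mean(axis=0)
    return pd.DataFrame(
        {"position": np.arange(1, posterior.n_items + 1), "prop_erratic": prop}
    )


def convergence_diagnostics(chains: np.ndarray, lags: tuple = (1, 5, 10)) -> pd.DataFrame:
    """Split-chain R-hat, ESS and lag-k autocorrelations.

    ``chains`` is (n_chains, n_draws) for one parameter or
    (n_chains, n_draws, n_params).  A single chain is accepted with a
    warning (split halves stand in for between-chain comparison).
    """
    arr = np.asarray(chains, float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.shape[0] < 2:
        warnings.warn("single chain: falling back to split-half R-hat", stacklevel=2)
    rows = []
    for p in range(arr.shape[2]):
        sub = arr[:, :, p]
        row = {"parameter": p, "rhat": _rhat(sub), "ess": _ess(sub)}
        for lag in lags:
            row[f"autocorr_lag{lag}"] = _lag_autocorr(sub, lag)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StateReport:
    sigma2: np.ndarray  # EAP residual variance per state
    accuracy: np.ndarray  # proportion correct per state
    disengaged_state: int | None  # 1-based label, None if indistinct
    warning: str | None


def characterize_states(posterior: JointModelPosterior,
                        variance_ratio_threshold: float = 2.0) -> StateReport:
    """Summarize the two states and identify which (if either) is disengaged.

    The disengaged state is the one with BOTH the larger residual variance
    and the lower accuracy.  If the high-variance state has the *higher*
    accuracy, the states likely reflect an engaged minority of responses
    (e.g., effortful processing of only the first few items) and an
    alternative-interpretation warning is attached instead.  Near-equal
    variances yield a 'states indistinct' warning.
    """
    sigma2 = posterior.eap("sigma2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        accuracy = np.nanmean(posterior.correct_by_state, axis=(0, 1))
    hi = int(np.argmax(sigma2))
    lo = 1 - hi
    if sigma2[hi] / max(sigma2[lo], 1e-12) < variance_ratio_threshold:
        return StateReport(sigma2=sigma2, accuracy=accuracy,
                           disengaged_state=None, warning="states indistinct")
    if accuracy[hi] < accuracy[lo]:
        return StateReport(sigma2=sigma2, accuracy=accuracy,
                           disengaged_state=hi + 1, warning=None)
    return StateReport(
        sigma2=sigma2, accuracy=accuracy, disengaged_state=None,
        warning=(
            "alternative interpretation: the high-variance state has the higher "
            "accuracy, suggesting an engaged minority of responses rather than "
            "disengagement"
        ),
    )
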