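"""Rasch and mixture-Rasch estimation with class enumeration and profiling.

The Rasch model gives the probability of a correct response as a logistic
function of (ability − difficulty).  Item difficulties are estimated by
conditional maximum likelihood (CML): conditioning on each person's raw
score removes the ability parameters from the likelihood, so the item
estimates do not depend on the ability distribution (specific objectivity).

The mixture extension posits G latent classes, each with its own item
difficulty vector; persons whose response patterns misfit one class's
difficulty ordering form another class.  We fit it by EM over class
memberships, with the within-class likelihood factored as
P(score | class) · P(pattern | score, class): the second factor is the
Rasch conditional likelihood, the first a free multinomial per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit, log_expit

from .data_model import TestDataset

__all__ = [
    "RaschParams",
    "MixtureRaschFit",
    "ClassProfile",
    "rasch_probability",
    "elementary_symmetric",
    "fit_rasch_cml",
    "fit_mixture_rasch",
    "likelihood_ratio_test",
    "profile_classes",
    "ml_abilities",
]

_BETA_BOUND = 15.0  # box for the CML optimizer; keeps exp(-beta) finite


def rasch_probability(theta, beta):
    """P(correct) = logistic(theta − beta); stable for |theta − beta| ≤ ~700."""
    theta = np.asarray(theta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(beta))):
        raise ValueError("rasch_probability requires finite inputs")
    return expit(theta - beta)


def elementary_symmetric(epsilons: np.ndarray) -> np.ndarray:
    """Elementary symmetric functions gamma_r of item easiness values.

    gamma_r is the sum over all r-subsets of products of epsilons; it is the
    normalizing constant of the Rasch conditional likelihood for raw score r.
    Computed by the usual one-item-at-a-time summation recursion, which is
    numerically stable (all terms positive).
    """
    eps = np.asarray(epsilons, dtype=float)
    if eps.ndim != 1 or eps.size == 0:
        raise ValueError("epsilons must be a non-empty 1-D vector")
    if (eps <= 0).any() or not np.all(np.isfinite(eps)):
        raise ValueError("all epsilons must be positive and finite")
    gamma = np.zeros(eps.size + 1)
    gamma[0] = 1.0
    for r, e in enumerate(eps):
        gamma[1 : r + 2] += e * gamma[0 : r + 1].copy()
    return gamma


def _esf_without(eps: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """ESF tables with each item deleted: row i is gamma(eps without item i).

    Deleted tables follow from gamma_r = gamma_r^(−i) + eps_i *
    gamma_{r−1}^(−i), solvable forward (subtraction; stable for small eps_i)
    or backward (division; stable for large eps_i).  Rows that still show
    cancellation damage (negative entries or a bad closure check) are
    recomputed exactly by the forward summation recursion.
    """
    n = eps.size
    out = np.zeros((n, n))  # row i: gamma_0..gamma_{n-1} of the n-1 remaining
    small = eps <= np.median(eps)
    large = ~small
    # forward: f_0 = 1, f_r = gamma_r - eps * f_{r-1}
    fwd = np.zeros((n, n))
    fwd[:, 0] = 1.0
    for r in range(1, n):
        fwd[:, r] = gamma[r] - eps * fwd[:, r - 1]
    # backward: b_{n-1} = gamma_n / eps, b_{r-1} = (gamma_r - b_r) / eps
    bwd = np.zeros((n, n))
    bwd[:, n - 1] = gamma[n] / eps
    for r in range(n - 1, 0, -1):
        bwd[:, r - 1] = (gamma[r] - bwd[:, r]) / eps
    out[small] = fwd[small]
    out[large] = bwd[large]
    # closure checks: positivity, backward rows recover gamma_0^(−i) = 1,
    # forward rows recover gamma_n = eps_i * gamma_{n-1}^(−i)
    bad = (out <= 0).any(axis=1)
    bad |= large & (np.abs(bwd[:, 0] - 1.0) > 1e-9)
    bad |= small & (np.abs(eps * fwd[:, n - 1] / gamma[n] - 1.0) > 1e-9)
    for i in np.flatnonzero(bad):
        out[i] = elementary_symmetric(np.delete(eps, i))
    return out


@dataclass(frozen=True)
class RaschParams:
    """Centered CML item difficulties."""

    difficulties: np.ndarray
    constraint_applied: bool = True

    def __post_init__(self):
        object.__setattr__(self, "difficulties", np.asarray(self.difficulties, float))


def _pattern_groups(responses: np.ndarray):
    """Group persons by missingness pattern; yields (obs_idx, sub_matrix, rows)."""
    obs = ~np.isnan(responses)
    keys = [tuple(np.flatnonzero(row)) for row in obs]
    groups: dict[tuple, list[int]] = {}
    for j, k in enumerate(keys):
        groups.setdefault(k, []).append(j)
    for key, rows in groups.items():
        idx = np.array(key, dtype=int)
        yield idx, responses[np.ix_(rows, idx)], np.array(rows)


def _cml_negloglik_grad(beta, responses, weights):
    """Weighted negative conditional log-likelihood and gradient.

    Extreme-score persons (0 or all correct within their observed set)
    contribute a constant and are skipped.
    """
    nll = 0.0
    grad = np.zeros_like(beta)
    for idx, sub, rows in _pattern_groups(responses):
        if idx.size == 0:
            continue
        w = weights[rows]
        scores = sub.sum(axis=1).astype(int)
        keep = (scores > 0) & (scores < idx.size)
        if not keep.any():
            continue
        sub, w, scores = sub[keep], w[keep], scores[keep]
        b = beta[idx]
        eps = np.exp(-b)
        gamma = elementary_symmetric(eps)
        loggamma = np.log(gamma)
        # -log P(pattern|score) = sum_i x_i beta_i + log gamma_r
        nll += float((w[:, None] * sub * b[None, :]).sum() + (w * loggamma[scores]).sum())
        # E[x_i | r] = eps_i * gamma_{r-1}(without i) / gamma_r
        gminus = _esf_without(eps, gamma)  # (n_sub, n_sub): gamma_0..gamma_{n-1}
        wr = np.bincount(scores, weights=w, minlength=idx.size + 1)
        contrib = np.zeros(idx.size)
        for r in np.flatnonzero(wr):
            if r == 0:
                continue
            contrib += wr[r] * eps * gminus[:, r - 1] / gamma[r]
        xw = (w[:, None] * sub).sum(axis=0)
        # d(nll)/d(beta_i) = sum_j w_j (x_ij - E[x_ij | r_j])  [note d eps/d beta = -eps]
        grad[idx] += xw - contrib
    return nll, grad


def fit_rasch_cml(
    responses: np.ndarray | TestDataset,
    weights: np.ndarray | None = None,
    tol: float = 1e-6,
    x0: np.ndarray | None = None,
) -> RaschParams:
    """Conditional maximum-likelihood Rasch difficulties, centered to mean 0.

    Persons with extreme raw scores carry no information about the
    difficulties and are ignored; every item must show both a correct and an
    incorrect response among the remaining persons.
    """
    if isinstance(responses, TestDataset):
        responses = responses.responses
    X = np.asarray(responses, dtype=float)
    if X.ndim != 2:
        raise ValueError("responses must be 2-D")
    n_persons, n_items = X.shape
    if weights is None:
        weights = np.ones(n_persons)
    weights = np.asarray(weights, dtype=float)

    obs = ~np.isnan(X)
    scores = np.nansum(X, axis=1)
    nobs = obs.sum(axis=1)
    informative = (scores > 0) & (scores < nobs)
    if not informative.any():
        raise ValueError("no persons with non-extreme raw scores; CML is undefined")
    Xi = X[informative]
    wi = weights[informative]
    for i in range(n_items):
        col = Xi[:, i]
        seen = ~np.isnan(col)
        wcol = wi[seen]
        if not seen.any():
            raise ValueError(f"item column {i} has no observations")
        ncorrect = float((col[seen] * wcol).sum())
        total = float(wcol.sum())
        if ncorrect <= 0 or ncorrect >= total:
            raise ValueError(
                f"item column {i} is perfectly separated (all correct or all "
                "incorrect among non-extreme persons); CML estimate diverges"
            )

    # The conditional likelihood is invariant to a constant shift of beta, so
    # the full parametrization is singular along the all-ones direction.  A
    # quadratic penalty on sum(beta) removes that null direction exactly: the
    # likelihood term depends only on the centered part, so the joint
    # minimizer is (centered CML estimate, mean 0) and the penalty is zero at
    # the solution.
    c = max(float(wi.sum()), 1.0) / n_items

    def fun(beta):
        nll, grad = _cml_negloglik_grad(beta, Xi, wi)
        s = beta.sum()
        return nll + 0.5 * c * s * s, grad + c * s

    start = np.zeros(n_items)
    if x0 is not None:
        x0 = np.asarray(x0, float)
        start = np.clip(x0 - x0.mean(), -_BETA_BOUND + 1, _BETA_BOUND - 1)
    x = start
    res = None
    for attempt in range(4):
        res = optimize.minimize(
            fun,
            x0=x,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-_BETA_BOUND, _BETA_BOUND)] * n_items,
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
        )
        if res.success or np.max(np.abs(res.jac)) <= 1e-3:
            break
        # aborted line search: restart from the best point with fresh curvature
        x = res.x
    beta = res.x - res.x.mean()
    if not res.success and np.max(np.abs(res.jac)) > 1e-3:
        raise RuntimeError(f"CML optimization failed to converge: {res.message}")
    return RaschParams(difficulties=beta)


def _conditional_pattern_loglik(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """log P(pattern | raw score) per person under difficulties beta.

    Requires a complete matrix. Extreme-score patterns have probability 1.
    """
    scores = X.sum(axis=1).astype(int)
    eps = np.exp(-beta)
    loggamma = np.log(elementary_symmetric(eps))
    return -(X @ beta) - loggamma[scores]


def ml_abilities(
    responses: np.ndarray,
    difficulties: np.ndarray,
    extreme_adjust: float = 0.3,
):
    """Per-person ML ability and SE given fixed difficulties.

    Solves sum_i P_i(theta) = r for theta over each person's observed items;
    extreme raw scores are pulled in by ``extreme_adjust`` score points so
    every person gets a finite estimate. SE = 1/sqrt(test information).
    """
    X = np.asarray(responses, dtype=float)
    beta = np.asarray(difficulties, dtype=float)
    n_persons = X.shape[0]
    theta = np.full(n_persons, np.nan)
    se = np.full(n_persons, np.nan)
    for j in range(n_persons):
        seen = ~np.isnan(X[j])
        if not seen.any():
            continue
        b = beta[seen]
        r = float(np.nansum(X[j]))
        n = int(seen.sum())
        r = max(min(r, n - extreme_adjust), extreme_adjust)

        def score_eq(t, b=b, r=r):
            return expit(t - b).sum() - r

        theta[j] = optimize.brentq(score_eq, -40, 40, xtol=1e-10)
        p = expit(theta[j] - b)
        se[j] = 1.0 / np.sqrt(np.sum(p * (1 - p)))
    return theta, se


def _person_fit_z(X: np.ndarray, theta: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Standardized log-likelihood person-fit index (negative = misfit)."""
    p = expit(theta[:, None] - beta[None, :])
    p = np.clip(p, 1e-12, 1 - 1e-12)
    obs = ~np.isnan(X)
    ll = np.where(obs, np.where(X == 1, np.log(p), np.log1p(-p)), 0.0).sum(axis=1)
    logit = np.log(p / (1 - p))
    mean = np.where(obs, p * np.log(p) + (1 - p) * np.log1p(-p), 0.0).sum(axis=1)
    var = np.where(obs, p * (1 - p) * logit**2, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (ll - mean) / np.sqrt(var)


@dataclass
class MixtureRaschFit:
    """Fitted G-class mixture Rasch model."""

    n_classes: int
    class_weights: np.ndarray
    difficulties_by_class: np.ndarray  # (G, n_items), each row centered
    memberships: np.ndarray  # (n_persons, G), rows sum to 1
    hard_assignments: np.ndarray  # argmax labels in 0..G-1
    abilities: np.ndarray  # ML ability within assigned class
    ability_se: np.ndarray
    minus2_loglik: float
    n_params: int
    person_fit: np.ndarray
    score_probs: np.ndarray = field(repr=False, default=None)  # (G, n_items+1)
    loglik_path: np.ndarray = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return self.minus2_loglik + 2 * self.n_params


def _mixture_loglik_members(X, scores, beta_by_class, log_score_probs, log_weights):
    """Observed-data log-lik and posterior memberships for current params."""
    G = beta_by_class.shape[0]
    n = X.shape[0]
    logL = np.empty((n, G))
    for g in range(G):
        logL[:, g] = (
            log_weights[g]
            + log_score_probs[g, scores]
            + _conditional_pattern_loglik(X, beta_by_class[g])
        )
    m = logL.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(logL - m).sum(axis=1))
    members = np.exp(logL - lse[:, None])
    return float(lse.sum()), members


def fit_mixture_rasch(
    dataset: TestDataset | np.ndarray,
    n_classes: int,
    n_starts: int = 20,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> MixtureRaschFit:
    """EM fit of the G-class mixture Rasch model.

    Each class has its own centered difficulty vector and its own raw-score
    distribution; class weights are free.  The best of ``n_starts`` random
    initializations (soft memberships from a symmetric Dirichlet) is kept.
    The parameter count charges n_items − 1 difficulties and 2 effective
    score-distribution parameters per class, plus G − 1 mixing weights.
    """
    X = dataset.responses if isinstance(dataset, TestDataset) else np.asarray(dataset, float)
    if np.isnan(X).any():
        raise ValueError(
            "fit_mixture_rasch requires a complete response matrix; trim-induced "
            "missingness is handled downstream by EAP rescoring, not here"
        )
    n_persons, n_items = X.shape
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    scores = X.sum(axis=1).astype(int)
    rng = np.random.default_rng(seed)
    G = n_classes

    best = None
    n_degenerate = 0
    for start in range(max(n_starts, 1)):
        if G == 1:
            members = np.ones((n_persons, 1))
        else:
            members = rng.dirichlet(np.ones(G), size=n_persons)
        beta_by_class = np.zeros((G, n_items))
        loglik_path = []
        prev_ll = -np.inf
        degenerate = False
        for _ in range(max_iter):
            # M-step
            wsum = members.sum(axis=0)
            if (wsum < 1.0) .any():
                degenerate = True
                break
            weights = wsum / n_persons
            score_probs = np.zeros((G, n_items + 1))
            for g in range(G):
                score_probs[g] = np.bincount(
                    scores, weights=members[:, g], minlength=n_items + 1
                ) / wsum[g]
                beta_by_class[g] = fit_rasch_cml(
                    X, weights=members[:, g], x0=beta_by_class[g]
                ).difficulties
            with np.errstate(divide="ignore"):
                lsp = np.log(score_probs)
                lw = np.log(weights)
            # E-step
            ll, members = _mixture_loglik_members(X, scores, beta_by_class, lsp, lw)
            loglik_path.append(ll)
            if ll - prev_ll < tol * max(1.0, abs(ll)) and len(loglik_path) > 1:
                prev_ll = ll
                break
            prev_ll = ll
        if degenerate:
            n_degenerate += 1
            continue
        if best is None or prev_ll > best["ll"]:
            best = {
                "ll": prev_ll,
                "beta": beta_by_class.copy(),
                "weights": weights.copy(),
                "score_probs": score_probs.copy(),
                "members": members.copy(),
                "path": np.array(loglik_path),
            }
        if G == 1:
            break  # all starts identical
    if best is None:
        raise RuntimeError(
            f"all {n_starts} EM starts degenerated (a class weight collapsed to 0)"
        )

    # reorder classes by descending weight for reporting stability
    order = np.argsort(-best["weights"])
    weights = best["weights"][order]
    beta_by_class = best["beta"][order]
    score_probs = best["score_probs"][order]
    members = best["members"][:, order]
    hard = members.argmax(axis=1)

    counts = np.bincount(hard, minlength=G)
    if (counts < 10).any():
        warnings.warn(
            f"smallest class has {counts.min()} persons (<10); "
            "interpret class-specific estimates cautiously",
            stacklevel=2,
        )

    abilities = np.full(n_persons, np.nan)
    ability_se = np.full(n_persons, np.nan)
    person_fit = np.full(n_persons, np.nan)
    for g in range(G):
        sel = hard == g
        if not sel.any():
            continue
        th, se = ml_abilities(X[sel], beta_by_class[g])
        abilities[sel] = th
        ability_se[sel] = se
        person_fit[sel] = _person_fit_z(X[sel], th, beta_by_class[g])

    n_params = G * (n_items - 1) + (G - 1) + 2 * G
    return MixtureRaschFit(
        n_classes=G,
        class_weights=weights,
        difficulties_by_class=beta_by_class,
        memberships=members,
        hard_assignments=hard,
        abilities=abilities,
        ability_se=ability_se,
        minus2_loglik=-2.0 * best["ll"],
        n_params=n_params,
        person_fit=person_fit,
        score_probs=score_probs,
        loglik_path=best["path"],
    )


def likelihood_ratio_test(fit_small: MixtureRaschFit, fit_large: MixtureRaschFit):
    """Chi-square LR test between nested class solutions.

    The p-value is approximate: mixture boundary hypotheses violate the
    regularity conditions of the chi-square reference distribution. The
    returned tuple carries an ``approximate`` flag to that effect.
    """
    if fit_small.n_classes >= fit_large.n_classes:
        raise ValueError("fit_small must have fewer classes than fit_large")
    statistic = fit_small.minus2_loglik - fit_large.minus2_loglik
    if statistic < -1e-8:
        raise ValueError(
            "negative LR statistic: fits are non-nested or the larger model "
            "did not converge to at least the smaller model's likelihood"
        )
    statistic = max(statistic, 0.0)
    df = fit_large.n_params - fit_small.n_params
    p_value = float(stats.chi2.sf(statistic, df))
    return LRTestResult(statistic=statistic, df=df, p_value=p_value, approximate=True)


@dataclass(frozen=True)
class LRTestResult:
    statistic: float
    df: int
    p_value: float
    approximate: bool = True


@dataclass
class ClassProfile:
    """Per-class person descriptives and item-level cognitive-model regressions."""

    person_summary: pd.DataFrame  # class × (trait mean/SD, mean lnRT, criterion, correlations)
    item_regressions: pd.DataFrame  # class × response variable rows


def _standardized_ols(y: np.ndarray, X: pd.DataFrame):
    """OLS on z-scored response and predictors; returns (betas, R, fitted_model)."""
    ys = (y - y.mean()) / y.std(ddof=1)
    Xs = (X - X.mean()) / X.std(ddof=1)
    if Xs.isna().any().any() or not np.isfinite(Xs.to_numpy()).all():
        return None
    model = sm.OLS(ys, sm.add_constant(Xs)).fit()
    return model


def profile_classes(
    fit: MixtureRaschFit,
    dataset: TestDataset,
    criterion_column: str = "criterion",
) -> ClassProfile:
    """Class/item profiling: descriptives, correlations, cognitive-model OLS.

    For each class: trait mean/SD, person mean lnRT, criterion mean/SD, and
    within-class Pearson correlations of trait with mean lnRT and criterion.
    At the item level, class difficulties and within-class item mean lnRT are
    regressed on (memory_load, unique_elements), then position is added and
    the R-change F test reported.
    """
    if dataset.item_covariates is None:
        raise ValueError("profile_classes requires item covariates")
    lnrt = np.log(dataset.response_times)
    person_lnrt = np.nanmean(lnrt, axis=1)
    try:
        criterion = dataset.criterion(criterion_column)
    except Exception:
        criterion = None

    person_rows = []
    item_rows = []
    cov = dataset.item_covariates.loc[dataset.item_ids]
    base_cols = ["memory_load", "unique_elements"]
    for g in range(fit.n_classes):
        sel = fit.hard_assignments == g
        theta = fit.abilities[sel]
        mlnrt = person_lnrt[sel]
        row = {
            "class": g + 1,
            "n": int(sel.sum()),
            "weight": fit.class_weights[g],
            "trait_mean": np.nanmean(theta),
            "trait_sd": np.nanstd(theta, ddof=1),
            "mean_lnrt": np.nanmean(mlnrt),
            "mean_lnrt_sd": np.nanstd(mlnrt, ddof=1),
            "r_trait_lnrt": _safe_corr(theta, mlnrt),
        }
        if criterion is not None:
            crit = criterion[sel]
            row.update(
                criterion_mean=np.nanmean(crit),
                criterion_sd=np.nanstd(crit, ddof=1),
                r_trait_criterion=_safe_corr(theta, crit),
            )
        person_rows.append(row)

        item_lnrt = np.nanmean(lnrt[sel], axis=0)
        for name, yvec in (
            ("difficulty", fit.difficulties_by_class[g]),
            ("mean_lnrt", item_lnrt),
        ):
            rec = {
                "class": g + 1,
                "response": name,
                "mean": float(np.mean(yvec)),
                "sd": float(np.std(yvec, ddof=1)),
                "r_lnrt": _safe_corr(yvec, item_lnrt),
            }
            Xb = cov[base_cols].astype(float)
            mb = _standardized_ols(yvec, Xb)
            if mb is None:
                rec.update(beta_memory_load=np.nan, beta_unique_elements=np.nan,
                           R=np.nan, R_with_position=np.nan,
                           position_F=np.nan, position_p=np.nan)
            else:
                rec["beta_memory_load"] = mb.params.get("memory_load", np.nan)
                rec["beta_unique_elements"] = mb.params.get("unique_elements", np.nan)
                rec["R"] = np.sqrt(max(mb.rsquared, 0.0))
                Xf = cov[base_cols + ["position"]].astype(float)
                mf = _standardized_ols(yvec, Xf)
                if mf is None:
                    rec.update(R_with_position=np.nan, position_F=np.nan, position_p=np.nan)
                else:
                    rec["R_with_position"] = np.sqrt(max(mf.rsquared, 0.0))
                    n_items = len(yvec)
                    q = 1
                    dfden = n_items - Xf.shape[1] - 1
                    num = (mf.rsquared - mb.rsquared) / q
                    den = (1 - mf.rsquared) / dfden
                    F = num / den if den > 0 else np.inf
                    rec["position_F"] = F
                    rec["position_p"] = float(stats.f.sf(F, q, dfden))
            item_rows.append(rec)

    return ClassProfile(
        person_summary=pd.DataFrame(person_rows),
        item_regressions=pd.DataFrame(item_rows),
    )


def _safe_corr(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return np.nan
    return float(np.corrcoef(a[ok], b[ok])[0, 1])
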