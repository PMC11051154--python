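import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respshift import (
    MixtureRaschFit,
    elementary_symmetric,
    fit_mixture_rasch,
    fit_rasch_cml,
    likelihood_ratio_test,
    profile_classes,
    rasch_probability,
)
from respshift.rasch_mixture import _esf_without


class TestRaschProbability:
    @pytest.mark.parametrize(
        "theta,expected",
        [(0.0, 0.5), (-0.235, 0.442), (1.689, 0.844), (0.746, 0.678)],
    )
    def test_class_mean_solving_probabilities(self, theta, expected):
        # probabilities at each class's mean trait level vs difficulty 0
        assert round(float(rasch_probability(theta, 0.0)), 3) == expected

    def test_extreme_logits_stay_in_unit_interval(self):
        assert rasch_probability(700.0, 0.0) == pytest.approx(1.0)
        assert rasch_probability(-700.0, 0.0) > 0.0

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            rasch_probability(np.nan, 0.0)


def _brute_force_esf(eps):
    n = len(eps)
    out = np.zeros(n + 1)
    for r in range(n + 1):
        out[r] = sum(
            np.prod([eps[i] for i in sub]) for sub in itertools.combinations(range(n), r)
        )
    return out


class TestElementarySymmetric:
    def test_single_item(self):
        np.testing.assert_allclose(elementary_symmetric(np.array([2.5])), [1.0, 2.5])

    def test_two_items_polynomial_expansion(self):
        # (1 + e1 x)(1 + e2 x) with e = (1, 2) -> coefficients (1, 3, 2)
        np.testing.assert_allclose(elementary_symmetric(np.array([1.0, 2.0])), [1, 3, 2])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.05, max_value=20.0), min_size=2, max_size=10)
    )
    def test_matches_exhaustive_subset_enumeration(self, eps):
        eps = np.array(eps)
        np.testing.assert_allclose(
            elementary_symmetric(eps), _brute_force_esf(eps), rtol=1e-9
        )

    def test_deleted_tables_match_enumeration(self):
        rng = np.random.default_rng(7)
        eps = np.exp(-rng.normal(0, 2.0, 8))
        gamma = elementary_symmetric(eps)
        got = _esf_without(eps, gamma)
        for i in range(8):
            np.testing.assert_allclose(
                got[i], _brute_force_esf(np.delete(eps, i)), rtol=1e-8
            )

    def test_invalid_epsilons_rejected(self):
        with pytest.raises(ValueError):
            elementary_symmetric(np.array([1.0, -0.5]))


def _conditional_loglik_3items(b, X):
    """Independent oracle: explicit subset expansion for 3 items."""
    e = np.exp(-b)
    gamma = np.array([
        1.0,
        e[0] + e[1] + e[2],
        e[0] * e[1] + e[0] * e[2] + e[1] * e[2],
        e[0] * e[1] * e[2],
    ])
    scores = X.sum(axis=1).astype(int)
    keep = (scores > 0) & (scores < 3)
    return float(
        -(X[keep] @ b).sum() - np.log(gamma[scores[keep]]).sum()
    )


class TestFitRaschCML:
    def test_identical_item_columns_get_equal_difficulty(self):
        rng = np.random.default_rng(0)
        col = (rng.random(40) < 0.5).astype(float)
        other = (rng.random(40) < 0.7).astype(float)
        X = np.column_stack([col, col, other])
        fit = fit_rasch_cml(X)
        assert fit.difficulties[0] == pytest.approx(fit.difficulties[1], abs=1e-7)
        assert fit.difficulties.mean() == pytest.approx(0.0, abs=1e-10)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        true_b = np.array([-0.8, 0.2, 0.6])
        theta = rng.normal(0, 1, 20)
        X = (rng.random((20, 3)) < 1 / (1 + np.exp(-(theta[:, None] - true_b)))).astype(float)
        fit = fit_rasch_cml(X)
        # maximize the conditional likelihood directly on a fine centered grid
        grid = np.linspace(-2.5, 2.5, 251)
        best, best_ll = None, -np.inf
        for b1 in grid:
            for b2 in grid:
                b = np.array([b1, b2, -b1 - b2])
                ll = _conditional_loglik_3items(b, X)
                if ll > best_ll:
                    best_ll, best = ll, b
        np.testing.assert_allclose(fit.difficulties, best, atol=0.02)

    def test_initial_guess_translation_invariance(self):
        rng = np.random.default_rng(1)
        X = (rng.random((50, 6)) < 0.5).astype(float)
        f1 = fit_rasch_cml(X, x0=np.zeros(6))
        f2 = fit_rasch_cml(X, x0=np.full(6, 2.0))
        np.testing.assert_allclose(f1.difficulties, f2.difficulties, atol=1e-5)

    def test_perfectly_separated_item_raises(self):
        rng = np.random.default_rng(2)
        X = (rng.random((30, 3)) < 0.5).astype(float)
        X[:, 1] = 1.0
        X[0, 0] = 0.0  # keep person scores non-extreme
        with pytest.raises(ValueError, match="separated"):
            fit_rasch_cml(X)

    def test_specific_objectivity_across_person_halves(self):
        """Difficulty estimates from two random halves agree (r > .9)."""
        from respshift import SimulationConfig, simulate_mixture_rasch

        sim = simulate_mixture_rasch(
            SimulationConfig(n_persons=500, n_items=20, seed=8)
        )
        X = sim.dataset.responses
        rng = np.random.default_rng(0)
        half = rng.permutation(500) < 250
        b1 = fit_rasch_cml(X[half]).difficulties
        b2 = fit_rasch_cml(X[~half]).difficulties
        assert np.corrcoef(b1, b2)[0, 1] > 0.9


class TestMixtureRasch:
    def test_two_opposed_classes_recovered(self, two_class_sim):
        fit = fit_mixture_rasch(two_class_sim.dataset, 2, n_starts=5, seed=3)
        labels = two_class_sim.truth["class_labels"]
        agreement = max(
            (fit.hard_assignments == labels).mean(),
            (fit.hard_assignments != labels).mean(),  # label switching
        )
        assert agreement >= 0.90
        np.testing.assert_allclose(fit.memberships.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(
            fit.difficulties_by_class.mean(axis=1), 0.0, atol=1e-6
        )

    def test_em_loglik_monotone(self, two_class_sim):
        fit = fit_mixture_rasch(two_class_sim.dataset, 2, n_starts=2, seed=1)
        assert np.all(np.diff(fit.loglik_path) >= -1e-6)

    def test_single_class_reduces_to_cml(self, two_class_sim):
        X = two_class_sim.dataset.responses
        f1 = fit_mixture_rasch(X, 1, n_starts=1)
        cml = fit_rasch_cml(X)
        np.testing.assert_allclose(
            f1.difficulties_by_class[0], cml.difficulties, atol=1e-6
        )

    def test_aic_identity_and_parameter_count(self, two_class_sim):
        fit = fit_mixture_rasch(two_class_sim.dataset, 2, n_starts=2, seed=1)
        assert fit.aic == fit.minus2_loglik + 2 * fit.n_params
        # 30 items: 29 difficulties + 2 distribution params per class + G-1
        assert fit.n_params == 2 * 29 + 1 + 2 * 2

    def test_missing_data_rejected(self):
        X = np.ones((20, 5))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            fit_mixture_rasch(X, 2)


def _stub_fit(n_classes, minus2_loglik, n_params):
    n = 4
    return MixtureRaschFit(
        n_classes=n_classes,
        class_weights=np.full(n_classes, 1 / n_classes),
        difficulties_by_class=np.zeros((n_classes, 3)),
        memberships=np.full((n, n_classes), 1 / n_classes),
        hard_assignments=np.zeros(n, dtype=int),
        abilities=np.zeros(n),
        ability_se=np.ones(n),
        minus2_loglik=minus2_loglik,
        n_params=n_params,
        person_fit=np.zeros(n),
    )


class TestLikelihoodRatio:
    def test_identical_fits_give_zero(self):
        a = _stub_fit(1, 1000.0, 31)
        b = _stub_fit(2, 1000.0, 63)
        assert likelihood_ratio_test(a, b).statistic == 0.0

    def test_class_enumeration_statistics(self):
        """Chi-square improvements across 1-, 2- and 3-class solutions."""
        one = _stub_fit(1, 9664.96, 31)
        two = _stub_fit(2, 9564.86, 63)
        three = _stub_fit(3, 9506.48, 95)
        t12 = likelihood_ratio_test(one, two)
        t23 = likelihood_ratio_test(two, three)
        assert t12.statistic == pytest.approx(100.10, abs=0.01)
        assert t23.statistic == pytest.approx(58.38, abs=0.01)
        assert t12.df == t23.df == 32
        assert t12.approximate  # boundary hypothesis: chi-square is approximate

    def test_negative_statistic_rejected(self):
        a = _stub_fit(1, 900.0, 31)
        b = _stub_fit(2, 950.0, 63)
        with pytest.raises(ValueError, match="negative"):
            likelihood_ratio_test(a, b)


class TestProfileClasses:
    def test_exact_linear_difficulty_gives_unit_multiple_r(self, two_class_sim):
        ds = two_class_sim.dataset
        fit = fit_mixture_rasch(ds, 1, n_starts=1)
        # overwrite difficulties with an exact function of memory load
        ml = ds.item_covariates["memory_load"].to_numpy(float)
        beta = 0.7 * (ml - ml.mean())
        object.__setattr__(fit, "difficulties_by_class", beta[None, :])
        prof = profile_classes(fit, ds)
        row = prof.item_regressions.query("response == 'difficulty'").iloc[0]
        assert row["R"] == pytest.approx(1.0, abs=1e-10)
        assert row["R_with_position"] >= row["R"] - 1e-12

    def test_coefficients_match_normal_equations_oracle(self, two_class_sim):
        ds = two_class_sim.dataset
        fit = fit_mixture_rasch(ds, 1, n_starts=1)
        prof = profile_classes(fit, ds)
        row = prof.item_regressions.query("response == 'difficulty'").iloc[0]
        y = fit.difficulties_by_class[0]
        Xc = ds.item_covariates[["memory_load", "unique_elements"]].to_numpy(float)
        ys = (y - y.mean()) / y.std(ddof=1)
        Xs = (Xc - Xc.mean(0)) / Xc.std(0, ddof=1)
        A = np.column_stack([np.ones(len(y)), Xs])
        coef = np.linalg.solve(A.T @ A, A.T @ ys)
        assert row["beta_memory_load"] == pytest.approx(coef[1], abs=1e-8)
        assert row["beta_unique_elements"] == pytest.approx(coef[2], abs=1e-8)
        pred = A @ coef
        r2 = 1 - ((ys - pred) ** 2).sum() / (ys**2).sum()
        assert row["R"] == pytest.approx(np.sqrt(r2), abs=1e-8)

    def test_correlation_of_vector_with_itself(self):
        from respshift.rasch_mixture import _safe_corr

        v = np.array([1.0, 2.0, 5.0, 3.0])
        assert _safe_corr(v, v) == pytest.approx(1.0)
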