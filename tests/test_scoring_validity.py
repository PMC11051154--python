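import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from respshift import (
    AbilityEstimates,
    ResidualMatrix,
    TrimMask,
    ValidityReport,
    bootstrap_gain_test,
    disattenuate,
    eap_abilities,
    empirical_reliability,
    fit_lognormal_rt,
    fit_rasch_cml,
    get_scenario,
    log_transform,
    mask_from_residual_threshold,
    mask_from_states,
    residuals,
    simulate_joint,
    validity_table,
)
from respshift.scoring_validity import _masked_adjusted_r


class TestMasks:
    def test_all_construct_driven_retains_everything(self):
        mask = mask_from_states(np.ones((4, 6), dtype=int))
        assert mask.retain.all()
        assert mask.n_trimmed == 0

    def test_step_pattern_retains_up_to_changepoint(self):
        states = np.where(np.arange(1, 31) <= 16, 1, 2)[None, :]
        mask = mask_from_states(states)
        assert mask.retain.sum() == 16

    def test_retained_count_equals_state1_count(self):
        rng = np.random.default_rng(4)
        states = rng.integers(1, 3, size=(50, 30))
        mask = mask_from_states(states)
        assert mask.retain.sum() == (states == 1).sum()

    def test_unscorable_person_flagged_not_dropped(self):
        states = np.full((2, 5), 2)
        states[0] = 1
        with pytest.warns(UserWarning, match="unscorable"):
            mask = mask_from_states(states)
        assert mask.retain.shape == (2, 5)
        np.testing.assert_array_equal(mask.unscorable_persons, [1])

    def test_residual_threshold_negative_side(self):
        res = ResidualMatrix(values=np.zeros((1, 3)),
                             standardized=np.array([[-2.6, -1.0, 3.0]]))
        mask = mask_from_residual_threshold(res, -2.5, side="negative")
        np.testing.assert_array_equal(mask.retain, [[False, True, True]])

    def test_residual_threshold_both_sides(self):
        res = ResidualMatrix(values=np.zeros((1, 3)),
                             standardized=np.array([[-2.6, -1.0, 3.0]]))
        mask = mask_from_residual_threshold(res, 2.5, side="both")
        np.testing.assert_array_equal(mask.retain, [[False, True, False]])

    def test_nothing_beyond_minus_six_sd_retains_all(self):
        rng = np.random.default_rng(1)
        res = ResidualMatrix(values=np.zeros((10, 10)),
                             standardized=rng.standard_normal((10, 10)))
        mask = mask_from_residual_threshold(res, -6.0, side="negative")
        assert mask.retain.all()


class TestEAPAbilities:
    def test_symmetric_half_correct_gives_zero(self):
        beta = np.array([-1.0, -0.5, 0.5, 1.0])
        X = np.array([[1.0, 1.0, 0.0, 0.0]])
        est = eap_abilities(X, beta)
        assert est.eap[0] == pytest.approx(0.0, abs=1e-10)

    def test_all_correct_is_finite_and_shrunk(self):
        beta = np.zeros(20)
        X = np.ones((1, 20))
        est = eap_abilities(X, beta, prior_mean=0.0, prior_sd=1.0)
        assert 0 < est.eap[0] < 4.0

    def test_matches_fine_grid_integration(self):
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 1, 30)
        beta -= beta.mean()
        X = (rng.random((100, 30)) < 0.6).astype(float)
        est = eap_abilities(X, beta)
        grid = np.linspace(-6, 6, 10_001)
        P = expit(grid[:, None] - beta[None, :])
        ll = X @ np.log(P).T + (1 - X) @ np.log(1 - P).T
        logw = ll - 0.5 * grid[None, :] ** 2
        w = np.exp(logw - logw.max(axis=1, keepdims=True))
        oracle = (w * grid[None, :]).sum(axis=1) / w.sum(axis=1)
        assert np.abs(est.eap - oracle).max() <= 1e-4

    def test_unscorable_person_gets_nan_estimate(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0]])
        mask = TrimMask(retain=np.array([[False, False], [True, True]]))
        est = eap_abilities(X, np.zeros(2), mask)
        assert np.isnan(est.eap[0]) and not np.isnan(est.eap[1])
        assert est.n_items_used[0] == 0


class TestReliabilityAndDisattenuation:
    def test_reliability_arithmetic(self):
        # var(EAP) = 1 and mean posterior variance = 1 -> reliability 1/2
        est = AbilityEstimates(
            eap=np.array([0.0, 2.0]) / np.sqrt(2),
            posterior_sd=np.ones(2),
            n_items_used=np.full(2, 30),
        )
        assert empirical_reliability(est) == pytest.approx(0.5)

    def test_vanishing_posterior_sd_gives_perfect_reliability(self):
        est = AbilityEstimates(
            eap=np.array([-1.0, 0.0, 1.0]),
            posterior_sd=np.full(3, 1e-9),
            n_items_used=np.full(3, 30),
        )
        assert empirical_reliability(est) == pytest.approx(1.0, abs=1e-12)

    def test_reliability_close_to_squared_true_score_correlation(self):
        sim = simulate_joint(get_scenario("null_single_state"), seed=21)
        diff = fit_rasch_cml(sim.dataset.responses)
        est = eap_abilities(sim.dataset, diff)
        rel = empirical_reliability(est)
        r2 = np.corrcoef(est.eap, sim.truth["theta"])[0, 1] ** 2
        assert rel == pytest.approx(r2, abs=0.05)

    def test_zero_variance_rejected(self):
        est = AbilityEstimates(eap=np.zeros(5), posterior_sd=np.ones(5),
                               n_items_used=np.full(5, 10))
        with pytest.raises(ValueError, match="variance"):
            empirical_reliability(est)

    @pytest.mark.parametrize(
        "raw_r,rel,expected", [(0.5, 0.64, 0.625), (0.3, 1.0, 0.3)]
    )
    def test_disattenuation_arithmetic(self, raw_r, rel, expected):
        assert disattenuate(raw_r, rel) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.0, max_value=0.6),
        st.floats(min_value=0.0, max_value=0.6),
        st.floats(min_value=0.5, max_value=1.0),
        st.floats(min_value=0.5, max_value=1.0),
    )
    def test_monotone_in_r_and_antitone_in_reliability(self, r1, r2, q1, q2):
        lo_r, hi_r = sorted([r1, r2])
        lo_q, hi_q = sorted([q1, q2])
        assert disattenuate(lo_r, lo_q) <= disattenuate(hi_r, lo_q) + 1e-12
        assert disattenuate(lo_r, hi_q) <= disattenuate(lo_r, lo_q) + 1e-12

    def test_invalid_reliability_rejected(self):
        with pytest.raises(ValueError):
            disattenuate(0.5, 0.0)

    def test_variance_explained_is_exact_square(self):
        rep = ValidityReport(raw_r=0.55, reliability=0.8, adjusted_r=0.628,
                             bootstrap_p=0.02, n=301)
        assert rep.variance_explained == 0.628**2


@pytest.fixture(scope="module")
def sim():
    return simulate_joint(get_scenario("late_shift_cp"), seed=100)


@pytest.fixture(scope="module")
def difficulties(sim):
    return fit_rasch_cml(sim.dataset.responses)


class TestBootstrapGainTest:
    def test_identical_masks_are_never_significant(self, sim, difficulties):
        full = TrimMask(retain=np.ones_like(sim.dataset.responses, dtype=bool))
        p = bootstrap_gain_test(sim.dataset, full, full, sim.truth["criterion"],
                                difficulties, n_boot=100, seed=1)
        assert p >= 0.5

    def test_targeted_trim_beats_null(self, sim, difficulties):
        mask = mask_from_states(sim.truth["states"])
        full = TrimMask(retain=np.ones_like(sim.dataset.responses, dtype=bool))
        p = bootstrap_gain_test(sim.dataset, mask, full, sim.truth["criterion"],
                                difficulties, n_boot=199, seed=1)
        assert p < 0.05

    def test_p_value_reproducible_under_fixed_seed(self, sim, difficulties):
        mask = mask_from_states(sim.truth["states"])
        full = TrimMask(retain=np.ones_like(sim.dataset.responses, dtype=bool))
        args = (sim.dataset, mask, full, sim.truth["criterion"], difficulties)
        p1 = bootstrap_gain_test(*args, n_boot=100, seed=7)
        p2 = bootstrap_gain_test(*args, n_boot=100, seed=7)
        assert p1 == p2

    def test_small_n_boot_warns(self, sim, difficulties):
        full = TrimMask(retain=np.ones_like(sim.dataset.responses, dtype=bool))
        with pytest.warns(UserWarning, match="n_boot"):
            bootstrap_gain_test(sim.dataset, full, full, sim.truth["criterion"],
                                difficulties, n_boot=50, seed=1)


@pytest.fixture(scope="module")
def table_inputs(sim, difficulties):
    ds = sim.dataset
    lnrt = log_transform(ds)
    res = residuals(lnrt, fit_lognormal_rt(lnrt))
    masks = {"state_trim": mask_from_states(sim.truth["states"])}
    table = validity_table(ds, difficulties, sim.truth["criterion"], masks=masks,
                           residuals=res)
    return sim, table


class TestValidityTable:
    def test_r2_column_is_exact_square(self, table_inputs):
        _, table = table_inputs
        np.testing.assert_array_equal(table["r2"], table["adjusted_r"] ** 2)

    def test_empty_trims_match_no_trim_row(self, table_inputs):
        _, table = table_inputs
        base = table.query("trim == 'no_trim'").iloc[0]
        for name in ("residual<-6SD", "residual<-5SD"):
            row = table[table["trim"] == name].iloc[0]
            if row["n_cells_trimmed"] == 0:
                assert row["adjusted_r"] == base["adjusted_r"]

    def test_state_trim_improves_on_no_trim(self, table_inputs):
        _, table = table_inputs
        base = table.query("trim == 'no_trim'")["adjusted_r"].iloc[0]
        state = table.query("trim == 'state_trim'")["adjusted_r"].iloc[0]
        assert state >= base
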