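"""The data generator: distributional checks and structural contracts."""

import numpy as np
import pytest

from mnrmmix.mixture_spec import CANONICAL_LABELS, class_probabilities
from mnrmmix.simulator import (
    CONDITIONS,
    SimulationDesign,
    assign_classes,
    build_faking_weights,
    draw_intercepts,
    draw_item_slopes,
    draw_person_params,
    draw_regression_coefficients,
    generate_responses,
    make_true_sigma,
    simulate,
    solve_intercepts_for_proportions,
    thresholds_to_intercepts,
)
from mnrmmix.mixture_spec import LatentRegression


class TestConditionRegistry:
    def test_ten_conditions_sum_to_one(self):
        assert sorted(CONDITIONS) == list(range(1, 11))
        for props in CONDITIONS.values():
            assert sum(props) == pytest.approx(1.0)

    def test_stated_proportions(self):
        assert CONDITIONS[1] == pytest.approx((1 / 3, 1 / 3, 1 / 3))
        assert CONDITIONS[2] == (0.6, 0.2, 0.2)
        assert CONDITIONS[5] == (0.0, 0.5, 0.5)
        assert CONDITIONS[8] == (1.0, 0.0, 0.0)
        assert CONDITIONS[10] == (0.0, 0.0, 1.0)


class TestItemSlopes:
    def test_bounds(self):
        rng = np.random.default_rng(0)
        a = draw_item_slopes(rng, 30, 4).alpha
        assert a.min() >= 0.5 and a.max() <= 1.0

    def test_seeded_reproducibility(self):
        a1 = draw_item_slopes(np.random.default_rng(5), 10, 4).alpha
        a2 = draw_item_slopes(np.random.default_rng(5), 10, 4).alpha
        np.testing.assert_array_equal(a1, a2)

    def test_uniform_mean(self):
        rng = np.random.default_rng(1)
        a = draw_item_slopes(rng, 100_000, 1).alpha
        assert a.mean() == pytest.approx(0.75, abs=0.005)


class TestFakingWeights:
    def test_monotone_family(self):
        w = build_faking_weights(None, 10, 6)
        mono = w[0]
        assert mono[0] == 0.0 and mono[-1] == 6.0
        assert np.all(np.diff(mono) >= 0)

    def test_inverted_u_family(self):
        w = build_faking_weights(None, 10, 6)
        inv_u = w[2]
        peak = int(np.argmax(inv_u))
        assert 0 < peak < 6
        assert inv_u.min() == 0.0 and inv_u.max() == 6.0

    def test_all_span_zero_to_six(self):
        w = build_faking_weights(None, 9, 6)
        assert np.all(w.min(axis=1) == 0.0)
        assert np.all(w.max(axis=1) == 6.0)

    def test_balanced_round_robin(self):
        w = build_faking_weights(None, 10, 6)
        fams = [tuple(row) for row in w]
        counts = sorted([fams.count(f) for f in set(fams)])
        assert counts == [3, 3, 4]

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            build_faking_weights(None, 2, 6)


class TestIntercepts:
    def test_cumulative_sum_arithmetic(self):
        np.testing.assert_allclose(
            thresholds_to_intercepts(np.array([0.5, 1.0])), [0.0, -0.5, -1.5]
        )

    def test_zero_thresholds(self):
        np.testing.assert_array_equal(thresholds_to_intercepts(np.zeros(3)), np.zeros(4))

    def test_first_category_zero_and_concavity(self):
        rng = np.random.default_rng(2)
        g = draw_intercepts(rng, 20, 6, 3).gamma
        assert np.all(g[:, :, 0] == 0)
        # sorted thresholds make gamma concave in the category index
        second_diff = np.diff(g, n=2, axis=2)
        assert np.all(second_diff <= 1e-12)

    def test_bounds_from_uniform_thresholds(self):
        rng = np.random.default_rng(3)
        g = draw_intercepts(rng, 50, 6, 1).gamma
        assert np.all(g[:, :, 1:] >= -2 * np.arange(1, 7))
        assert np.all(g[:, :, 1:] <= 2 * np.arange(1, 7))


class TestPersonParams:
    def test_correlation_recovery(self):
        rng = np.random.default_rng(4)
        Sigma = np.eye(4)
        Sigma[0, 1] = Sigma[1, 0] = 0.3
        th = draw_person_params(rng, 100_000, Sigma).theta
        r = np.corrcoef(th.T)
        assert r[0, 1] == pytest.approx(0.3, abs=0.01)
        assert abs(r[2, 3]) < 0.01

    def test_unit_variances(self):
        rng = np.random.default_rng(5)
        th = draw_person_params(rng, 100_000, np.eye(3)).theta
        np.testing.assert_allclose(th.var(axis=0), 1.0, atol=0.02)

    def test_non_pd_rejected(self):
        bad = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(np.linalg.LinAlgError):
            draw_person_params(np.random.default_rng(0), 10, bad)

    def test_true_sigma_structure(self):
        rng = np.random.default_rng(6)
        S = make_true_sigma(rng, 3)
        np.testing.assert_array_equal(np.diag(S), np.ones(4))
        trait_pairs = sorted([S[0, 1], S[0, 2], S[1, 2]])
        assert trait_pairs == pytest.approx([-0.3, 0.0, 0.3])
        assert np.all(S[3, :3] == 0)  # faking uncorrelated with traits


class TestRegressionCoefficients:
    def test_null_and_reference_zero(self):
        rng = np.random.default_rng(7)
        reg = draw_regression_coefficients(rng, 3, ("null", "weak", "strong"), 0)
        assert np.all(reg.beta[0] == 0)  # null covariate
        assert np.all(reg.beta[:, 0] == 0)  # reference class

    def test_half_sign_flipped(self):
        rng = np.random.default_rng(8)
        reg = draw_regression_coefficients(rng, 3, ("null", "weak", "strong"), 0)
        nonzero = reg.beta[1:, 1:].ravel()
        assert (nonzero < 0).sum() == 2  # exactly half of the 4 nonzero slopes

    def test_effect_magnitudes(self):
        rng = np.random.default_rng(9)
        weak, strong = [], []
        for _ in range(200):
            reg = draw_regression_coefficients(rng, 3, ("null", "weak", "strong"), 0)
            weak.extend(np.abs(reg.beta[1, 1:]))
            strong.extend(np.abs(reg.beta[2, 1:]))
        assert np.mean(weak) == pytest.approx(1.0, abs=0.05)
        assert np.mean(strong) == pytest.approx(2.0, abs=0.05)
        assert np.all(np.abs(np.array(weak) - 1) < 1.0)  # ~5 sigma


class TestInterceptSolver:
    def test_symmetric_closed_form(self):
        reg = LatentRegression(np.zeros(3), np.zeros((3, 3)))
        out = solve_intercepts_for_proportions(np.full(3, 1 / 3), reg)
        np.testing.assert_allclose(out.beta0, 0.0, atol=1e-12)

    def test_logit_closed_form(self):
        reg = LatentRegression(np.zeros(3), np.zeros((3, 3)))
        out = solve_intercepts_for_proportions(np.array([0.25, 0.5, 0.25]), reg)
        np.testing.assert_allclose(out.beta0, [0.0, np.log(2.0), 0.0], atol=1e-12)

    def test_monte_carlo_self_consistency(self):
        rng = np.random.default_rng(10)
        reg = draw_regression_coefficients(rng, 3, ("null", "weak", "strong"), 0)
        target = np.array([0.5, 0.3, 0.2])
        solved = solve_intercepts_for_proportions(target, reg, rng)
        X = np.random.default_rng(99).standard_normal((500_000, 3))
        achieved = class_probabilities(solved, X).mean(axis=0)
        np.testing.assert_allclose(achieved, target, atol=0.005)

    def test_invalid_targets(self):
        reg = LatentRegression(np.zeros(2), np.zeros((1, 2)))
        with pytest.raises(ValueError):
            solve_intercepts_for_proportions(np.array([0.7, 0.7]), reg)
        with pytest.raises(ValueError):
            solve_intercepts_for_proportions(np.array([1.0, 0.0]), reg)


class TestClassAssignment:
    def test_degenerate_probabilities(self):
        reg = LatentRegression(np.array([0.0, -40.0, -40.0]), np.zeros((1, 3)))
        state = assign_classes(np.random.default_rng(0), reg, np.zeros((200, 1)))
        assert np.all(state.zeta == 0)

    def test_law_of_large_numbers(self):
        reg = LatentRegression(np.array([0.0, np.log(2.0), 0.0]), np.zeros((1, 3)))
        X = np.random.default_rng(1).standard_normal((40_000, 1))
        # beta has 1 row here; pad to match X columns
        reg = LatentRegression(reg.beta0, np.zeros((1, 3)))
        state = assign_classes(np.random.default_rng(2), reg, X)
        freqs = np.bincount(state.zeta, minlength=3) / len(state.zeta)
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.01)


class TestResponses:
    def test_category_range_and_determinism(self):
        d = SimulationDesign(items_per_trait=5, n_persons=100, condition=1, seed=11)
        s1, s2 = simulate(d), simulate(d)
        assert s1.responses.values.min() >= 0 and s1.responses.values.max() <= 6
        np.testing.assert_array_equal(s1.responses.values, s2.responses.values)
        d2 = SimulationDesign(items_per_trait=5, n_persons=100, condition=1, seed=12)
        assert not np.array_equal(simulate(d2).responses.values, s1.responses.values)

    def test_flat_parameters_give_uniform_categories(self):
        d = SimulationDesign(items_per_trait=4, n_persons=3000, condition=8, seed=13)
        sim = simulate(d)
        t = sim.truth
        t.alpha[:] = 0.0
        t.gamma[:] = 0.0
        resp = generate_responses(np.random.default_rng(0), t)
        freqs = np.bincount(resp.values.ravel(), minlength=7) / resp.values.size
        np.testing.assert_allclose(freqs, 1 / 7, atol=0.01)

    def test_extreme_faker_hits_most_desirable_categories(self):
        d = SimulationDesign(items_per_trait=3, n_persons=50, condition=10, seed=14)
        sim = simulate(d)
        t = sim.truth
        t.theta[:, 3] = 8.0  # huge faking score, F-only population
        resp = generate_responses(np.random.default_rng(1), t)
        fw = t.weights.faking_rows
        peaks = fw.argmax(axis=1)
        match = (resp.values == peaks[None, :]).mean()
        assert match > 0.8

    def test_absent_classes_have_no_members(self):
        for cond in (5, 6, 7):
            d = SimulationDesign(items_per_trait=3, n_persons=400, condition=cond, seed=cond)
            sim = simulate(d)
            absent = int(np.flatnonzero(np.array(CONDITIONS[cond]) == 0.0)[0])
            assert not np.any(sim.truth.zeta == absent)

    def test_realized_proportions_near_target(self):
        d = SimulationDesign(items_per_trait=3, n_persons=4000, condition=2, seed=15)
        sim = simulate(d)
        freqs = np.bincount(sim.truth.zeta, minlength=3) / d.n_persons
        np.testing.assert_allclose(freqs, [0.6, 0.2, 0.2], atol=0.03)
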