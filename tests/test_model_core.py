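"""Probability machinery: closed-form softmax oracles and enumeration checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnrmmix.model_core import (
    MISSING,
    ModelParams,
    ResponseMatrix,
    ScoringWeights,
    category_logit,
    class_conditional_prob,
    log_likelihood,
    mixture_prob,
    person_class_loglik,
)


def _one_item_params(alpha, s_rows, gamma_rows, theta, masks):
    """Single-item ModelParams with D = number of scoring rows (last = faking)."""
    S = np.asarray(s_rows, dtype=float)[None, :, :]  # (1, D, K+1)
    weights = ScoringWeights(S, n_traits=S.shape[1] - 1)
    return ModelParams(
        weights=weights,
        alpha=np.atleast_2d(alpha).astype(float),
        gamma=np.asarray(gamma_rows, dtype=float),
        theta=np.atleast_2d(theta).astype(float),
        masks=np.asarray(masks, dtype=float),
    )


class TestCategoryLogit:
    def test_zero_slope_gives_intercept(self):
        assert category_logit([0.0, 0.0], [1.0, 2.0], [0.5, -1.0], 0.0) == 0.0

    def test_hand_arithmetic(self):
        # 1 * 2 * 0.5 - 0.3
        assert category_logit([1.0], [2.0], [0.5], -0.3) == pytest.approx(0.7)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            category_logit([1.0, 2.0], [1.0], [0.5], 0.0)


class TestClassConditionalProb:
    def test_uniform_when_flat(self):
        p = _one_item_params(
            alpha=[0.0],
            s_rows=[[0.0, 1.0]],
            gamma_rows=[[[0.0, 0.0]]],
            theta=[0.0],
            masks=[[[1.0]]],
        )
        np.testing.assert_allclose(class_conditional_prob(0, 0, 0, p), [0.5, 0.5])

    def test_softmax_of_scoring_weights(self):
        # logits (0, 1, 2) -> softmax = (0.0900, 0.2447, 0.6652)
        p = _one_item_params(
            alpha=[1.0],
            s_rows=[[0.0, 1.0, 2.0]],
            gamma_rows=[[[0.0, 0.0, 0.0]]],
            theta=[1.0],
            masks=[[[1.0]]],
        )
        e = np.exp([0.0, 1.0, 2.0])
        np.testing.assert_allclose(class_conditional_prob(0, 0, 0, p), e / e.sum(), atol=1e-10)
        np.testing.assert_allclose(
            class_conditional_prob(0, 0, 0, p), [0.0900, 0.2447, 0.6652], atol=5e-5
        )

    def test_intercept_shift_invariance(self):
        rng = np.random.default_rng(7)
        gam = rng.normal(size=3)
        base = _one_item_params(
            alpha=[0.8],
            s_rows=[[0.0, 1.0, 2.0]],
            gamma_rows=[[gam]],
            theta=[0.4],
            masks=[[[1.0]]],
        )
        shifted = _one_item_params(
            alpha=[0.8],
            s_rows=[[0.0, 1.0, 2.0]],
            gamma_rows=[[gam + 3.7]],
            theta=[0.4],
            masks=[[[1.0]]],
        )
        np.testing.assert_allclose(
            class_conditional_prob(0, 0, 0, base),
            class_conditional_prob(0, 0, 0, shifted),
            atol=1e-12,
        )

    def test_partial_credit_equivalence(self):
        """With evenly spaced weights and one dimension, the nominal model is a
        partial credit model; an explicit cumulative-threshold oracle agrees."""
        rng = np.random.default_rng(11)
        gamma = np.concatenate([[0.0], rng.normal(size=2)])
        alpha = 1.0
        for theta in (-1.5, 0.0, 0.7, 2.0):
            p = _one_item_params(
                alpha=[alpha],
                s_rows=[[0.0, 1.0, 2.0]],
                gamma_rows=[[gamma]],
                theta=[theta],
                masks=[[[1.0]]],
            )
            ours = class_conditional_prob(0, 0, 0, p)
            # PCM oracle: logit_k = sum_{m<=k} (theta - delta_m), delta_m = gamma_{m-1} - gamma_m
            delta = gamma[:-1] - gamma[1:]
            logits = np.concatenate([[0.0], np.cumsum(theta - delta)])
            pcm = np.exp(logits) / np.exp(logits).sum()
            np.testing.assert_allclose(ours, pcm, atol=1e-10)


class TestMixtureProb:
    def _two_class_params(self):
        # class A: p0 = 0.2, class B: p0 = 0.6 (slopes zero, intercepts chosen)
        return _one_item_params(
            alpha=[0.0],
            s_rows=[[0.0, 1.0]],
            gamma_rows=[[[0.0, np.log(4.0)]], [[0.0, np.log(2.0 / 3.0)]]],
            theta=[0.0],
            masks=[[[1.0]], [[1.0]]],
        )

    def test_degenerate_mixture(self):
        p = self._two_class_params()
        np.testing.assert_allclose(
            mixture_prob(0, 0, [1.0, 0.0], p), class_conditional_prob(0, 0, 0, p)
        )

    def test_weighted_mean(self):
        p = self._two_class_params()
        out = mixture_prob(0, 0, [0.5, 0.5], p)
        assert out[0] == pytest.approx(0.4, abs=1e-10)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            mixture_prob(0, 0, [1.5, -0.5], self._two_class_params())

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_probabilities_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        K = 3
        p = _one_item_params(
            alpha=rng.uniform(0, 2, size=2),
            s_rows=rng.normal(size=(2, K + 1)),
            gamma_rows=np.concatenate(
                [np.zeros((2, 1, 1)), rng.normal(size=(2, 1, K))], axis=2
            ),
            theta=rng.normal(size=2),
            masks=rng.integers(0, 2, size=(2, 1, 2)).astype(float) + 0.0,
        )
        w = rng.dirichlet([1.0, 1.0])
        assert mixture_prob(0, 0, w, p).sum() == pytest.approx(1.0, abs=1e-10)
        for c in range(2):
            assert class_conditional_prob(0, 0, c, p).sum() == pytest.approx(1.0, abs=1e-10)


def _random_instance(rng, N=2, I=2, K=2, C=2, T=1):
    D = T + 1
    S = np.zeros((I, D, K + 1))
    S[:, 0, :] = np.arange(K + 1)
    S[:, T, :] = rng.uniform(0, 6, size=(I, K + 1))
    weights = ScoringWeights(S, n_traits=T)
    masks = np.ones((C, I, D))
    if C == 2:
        masks[1, :, T] = 0.0  # second class: trait only
    gamma = np.concatenate([np.zeros((C, I, 1)), rng.normal(size=(C, I, K))], axis=2)
    params = ModelParams(
        weights=weights,
        alpha=rng.uniform(0.5, 1.0, size=(I, D)),
        gamma=gamma,
        theta=rng.normal(size=(N, D)),
        masks=masks,
    )
    responses = ResponseMatrix(rng.integers(0, K + 1, size=(N, I)), K, np.zeros(I, dtype=int))
    return params, responses


class TestLogLikelihood:
    def test_single_flat_item(self):
        p = _one_item_params(
            alpha=[0.0],
            s_rows=[[0.0, 1.0]],
            gamma_rows=[[[0.0, 0.0]]],
            theta=[0.0],
            masks=[[[1.0]]],
        )
        resp = ResponseMatrix(np.array([[1]]), 1, np.array([0]))
        assert log_likelihood(resp, p, mode="marginal", class_probs=[1.0]) == pytest.approx(
            np.log(0.5)
        )

    def test_single_class_marginal_equals_conditional(self):
        rng = np.random.default_rng(5)
        params, resp = _random_instance(rng, C=1)
        marg = log_likelihood(resp, params, mode="marginal", class_probs=[1.0])
        cond = log_likelihood(resp, params, mode="class_conditional", zeta=0)
        assert marg == pytest.approx(cond, abs=1e-10)

    def test_enumeration_oracle(self):
        """Marginal mixture likelihood matches brute-force enumeration over
        response probabilities, person by person."""
        rng = np.random.default_rng(17)
        params, resp = _random_instance(rng, N=2, I=2, K=2, C=2)
        pi = np.array([0.3, 0.7])
        total = log_likelihood(resp, params, mode="marginal", class_probs=pi)
        brute = 0.0
        for n in range(2):
            pn = 0.0
            for c in range(2):
                prod = 1.0
                for i in range(2):
                    prod *= class_conditional_prob(i, n, c, params)[resp.values[n, i]]
                pn += pi[c] * prod
            brute += np.log(pn)
        assert total == pytest.approx(brute, abs=1e-10)

    def test_person_level_factorization(self):
        """Per-person class enumeration equals brute force over all joint
        class-assignment vectors (one zeta per person)."""
        rng = np.random.default_rng(23)
        params, resp = _random_instance(rng, N=3, I=2, K=2, C=2)
        pi = np.array([0.4, 0.6])
        total = log_likelihood(resp, params, mode="marginal", class_probs=pi)
        from itertools import product

        brute = 0.0
        for assignment in product(range(2), repeat=3):
            term = 1.0
            for n, c in enumerate(assignment):
                term *= pi[c]
                for i in range(2):
                    term *= class_conditional_prob(i, n, c, params)[resp.values[n, i]]
            brute += term
        assert total == pytest.approx(np.log(brute), abs=1e-10)

    def test_missing_responses_skipped(self):
        rng = np.random.default_rng(31)
        params, resp = _random_instance(rng, N=2, I=2, K=2, C=2)
        vals = resp.values.copy()
        vals[0, 1] = MISSING
        resp_missing = ResponseMatrix(vals, 2, resp.item_scale_map)
        L = person_class_loglik(params, resp_missing)
        # person 0's likelihood uses only item 0
        expected = np.log(
            [class_conditional_prob(0, 0, c, params)[vals[0, 0]] for c in range(2)]
        )
        np.testing.assert_allclose(L[0], expected, atol=1e-10)

    def test_out_of_range_category_rejected(self):
        with pytest.raises(ValueError):
            ResponseMatrix(np.array([[7]]), 6, np.array([0]))
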