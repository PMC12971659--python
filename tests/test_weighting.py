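"""Objective weighting methods and Bonferroni fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oshprior import (
    DecisionProblem,
    WeightVector,
    bonferroni_fuse,
    cilos_weights,
    compute_bundle,
    critic_weights,
    entropy_weights,
    generate_synthetic,
    merec_weights,
    normalize,
)

# Published weight rows of the bundled case study, one vector per method.
CASE_WEIGHTS = {
    "entropy": [0.5110, 0.0785, 0.0647, 0.0628, 0.1415, 0.1415],
    "critic": [0.2790, 0.1391, 0.1211, 0.1244, 0.1675, 0.1689],
    "merec": [0.1442, 0.1814, 0.1721, 0.1767, 0.1628, 0.1628],
    "cilos": [0.2153, 0.1469, 0.1540, 0.1500, 0.1668, 0.1668],
}
METHODS = {
    "entropy": entropy_weights,
    "critic": critic_weights,
    "merec": merec_weights,
    "cilos": cilos_weights,
}


@pytest.mark.parametrize("method", sorted(CASE_WEIGHTS))
def test_case_study_weights_reproduce(problem, method):
    w = METHODS[method](problem)
    np.testing.assert_allclose(w.weights, CASE_WEIGHTS[method], atol=5e-4)


@pytest.mark.parametrize("method", sorted(METHODS))
@settings(max_examples=20, derandomize=True)
@given(seed=st.integers(0, 5000))
def test_weights_normalized_and_nonnegative(method, seed):
    p = generate_synthetic(6, 5, seed=seed)
    w = METHODS[method](p).weights
    assert np.all(w >= 0)
    assert w.sum() == pytest.approx(1.0, abs=1e-9)


class TestEntropy:
    def test_identical_value_multisets_get_equal_weight(self, problem):
        # C5 and C6 hold the same multiset of scores
        w = entropy_weights(problem).weights
        assert w[4] == pytest.approx(w[5], abs=1e-12)

    def test_constant_column_gets_zero_weight(self):
        p = DecisionProblem(("a", "b", "c"), ("C1", "C2"),
                            [[5, 1], [5, 2], [5, 4]])
        w = entropy_weights(p).weights
        assert w[0] == pytest.approx(0.0, abs=1e-12)
        assert w[1] == pytest.approx(1.0)

    def test_all_constant_columns_error(self):
        p = DecisionProblem(("a", "b"), ("C1", "C2"), [[5, 3], [5, 3]])
        with pytest.raises(ValueError, match="no information"):
            entropy_weights(p)

    def test_column_rescaling_invariance(self, problem):
        scaled = problem.scores.copy()
        scaled[:, 1] *= 4.2
        w1 = entropy_weights(problem).weights
        w2 = entropy_weights(
            DecisionProblem(problem.alternative_ids, problem.criterion_ids, scaled)
        ).weights
        np.testing.assert_allclose(w1, w2, atol=1e-12)


class TestCritic:
    def test_perfectly_opposed_columns_share_weight(self):
        p = DecisionProblem(("a", "b", "c"), ("C1", "C2"),
                            [[1, 3], [2, 2], [3, 1]])
        np.testing.assert_allclose(critic_weights(p).weights, [0.5, 0.5])

    def test_constant_column_error(self):
        p = DecisionProblem(("a", "b"), ("C1", "C2"), [[5, 1], [5, 2]])
        with pytest.raises(ValueError, match="constant"):
            critic_weights(p)

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_sd_convention_does_not_change_weights(self, seed):
        p = generate_synthetic(7, 4, seed=seed)
        w_sample = critic_weights(p, ddof=1).weights
        w_population = critic_weights(p, ddof=0).weights
        np.testing.assert_allclose(w_sample, w_population, atol=1e-12)


class TestRemovalEffect:
    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_closed_form_equals_literal_removal(self, seed):
        """Oracle: drop each criterion's term explicitly at coefficient 1/m."""
        p = generate_synthetic(6, 5, seed=seed)
        r = normalize(p).values
        n, m = r.shape
        p_full = r.sum(axis=1) / m
        effect = np.empty(m)
        for j in range(m):
            p_minus = np.delete(r, j, axis=1).sum(axis=1) / m  # keep 1/m
            effect[j] = np.abs(p_full - p_minus).sum()
        np.testing.assert_allclose(
            merec_weights(p).weights, effect / effect.sum(), atol=1e-12
        )

    def test_all_ones_matrix_gives_equal_weights(self):
        p = DecisionProblem(("a", "b"), ("C1", "C2", "C3"), np.ones((2, 3)))
        np.testing.assert_allclose(merec_weights(p).weights, 1 / 3)

    def test_logarithmic_variant_differs_and_normalizes(self, problem):
        w_log = merec_weights(problem, variant="logarithmic")
        assert w_log.method_id == "merec[logarithmic]"
        assert w_log.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert not np.allclose(w_log.weights, merec_weights(problem).weights)

    def test_unknown_variant_rejected(self, problem):
        with pytest.raises(ValueError, match="variant"):
            merec_weights(problem, variant="bogus")


class TestImpactLoss:
    def test_symmetric_reciprocal_sums(self):
        p = DecisionProblem(("a", "b"), ("C1", "C2"), [[1, 2], [2, 1]])
        np.testing.assert_allclose(cilos_weights(p).weights, [0.5, 0.5])

    def test_direct_reciprocal_arithmetic(self):
        # T = (1/1 + 1/2, 1/1 + 1/4) = (1.5, 1.25)
        p = DecisionProblem(("a", "b"), ("C1", "C2"), [[1, 1], [2, 4]])
        np.testing.assert_allclose(
            cilos_weights(p).weights, [1.5 / 2.75, 1.25 / 2.75], atol=1e-4
        )


class TestBonferroniFusion:
    def test_case_study_fusion_close_with_same_criterion_order(self, problem, fused_weights):
        bundle = compute_bundle(problem)
        np.testing.assert_allclose(
            bundle.fused.weights, fused_weights.weights, atol=0.02
        )
        assert np.argsort(-bundle.fused.weights).tolist() == \
            np.argsort(-fused_weights.weights).tolist()

    def test_identical_vectors_fuse_to_themselves(self):
        wv = WeightVector("m", ("C1", "C2", "C3"), [0.5, 0.3, 0.2])
        fused = bonferroni_fuse([wv, wv, wv])
        np.testing.assert_allclose(fused.weights, wv.weights, atol=1e-12)

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 5000), k=st.integers(2, 5))
    def test_pairwise_sum_closed_form_equals_double_loop(self, seed, k):
        rng = np.random.default_rng(seed)
        w = rng.dirichlet(np.ones(4), size=k)
        closed = w.sum(axis=0) ** 2 - (w**2).sum(axis=0)
        explicit = np.zeros(4)
        for a in range(k):
            for b in range(k):
                if a != b:
                    explicit += w[a] * w[b]
        np.testing.assert_allclose(closed, explicit, atol=1e-12)

    def test_fusion_symmetric_in_method_order(self, problem):
        bundle = compute_bundle(problem)
        reversed_fused = bonferroni_fuse(tuple(reversed(bundle.methods)))
        np.testing.assert_allclose(reversed_fused.weights, bundle.fused.weights)

    def test_fewer_than_two_vectors_rejected(self):
        wv = WeightVector("m", ("C1", "C2"), [0.6, 0.4])
        with pytest.raises(ValueError, match="at least two"):
            bonferroni_fuse([wv])
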