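"""Benchmark rankers: score oracles, rank orders, structural invariants."""

import numpy as np
import pytest

from oshprior import (
    CASE_STUDY_METHOD_RANKS,
    DecisionProblem,
    WeightVector,
    edas_rank,
    generate_synthetic,
    marcos_rank,
    promethee2_rank,
    run_rankers,
    topsis_rank,
    vikor_rank,
    waspas_rank,
)

# Frozen from independent hand/numpy oracle computations of each
# method's standard formulas on the bundled matrix + fused weights.
ORACLE_SCORES = {
    "topsis": [0.2921, 0.7122, 0.7189, 0.6279, 0.2891],
    "vikor": [0.8749, 0.0642, 0.1442, 0.0366, 0.9083],  # raw Q, lower better
    "edas": [0.2341, 0.6800, 0.7561, 0.6030, 0.2270],
    "waspas": [0.6865, 0.8229, 0.8322, 0.8058, 0.6730],
    "promethee2": [-0.1297, 0.0838, 0.1678, 0.0001, -0.1220],
}


class TestCaseStudyScores:
    def test_topsis_closeness(self, problem, fused_weights):
        cc = topsis_rank(problem, fused_weights).scores
        np.testing.assert_allclose(cc, ORACLE_SCORES["topsis"], atol=5e-4)

    def test_vikor_q(self, problem, fused_weights):
        q = vikor_rank(problem, fused_weights, v=0.5).raw_scores
        np.testing.assert_allclose(q, ORACLE_SCORES["vikor"], atol=5e-4)

    def test_edas_appraisal(self, problem, fused_weights):
        a = edas_rank(problem, fused_weights).scores
        np.testing.assert_allclose(a, ORACLE_SCORES["edas"], atol=5e-4)

    def test_waspas_mix(self, problem, fused_weights):
        q = waspas_rank(problem, fused_weights, lambda_mix=0.5).scores
        np.testing.assert_allclose(q, ORACLE_SCORES["waspas"], atol=5e-4)

    def test_promethee_net_flows(self, problem, fused_weights):
        phi = promethee2_rank(problem, fused_weights).scores
        np.testing.assert_allclose(phi, ORACLE_SCORES["promethee2"], atol=5e-4)


class TestCaseStudyRankOrders:
    @pytest.mark.parametrize("method", sorted(CASE_STUDY_METHOD_RANKS))
    def test_published_ranks_reproduce(self, method_rankings, method):
        result = next(r for r in method_rankings if r.method_id == method)
        np.testing.assert_array_equal(result.ranks, CASE_STUDY_METHOD_RANKS[method])

    def test_a2_is_second_everywhere(self, method_rankings):
        for r in method_rankings:
            assert r.ranks[1] == 2, r.method_id

    def test_promethee_order_equals_marcos_order(self, method_rankings):
        orders = {r.method_id: r.order() for r in method_rankings}
        assert orders["promethee2"] == orders["marcos"]

    def test_vikor_puts_training_first(self, method_rankings):
        vikor = next(r for r in method_rankings if r.method_id == "vikor")
        assert vikor.order()[0] == "A4"


class TestInvariants:
    def test_score_ranges(self, problem, fused_weights):
        assert np.all((topsis_rank(problem, fused_weights).scores >= 0)
                      & (topsis_rank(problem, fused_weights).scores <= 1))
        q = vikor_rank(problem, fused_weights).raw_scores
        assert np.all((q >= 0) & (q <= 1))
        a = edas_rank(problem, fused_weights).scores
        assert np.all((a >= 0) & (a <= 1))

    def test_net_flows_sum_to_zero(self, problem, fused_weights):
        assert promethee2_rank(problem, fused_weights).scores.sum() == \
            pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_net_flows_sum_to_zero_on_random_input(self, seed, fused_weights):
        p = generate_synthetic(7, 6, seed=seed)
        w = WeightVector("w", p.criterion_ids, fused_weights.weights)
        assert promethee2_rank(p, w).scores.sum() == pytest.approx(0.0, abs=1e-10)

    def test_dominant_alternative_ranks_first(self):
        p = DecisionProblem(("top", "a", "b"), ("C1", "C2", "C3"),
                            [[9, 9, 9], [5, 6, 4], [3, 2, 8]])
        w = WeightVector("equal", p.criterion_ids, np.full(3, 1 / 3))
        for fn in (topsis_rank, edas_rank, waspas_rank, promethee2_rank):
            assert fn(p, w).ranks[0] == 1, fn.__name__
        q = vikor_rank(p, w).raw_scores
        assert q[0] == pytest.approx(0.0, abs=1e-12)

    def test_vikor_two_alternatives_extremes(self):
        p = DecisionProblem(("worse", "better"), ("C1", "C2"), [[1, 1], [2, 2]])
        w = WeightVector("equal", p.criterion_ids, [0.5, 0.5])
        q = vikor_rank(p, w).raw_scores
        np.testing.assert_allclose(q, [1.0, 0.0])

    def test_vikor_identical_alternatives_rejected(self):
        p = DecisionProblem(("a", "b"), ("C1", "C2"), [[2, 3], [2, 3]])
        w = WeightVector("equal", p.criterion_ids, [0.5, 0.5])
        with pytest.raises(ValueError, match="identical"):
            vikor_rank(p, w)

    def test_edas_average_row_scores_half_when_others_deviate(self):
        # middle row equals the column means exactly
        p = DecisionProblem(("lo", "mid", "hi"), ("C1", "C2"),
                            [[1, 2], [2, 4], [3, 6]])
        w = WeightVector("equal", p.criterion_ids, [0.5, 0.5])
        assert edas_rank(p, w).scores[1] == pytest.approx(0.5)

    def test_waspas_lambda_one_reduces_to_weighted_sum(self, problem, fused_weights):
        wsm = waspas_rank(problem, fused_weights, lambda_mix=1.0).scores
        q = marcos_rank(problem, fused_weights).row_scores
        np.testing.assert_allclose(wsm, q, atol=1e-12)

    @pytest.mark.parametrize("seed", [2, 13, 77])
    def test_dominated_duplicate_never_displaces_winner(self, seed):
        p = generate_synthetic(6, 4, seed=seed)
        w = WeightVector("equal", p.criterion_ids, np.full(4, 0.25))
        for fn in (topsis_rank, edas_rank, waspas_rank):
            base = fn(p, w)
            winner = base.order()[0]
            dominated = p.scores.min(axis=0) * 0.5
            extended = DecisionProblem(
                p.alternative_ids + ("dup",), p.criterion_ids,
                np.vstack([p.scores, dominated]),
            )
            again = fn(extended, WeightVector("equal", p.criterion_ids, np.full(4, 0.25)))
            assert again.order()[0] == winner, fn.__name__

    def test_unknown_method_rejected(self, problem, fused_weights):
        with pytest.raises(ValueError, match="unknown ranking method"):
            run_rankers(problem, fused_weights, ("marcos", "bogus"))
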