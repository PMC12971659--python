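"""Benchmark rankers run with the same weights: TOPSIS, VIKOR, EDAS,
WASPAS, PROMETHEE-II.

Variant choices (fixed, documented in docs/methods.md):

* TOPSIS — vector (root-sum-square) column normalization, Euclidean
  distances to ideal / negative-ideal, closeness ``CC = D⁻/(D⁺+D⁻)``.
* VIKOR — linear (max−min) normalization, compromise coefficient
  ``v = 0.5``, single complete ranking by ascending ``Q`` (no
  acceptable-advantage screening). ``Q`` is negated for storage so all
  results share the higher-is-better orientation; the raw ``Q`` stays
  in ``raw_scores``.
* EDAS — arithmetic-mean average solution, weighted positive/negative
  distances, appraisal ``AS = (NSP + NSN)/2``.
* WASPAS — mix ``λ·WSM + (1−λ)·WPM`` of the weighted sum and weighted
  product of max-normalized values, default ``λ = 0.5``.
* PROMETHEE-II — usual (0/1) preference criterion on raw scores,
  weighted pairwise preference index, complete ranking by net flow
  ``φ`` (net flows sum to zero by antisymmetry).

Cost criteria are handled inside each method by its own convention
(direction of the ideal, sign of the deviation, or reversed pairwise
preference).
"""

from __future__ import annotations

import numpy as np

from .core_matrix import BENEFIT, DecisionProblem, normalize
from .marcos import marcos_ranking
from .ranking import RankingResult, ranks_from_scores
from .weighting import WeightVector

__all__ = [
    "topsis_rank",
    "vikor_rank",
    "edas_rank",
    "waspas_rank",
    "promethee2_rank",
    "RANKERS",
    "run_rankers",
]


def _check(problem: DecisionProblem, weights: WeightVector) -> None:
    if weights.criterion_ids != problem.criterion_ids:
        raise ValueError("weight vector criteria do not match the problem")


def topsis_rank(problem: DecisionProblem, weights: WeightVector) -> RankingResult:
    """Closeness to the ideal solution under vector normalization."""
    _check(problem, weights)
    x = problem.scores
    v = x / np.sqrt((x**2).sum(axis=0)) * weights.weights
    benefit = problem.directions == BENEFIT
    ideal = np.where(benefit, v.max(axis=0), v.min(axis=0))
    nadir = np.where(benefit, v.min(axis=0), v.max(axis=0))
    d_plus = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - nadir) ** 2).sum(axis=1))
    cc = d_minus / (d_plus + d_minus)
    return RankingResult("topsis", problem.alternative_ids, cc, ranks_from_scores(cc))


def vikor_rank(
    problem: DecisionProblem, weights: WeightVector, v: float = 0.5
) -> RankingResult:
    """Compromise ranking balancing group utility S and max regret R."""
    _check(problem, weights)
    x = problem.scores
    benefit = problem.directions == BENEFIT
    best = np.where(benefit, x.max(axis=0), x.min(axis=0))
    worst = np.where(benefit, x.min(axis=0), x.max(axis=0))
    span = best - worst
    if np.all(span == 0):
        raise ValueError("vikor: all alternatives identical on every criterion")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(span != 0, (best - x) / span, 0.0)
    wd = weights.weights * d
    s = wd.sum(axis=1)
    r = wd.max(axis=1)
    s_span = s.max() - s.min()
    r_span = r.max() - r.min()
    q = np.zeros_like(s)
    if s_span > 0:
        q += v * (s - s.min()) / s_span
    if r_span > 0:
        q += (1.0 - v) * (r - r.min()) / r_span
    return RankingResult(
        "vikor",
        problem.alternative_ids,
        scores=-q,  # higher-better orientation for downstream use
        ranks=ranks_from_scores(q, higher_is_better=False),
        raw_scores=q,
    )


def edas_rank(problem: DecisionProblem, weights: WeightVector) -> RankingResult:
    """Appraisal by weighted distance from the average solution."""
    _check(problem, weights)
    x = problem.scores
    av = x.mean(axis=0)
    benefit = problem.directions == BENEFIT
    diff = np.where(benefit, x - av, av - x)
    pda = np.maximum(0.0, diff) / av
    nda = np.maximum(0.0, -diff) / av
    sp = (weights.weights * pda).sum(axis=1)
    sn = (weights.weights * nda).sum(axis=1)
    nsp = sp / sp.max() if sp.max() > 0 else np.ones_like(sp)
    nsn = 1.0 - sn / sn.max() if sn.max() > 0 else np.ones_like(sn)
    score = 0.5 * (nsp + nsn)
    return RankingResult("edas", problem.alternative_ids, score, ranks_from_scores(score))


def waspas_rank(
    problem: DecisionProblem, weights: WeightVector, lambda_mix: float = 0.5
) -> RankingResult:
    """Weighted-sum / weighted-product mix on max-normalized values."""
    _check(problem, weights)
    if not 0.0 <= lambda_mix <= 1.0:
        raise ValueError("lambda_mix must lie in [0, 1]")
    r = normalize(problem).values
    w = weights.weights
    wsm = (w * r).sum(axis=1)
    wpm = np.prod(r**w, axis=1)
    score = lambda_mix * wsm + (1.0 - lambda_mix) * wpm
    return RankingResult("waspas", problem.alternative_ids, score, ranks_from_scores(score))


def promethee2_rank(problem: DecisionProblem, weights: WeightVector) -> RankingResult:
    """Complete ranking by net outranking flow with the usual criterion."""
    _check(problem, weights)
    x = problem.scores * problem.directions  # cost columns flip preference
    n = problem.n_alternatives
    w = weights.weights
    # π(a, b) = Σ_j w_j · [x_aj > x_bj]
    pref = (x[:, None, :] > x[None, :, :]) @ w
    phi = (pref - pref.T).sum(axis=1) / (n - 1)
    return RankingResult("promethee2", problem.alternative_ids, phi, ranks_from_scores(phi))


#: Registry of all rankers sharing the (problem, weights) signature.
RANKERS = {
    "marcos": marcos_ranking,
    "topsis": topsis_rank,
    "vikor": vikor_rank,
    "edas": edas_rank,
    "waspas": waspas_rank,
    "promethee2": promethee2_rank,
}


def run_rankers(
    problem: DecisionProblem,
    weights: WeightVector,
    methods: tuple[str, ...] = ("marcos", "topsis", "vikor", "edas", "waspas", "promethee2"),
) -> list[RankingResult]:
    """Run the requested ranking methods with one shared weight vector."""
    try:
        return [RANKERS[m](problem, weights) for m in methods]
    except KeyError as exc:
        raise ValueError(f"unknown ranking method {exc.args[0]!r}") from None
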