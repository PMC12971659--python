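"""Compromise ranking against ideal and anti-ideal references (MARCOS).

MARCOS (Measurement of Alternatives and Ranking according to Compromise
Solution) appends the ideal profile (per-criterion best normalized
value) and the anti-ideal profile (per-criterion worst) to the
normalized matrix as synthetic reference alternatives, forms the
weighted-sum score ``Q_i = Σ_j w_j r_ij`` for every row, and benchmarks
each alternative through the two ratios

    λ⁺_i = Q_i / Q⁺      λ⁻_i = Q_i / Q⁻

where ``Q⁺``/``Q⁻`` are the ideal and anti-ideal scores. The final
utility combines both ratios through the standard MARCOS utility
function

    U_i = (λ⁺_i + λ⁻_i) / (1 + (1 − f⁺)/f⁺ + (1 − f⁻)/f⁻),

with ``f⁺ = λ⁻/(λ⁺ + λ⁻)`` and ``f⁻ = λ⁺/(λ⁺ + λ⁻)``. ``U`` is
strictly increasing in ``Q`` at fixed references, so MARCOS never
reverses the weighted-sum order within a single run; the utility
rescales it against the attainable range. With all-benefit criteria
and weights summing to one the ideal score is exactly 1, making
``λ⁺_i = Q_i``.

A simple-ratio utility ``λ⁺/λ⁻`` is sometimes written in place of the
function above, but it is degenerate — it equals ``Q⁻/Q⁺`` for every
alternative — so this module implements the standard utility, which
also reproduces the bundled case study's published utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_matrix import DecisionProblem, normalize
from .ranking import RankingResult, ranks_from_scores
from .weighting import WeightVector

__all__ = ["MarcosTable", "marcos_rank", "marcos_ranking"]


@dataclass(frozen=True)
class MarcosTable:
    """Full MARCOS tableau: weighted matrix, reference rows, utilities."""

    alternative_ids: tuple[str, ...]
    criterion_ids: tuple[str, ...]
    weighted_matrix: np.ndarray  # (n, m) u_ij for the alternatives
    row_scores: np.ndarray  # (n,) Q_i
    ideal_score: float  # Q+
    anti_ideal_score: float  # Q−
    k_plus: np.ndarray  # λ⁺_i
    k_minus: np.ndarray  # λ⁻_i
    utilities: np.ndarray  # U_i
    ideal_utility: float
    anti_ideal_utility: float
    ranks: np.ndarray  # 1-based, 1 = best

    def to_frame(self) -> pd.DataFrame:
        """One row per alternative plus the two reference rows."""
        rows = list(self.alternative_ids) + ["ideal", "anti-ideal"]
        q = np.concatenate([self.row_scores, [self.ideal_score, self.anti_ideal_score]])
        kp = np.concatenate([self.k_plus, [1.0, self.anti_ideal_score / self.ideal_score]])
        km = np.concatenate(
            [self.k_minus, [self.ideal_score / self.anti_ideal_score, 1.0]]
        )
        u = np.concatenate([self.utilities, [self.ideal_utility, self.anti_ideal_utility]])
        rank_col = [int(r) for r in self.ranks] + [None, None]
        return pd.DataFrame(
            {"Q": q, "k_plus": kp, "k_minus": km, "utility": u, "rank": rank_col},
            index=rows,
        )

    def to_dict(self) -> dict:
        return {
            "alternatives": list(self.alternative_ids),
            "criteria": list(self.criterion_ids),
            "weighted_matrix": self.weighted_matrix.tolist(),
            "Q": self.row_scores.tolist(),
            "Q_ideal": self.ideal_score,
            "Q_anti_ideal": self.anti_ideal_score,
            "k_plus": self.k_plus.tolist(),
            "k_minus": self.k_minus.tolist(),
            "utilities": self.utilities.tolist(),
            "ideal_utility": self.ideal_utility,
            "anti_ideal_utility": self.anti_ideal_utility,
            "ranks": np.asarray(self.ranks).tolist(),
        }


def _utility(k_plus: np.ndarray, k_minus: np.ndarray) -> np.ndarray:
    total = k_plus + k_minus
    f_plus = k_minus / total
    f_minus = k_plus / total
    return total / (1.0 + (1.0 - f_plus) / f_plus + (1.0 - f_minus) / f_minus)


def marcos_rank(problem: DecisionProblem, weights: WeightVector) -> MarcosTable:
    """Rank a decision problem with MARCOS under the given weights."""
    if weights.criterion_ids != problem.criterion_ids:
        raise ValueError("weight vector criteria do not match the problem")
    nm = normalize(problem)
    w = weights.weights
    u = nm.values * w
    q = u.sum(axis=1)
    q_plus = float(nm.ideal_profile @ w)
    q_minus = float(nm.anti_ideal_profile @ w)
    k_plus = q / q_plus
    k_minus = q / q_minus
    utilities = _utility(k_plus, k_minus)
    ideal_u = float(_utility(np.array([1.0]), np.array([q_plus / q_minus]))[0])
    anti_u = float(_utility(np.array([q_minus / q_plus]), np.array([1.0]))[0])
    return MarcosTable(
        alternative_ids=problem.alternative_ids,
        criterion_ids=problem.criterion_ids,
        weighted_matrix=u,
        row_scores=q,
        ideal_score=q_plus,
        anti_ideal_score=q_minus,
        k_plus=k_plus,
        k_minus=k_minus,
        utilities=utilities,
        ideal_utility=ideal_u,
        anti_ideal_utility=anti_u,
        ranks=ranks_from_scores(utilities),
    )


def marcos_ranking(problem: DecisionProblem, weights: WeightVector) -> RankingResult:
    """MARCOS as a :class:`RankingResult` (utilities as scores)."""
    table = marcos_rank(problem, weights)
    return RankingResult(
        method_id="marcos",
        alternative_ids=table.alternative_ids,
        scores=table.utilities,
        ranks=table.ranks,
    )
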