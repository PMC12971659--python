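"""Borda / Copeland rank aggregation and the final consensus order.

Given M rank permutations over the same n alternatives:

* **Borda** — each ranking awards ``n − rank`` points; totals are summed
  across rankings. Over tie-free rankings the totals conserve
  ``Σ_i B_i = M · n(n−1)/2``.
* **Copeland** — for each ordered pair, count the rankings placing i
  above j; the pairwise outcome is +1 / 0 / −1 by majority and the
  Copeland score is the row sum over opponents. Scores always sum to
  zero by antisymmetry.

The final consensus orders by Borda score descending, breaking ties by
Copeland score, then Stability Index, then alternative id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ranking import RankingResult

__all__ = ["ConsensusReport", "borda", "copeland", "final_consensus"]


def _rank_matrix(rankings: Sequence[RankingResult]) -> tuple[tuple[str, ...], np.ndarray]:
    if not rankings:
        raise ValueError("need at least one ranking")
    alts = rankings[0].alternative_ids
    for rr in rankings[1:]:
        if rr.alternative_ids != alts:
            raise ValueError("rankings cover different alternative sets")
    return alts, np.vstack([np.asarray(r.ranks, dtype=float) for r in rankings])


def borda(rankings: Sequence[RankingResult]) -> dict[str, float]:
    """Total Borda score ``Σ_m (n − r_i^(m))`` per alternative."""
    alts, ranks = _rank_matrix(rankings)
    n = len(alts)
    scores = (n - ranks).sum(axis=0)
    return {a: float(s) for a, s in zip(alts, scores)}


def copeland(rankings: Sequence[RankingResult]) -> dict[str, float]:
    """Net pairwise-majority wins per alternative."""
    alts, ranks = _rank_matrix(rankings)
    n = len(alts)
    scores = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            wins_i = int((ranks[:, i] < ranks[:, j]).sum())
            wins_j = int((ranks[:, j] < ranks[:, i]).sum())
            scores[i] += np.sign(wins_i - wins_j)
    return {a: float(s) for a, s in zip(alts, scores)}


@dataclass(frozen=True)
class ConsensusReport:
    """Aggregated Borda/Copeland scores, stability, and the final order."""

    alternative_ids: tuple[str, ...]
    borda_scores: dict[str, float]
    borda_ranks: dict[str, int]
    copeland_scores: dict[str, float]
    copeland_ranks: dict[str, int]
    stability: dict[str, float]
    final_ranks: dict[str, int]

    def order(self) -> tuple[str, ...]:
        return tuple(sorted(self.alternative_ids, key=lambda a: self.final_ranks[a]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "borda_score": self.borda_scores,
                "borda_rank": self.borda_ranks,
                "copeland_score": self.copeland_scores,
                "copeland_rank": self.copeland_ranks,
                "stability_index": self.stability,
                "final_rank": self.final_ranks,
            }
        ).loc[list(self.alternative_ids)]

    def to_dict(self) -> dict:
        return {
            "alternatives": list(self.alternative_ids),
            "borda_scores": self.borda_scores,
            "borda_ranks": self.borda_ranks,
            "copeland_scores": self.copeland_scores,
            "copeland_ranks": self.copeland_ranks,
            "stability_index": self.stability,
            "final_ranks": self.final_ranks,
        }


def _dense_ranks(alts: Sequence[str], scores: Mapping[str, float]) -> dict[str, int]:
    """1-based competition ranks by descending score (ties share rank)."""
    vals = np.array([scores[a] for a in alts])
    ranks = {}
    for a, v in zip(alts, vals):
        ranks[a] = 1 + int((vals > v).sum())
    return ranks


def final_consensus(
    rankings: Sequence[RankingResult],
    stability: Mapping[str, float] | None = None,
) -> ConsensusReport:
    """Aggregate M rankings into the final consensus ordering.

    Orders by Borda descending with Copeland, then Stability Index,
    then alternative id as successive tie-breaks. ``stability``
    defaults to the top-1 Stability Index over the supplied rankings
    themselves.
    """
    from .sensitivity import StabilityConfig, stability_index  # local: avoid cycle

    alts, _ = _rank_matrix(rankings)
    b = borda(rankings)
    c = copeland(rankings)
    si = dict(stability) if stability is not None else stability_index(
        rankings, StabilityConfig(k=1)
    )
    order = sorted(alts, key=lambda a: (-b[a], -c[a], -si.get(a, 0.0), a))
    return ConsensusReport(
        alternative_ids=alts,
        borda_scores=b,
        borda_ranks=_dense_ranks(alts, b),
        copeland_scores=c,
        copeland_ranks=_dense_ranks(alts, c),
        stability=si,
        final_ranks={a: i + 1 for i, a in enumerate(order)},
    )
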