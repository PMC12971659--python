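"""Shared ranking container and rank extraction.

All rankers in this package expose a :class:`RankingResult` whose
``scores`` are oriented higher-is-better (methods that natively rank
ascending store negated scores and keep the raw values in
``raw_scores``). Ranks are 1-based with 1 = best; tied scores share the
average rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["RankingResult", "ranks_from_scores"]


def ranks_from_scores(scores: np.ndarray, higher_is_better: bool = True) -> np.ndarray:
    """1-based ranks (1 = best) from a score vector; ties get average rank."""
    s = np.asarray(scores, dtype=float)
    r = rankdata(-s if higher_is_better else s, method="average")
    if np.all(r == np.round(r)):
        return r.astype(int)
    return r


@dataclass(frozen=True)
class RankingResult:
    """Per-alternative scores and 1-based ranks from one ranking method."""

    method_id: str
    alternative_ids: tuple[str, ...]
    scores: np.ndarray
    ranks: np.ndarray
    raw_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "alternative_ids", tuple(self.alternative_ids))
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "ranks", np.asarray(self.ranks))
        if self.scores.size != len(self.alternative_ids) or self.ranks.size != self.scores.size:
            raise ValueError("scores/ranks must match alternative_ids")

    def order(self) -> tuple[str, ...]:
        """Alternative ids from best to worst."""
        idx = np.argsort(self.ranks, kind="stable")
        return tuple(self.alternative_ids[i] for i in idx)

    def to_dict(self) -> dict:
        out = {
            "method": self.method_id,
            "alternatives": list(self.alternative_ids),
            "scores": self.scores.tolist(),
            "ranks": self.ranks.tolist(),
        }
        if self.raw_scores is not None:
            out["raw_scores"] = np.asarray(self.raw_scores).tolist()
        return out
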