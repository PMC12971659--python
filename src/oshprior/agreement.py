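"""Inter-method rank concordance: Kendall's τ, Spearman's ρ.

Kendall's τ is the tau-a statistic, ``(N_c − N_d) / (n(n−1)/2)``, with
tied pairs counted as neither concordant nor discordant (no tie
correction in the denominator). Spearman's ρ uses the classical
difference formula ``1 − 6 Σ d² / (n(n²−1))`` on tie-free rank vectors
and falls back to the product-moment correlation of the rank vectors
when ties are present.

The correlation matrix's per-method row means include the diagonal
self-correlation of 1 by default — a deliberate, non-standard
convention matching the bundled case study's published summary values
(e.g. the VIKOR row mean τ of 0.433 is (0.2+0.4+1+0.4+0.4+0.2)/6);
pass ``include_diagonal=False`` for conventional off-diagonal means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ranking import RankingResult

__all__ = ["CorrelationMatrix", "kendall_tau", "spearman_rho", "correlation_matrix"]


def _as_ranks(a: Sequence[float]) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise ValueError("rank vector must be 1-D")
    return arr


def kendall_tau(rank_a: Sequence[float], rank_b: Sequence[float]) -> float:
    """Tau-a rank correlation between two rank vectors of length ≥ 2."""
    a, b = _as_ranks(rank_a), _as_ranks(rank_b)
    if a.size != b.size:
        raise ValueError("rank vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two items")
    da = np.sign(a[:, None] - a[None, :])
    db = np.sign(b[:, None] - b[None, :])
    prod = da * db
    iu = np.triu_indices(n, k=1)
    concordant = int((prod[iu] > 0).sum())
    discordant = int((prod[iu] < 0).sum())
    return (concordant - discordant) / (n * (n - 1) / 2)


def spearman_rho(rank_a: Sequence[float], rank_b: Sequence[float]) -> float:
    """Spearman rank correlation via the rank-difference formula."""
    a, b = _as_ranks(rank_a), _as_ranks(rank_b)
    if a.size != b.size:
        raise ValueError("rank vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two items")
    has_ties = len(set(a.tolist())) < n or len(set(b.tolist())) < n
    if has_ties:
        return float(np.corrcoef(a, b)[0, 1])
    d2 = ((a - b) ** 2).sum()
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise τ and ρ between method rankings, with row means."""

    method_ids: tuple[str, ...]
    kendall: np.ndarray
    spearman: np.ndarray
    kendall_row_means: np.ndarray
    spearman_row_means: np.ndarray
    includes_diagonal: bool

    def kendall_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.kendall, index=self.method_ids, columns=self.method_ids)
        df["mean"] = self.kendall_row_means
        return df

    def spearman_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.spearman, index=self.method_ids, columns=self.method_ids)
        df["mean"] = self.spearman_row_means
        return df

    def to_dict(self) -> dict:
        return {
            "methods": list(self.method_ids),
            "kendall": self.kendall.tolist(),
            "spearman": self.spearman.tolist(),
            "kendall_row_means": self.kendall_row_means.tolist(),
            "spearman_row_means": self.spearman_row_means.tolist(),
            "includes_diagonal": self.includes_diagonal,
        }


def correlation_matrix(
    rankings: Sequence[RankingResult], include_diagonal: bool = True
) -> CorrelationMatrix:
    """Pairwise τ/ρ matrices over ≥ 2 rankings of the same alternatives."""
    if len(rankings) < 2:
        raise ValueError("need at least two rankings")
    alts = rankings[0].alternative_ids
    for rr in rankings[1:]:
        if rr.alternative_ids != alts:
            raise ValueError("rankings cover different alternative sets")
    m = len(rankings)
    tau = np.eye(m)
    rho = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            tau[i, j] = tau[j, i] = kendall_tau(rankings[i].ranks, rankings[j].ranks)
            rho[i, j] = rho[j, i] = spearman_rho(rankings[i].ranks, rankings[j].ranks)
    if include_diagonal:
        tau_means = tau.mean(axis=1)
        rho_means = rho.mean(axis=1)
    else:
        off = ~np.eye(m, dtype=bool)
        tau_means = (tau * off).sum(axis=1) / (m - 1)
        rho_means = (rho * off).sum(axis=1) / (m - 1)
    return CorrelationMatrix(
        method_ids=tuple(r.method_id for r in rankings),
        kendall=tau,
        spearman=rho,
        kendall_row_means=tau_means,
        spearman_row_means=rho_means,
        includes_diagonal=include_diagonal,
    )
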