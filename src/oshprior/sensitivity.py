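"""One-at-a-time (OAT) weight perturbation and ranking stability.

For a focal criterion *h* and perturbation ε, the OAT update is

    ω′_h = ω_h ± ε,      ω′_j = ω_j ∓ ε/(m−1)   (j ≠ h),

which conserves the unit sum by redistributing the shift equally over
the other m−1 criteria. A scenario is *infeasible* when the raw update
drives the focal weight below zero. Three policies govern infeasible
scenarios when re-ranking:

* ``include`` (default) — use ω′ as-is, negative focal weight and all;
  every scenario contributes, so frequency-table rows sum to the full
  scenario count.
* ``skip`` — drop infeasible scenarios from the tabulation.
* ``clamp`` — floor negative weights at zero and renormalize.

Rank frequencies over the scenario set feed the Stability Index

    SI_i(k) = #{scenarios with rank(A_i) ≤ k} / #scenarios,

the fraction of scenarios in which an alternative stays in the top-k.
SI is non-decreasing in k and equals 1 for every alternative at k = n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_matrix import DecisionProblem
from .ranking import RankingResult
from .weighting import WeightVector

__all__ = [
    "Scenario",
    "ScenarioSet",
    "RankFrequencyTable",
    "StabilityConfig",
    "generate_oat_scenarios",
    "run_sensitivity",
    "stability_index",
]

_POLICIES = ("include", "skip", "clamp")


@dataclass(frozen=True)
class Scenario:
    """One OAT perturbation: focal criterion, signed ε, resulting weights."""

    criterion_id: str
    epsilon: float  # signed
    weights: np.ndarray  # raw ω′ (may have a negative focal entry)
    feasible: bool

    @property
    def scenario_id(self) -> str:
        return f"{self.criterion_id}{self.epsilon:+g}"


@dataclass(frozen=True)
class ScenarioSet:
    """Ordered OAT scenarios (criterion-major, then ε level, then sign)."""

    base: WeightVector
    scenarios: tuple[Scenario, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenarios", tuple(self.scenarios))

    def __len__(self) -> int:
        return len(self.scenarios)

    @property
    def n_infeasible(self) -> int:
        return sum(not s.feasible for s in self.scenarios)

    def summary(self) -> dict:
        return {
            "total_scenarios": len(self),
            "feasible_scenarios": len(self) - self.n_infeasible,
            "infeasible_scenarios": [
                s.scenario_id for s in self.scenarios if not s.feasible
            ],
        }


@dataclass(frozen=True)
class RankFrequencyTable:
    """Counts of each rank per alternative over a scenario set."""

    alternative_ids: tuple[str, ...]
    counts: np.ndarray  # (n, n); entry (i, r-1) = #scenarios with rank r
    denominator: int

    def to_frame(self) -> pd.DataFrame:
        n = len(self.alternative_ids)
        return pd.DataFrame(
            self.counts,
            index=self.alternative_ids,
            columns=[f"rank_{r}" for r in range(1, n + 1)],
        )

    def to_dict(self) -> dict:
        return {
            "alternatives": list(self.alternative_ids),
            "counts": self.counts.tolist(),
            "denominator": self.denominator,
        }


@dataclass(frozen=True)
class StabilityConfig:
    """Top-k cutoff and scenario universe for the Stability Index."""

    k: int = 1
    scenario_source: str = "methods"  # methods | oat | combined


def generate_oat_scenarios(
    base_weights: WeightVector,
    eps_levels: Sequence[float] = (0.05, 0.10, 0.15),
    signs: Sequence[int] = (1, -1),
) -> ScenarioSet:
    """Build the full OAT scenario grid: m criteria × |levels| × signs."""
    w = base_weights.weights
    m = w.size
    for eps in eps_levels:
        if eps < 0:
            raise ValueError(f"perturbation level must be >= 0, got {eps}")
    scenarios = []
    for h, crit in enumerate(base_weights.criterion_ids):
        for eps in eps_levels:
            for sign in signs:
                wp = w - sign * eps / (m - 1)
                wp[h] = w[h] + sign * eps
                scenarios.append(
                    Scenario(
                        criterion_id=crit,
                        epsilon=sign * eps,
                        weights=wp,
                        feasible=bool(wp[h] >= 0),
                    )
                )
    return ScenarioSet(base=base_weights, scenarios=tuple(scenarios))


def _scenario_weight_vector(s: Scenario, base: WeightVector, policy: str) -> WeightVector | None:
    w = s.weights
    if not s.feasible:
        if policy == "skip":
            return None
        if policy == "clamp":
            w = np.maximum(w, 0.0)
            w = w / w.sum()
    # Bypass the WeightVector non-negativity contract for the include
    # policy: perturbed vectors may carry a negative focal weight.
    wv = object.__new__(WeightVector)
    object.__setattr__(wv, "method_id", f"oat[{s.scenario_id}]")
    object.__setattr__(wv, "criterion_ids", base.criterion_ids)
    object.__setattr__(wv, "weights", w)
    return wv


def run_sensitivity(
    problem: DecisionProblem,
    scenarios: ScenarioSet,
    ranker: str = "marcos",
    policy: str = "include",
) -> RankFrequencyTable:
    """Re-rank the problem under every scenario and tabulate the ranks."""
    from .comparators import RANKERS  # deferred to avoid an import cycle

    if policy not in _POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {_POLICIES}")
    if ranker not in RANKERS:
        raise ValueError(f"unknown ranker {ranker!r}; choose from {sorted(RANKERS)}")
    if len(scenarios.base.criterion_ids) != problem.n_criteria:
        raise ValueError("scenario weights do not match the problem's criteria")
    rank_fn = RANKERS[ranker]
    n = problem.n_alternatives
    counts = np.zeros((n, n), dtype=int)
    used = 0
    for s in scenarios.scenarios:
        wv = _scenario_weight_vector(s, scenarios.base, policy)
        if wv is None:
            continue
        result = rank_fn(problem, wv)
        for i, r in enumerate(np.asarray(result.ranks)):
            counts[i, int(round(r)) - 1] += 1
        used += 1
    return RankFrequencyTable(
        alternative_ids=problem.alternative_ids, counts=counts, denominator=used
    )


def stability_index(
    source: RankFrequencyTable | Sequence[RankingResult],
    config: StabilityConfig = StabilityConfig(),
) -> dict[str, float]:
    """Fraction of scenarios with each alternative in the top-k.

    ``source`` is either a rank-frequency table (scenario universe =
    weight perturbations) or a list of :class:`RankingResult` (scenario
    universe = ranking methods).
    """
    if isinstance(source, RankFrequencyTable):
        alts = source.alternative_ids
        n = len(alts)
        if not 1 <= config.k <= n:
            raise ValueError(f"k must lie in 1..{n}, got {config.k}")
        if source.denominator <= 0:
            raise ValueError("empty scenario set")
        top = source.counts[:, : config.k].sum(axis=1)
        return {a: float(t) / source.denominator for a, t in zip(alts, top)}
    rankings = list(source)
    if not rankings:
        raise ValueError("empty scenario set")
    alts = rankings[0].alternative_ids
    n = len(alts)
    if not 1 <= config.k <= n:
        raise ValueError(f"k must lie in 1..{n}, got {config.k}")
    for rr in rankings[1:]:
        if rr.alternative_ids != alts:
            raise ValueError("rankings cover different alternative sets")
    hits = np.zeros(n)
    for rr in rankings:
        hits += np.asarray(rr.ranks) <= config.k
    return {a: float(h) / len(rankings) for a, h in zip(alts, hits)}
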