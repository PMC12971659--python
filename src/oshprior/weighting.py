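"""Objective criterion weighting and Bonferroni weight fusion.

Four data-driven weighting schemes derive criterion importance from the
decision matrix itself rather than from stated preferences:

* **Entropy** — criteria whose score distribution across alternatives is
  far from uniform (low Shannon entropy of the column-share vector)
  carry more discriminating information and receive more weight.
* **CRITIC** — weight ∝ (column standard deviation) × (total conflict
  with the other criteria, measured as ``Σ_k (1 − Pearson r_jk)``);
  a criterion is informative when it varies a lot and is weakly
  correlated with the rest.
* **Removal-effect (MEREC variant)** — each alternative's composite
  score is the equal-coefficient mean of its normalized row; a
  criterion's weight is proportional to the total change in those
  composites when its term is dropped. With equal coefficients the
  removal effect reduces in closed form to the column sums of the
  normalized matrix. A ``variant="logarithmic"`` flag exposes the
  canonical logarithmic removal-effect formulation for comparison.
* **Impact-loss (CILOS variant)** — weight ∝ the column sum of
  reciprocal raw scores; columns where alternatives score poorly
  (large reciprocals) are deemed to constrain the system most. This
  reciprocal-sum formulation differs from the canonical impact-loss
  method and is documented as such.

The fused vector is the pairwise Bonferroni mean (p = q = 1) of the
per-method weights, renormalized to sum to one. The Bonferroni mean
averages products over ordered pairs of distinct methods and therefore
captures interactions between schemes while damping outlier weights
from any single method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_matrix import DecisionProblem, normalize

__all__ = [
    "WeightVector",
    "WeightingBundle",
    "entropy_weights",
    "critic_weights",
    "merec_weights",
    "cilos_weights",
    "bonferroni_fuse",
    "compute_bundle",
    "WEIGHTING_METHODS",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class WeightVector:
    """A normalized criterion-weight vector produced by one method."""

    method_id: str
    criterion_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "criterion_ids", tuple(self.criterion_ids))
        if w.ndim != 1 or w.size != len(self.criterion_ids):
            raise ValueError("weights must be a 1-D vector matching criterion_ids")
        if np.any(w < -_SUM_TOL):
            raise ValueError(f"{self.method_id}: negative weight in {w}")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError(f"{self.method_id}: weights sum to {w.sum()!r}, not 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.criterion_ids, self.weights.tolist()))


@dataclass(frozen=True)
class WeightingBundle:
    """Per-method weight vectors plus their fused combination."""

    methods: tuple[WeightVector, ...]
    fused: WeightVector

    def __post_init__(self) -> None:
        object.__setattr__(self, "methods", tuple(self.methods))
        crits = self.fused.criterion_ids
        for wv in self.methods:
            if wv.criterion_ids != crits:
                raise ValueError("all weight vectors must share criterion order")


def _as_weight_vector(method_id: str, problem: DecisionProblem, raw: np.ndarray) -> WeightVector:
    total = raw.sum()
    if total <= 0:
        raise ValueError(f"{method_id}: degenerate weights (total information is zero)")
    return WeightVector(method_id, problem.criterion_ids, raw / total)


def entropy_weights(problem: DecisionProblem) -> WeightVector:
    """Shannon-entropy weights from column-share distributions.

    ``q_ij = x_ij / Σ_i x_ij``; ``E_j = −(1/ln n) Σ_i q_ij ln q_ij``;
    weight ∝ ``1 − E_j``. A column with identical entries has maximal
    entropy and zero weight; if *every* column is constant there is no
    information to weight and an error is raised.
    """
    x = problem.scores
    n = problem.n_alternatives
    q = x / x.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log(q), 0.0)  # 0·ln 0 := 0
    e = -terms.sum(axis=0) / np.log(n)
    d = 1.0 - e
    d = np.where(np.abs(d) < 1e-12, 0.0, d)  # clip fp noise on constant columns
    if d.sum() <= 0:
        raise ValueError("entropy: all columns are constant — no information to weight")
    return _as_weight_vector("entropy", problem, d)


def critic_weights(problem: DecisionProblem, ddof: int = 1) -> WeightVector:
    """Dispersion × conflict weights (CRITIC).

    ``I_j = s_j Σ_k (1 − r_jk)`` on the raw columns, normalized. The
    standard-deviation convention (``ddof``) cancels in the
    normalization, so sample vs population gives identical weights.
    """
    x = problem.scores
    s = x.std(axis=0, ddof=ddof)
    if np.any(s == 0):
        j = int(np.flatnonzero(s == 0)[0])
        raise ValueError(
            f"critic: criterion {problem.criterion_ids[j]!r} is constant — "
            "correlation undefined"
        )
    corr = np.corrcoef(x.T)
    info = s * (1.0 - corr).sum(axis=1)
    if info.sum() <= 1e-15:
        # all columns perfectly correlated: zero conflict everywhere, so
        # no criterion is more informative than another — equal weights
        info = np.full(problem.n_criteria, 1.0)
    return _as_weight_vector("critic", problem, info)


def merec_weights(problem: DecisionProblem, variant: str = "default") -> WeightVector:
    """Removal-effect weights.

    ``variant="default"``: composite ``P_i`` is the equal-coefficient
    (1/m) mean of the normalized row; dropping criterion j's term while
    keeping the 1/m coefficient changes ``P_i`` by exactly ``r_ij / m``,
    so the removal effect of j is the column sum of r (scaled), and the
    weights are the normalized column sums of the normalized matrix.

    ``variant="logarithmic"``: the canonical removal-effect scheme —
    ``P_i = ln(1 + mean_j |ln r_ij|)`` with criterion j removed from the
    inner mean — provided for comparison only.
    """
    r = normalize(problem).values
    n, m = r.shape
    if variant == "default":
        effect = r.sum(axis=0) / m
    elif variant == "logarithmic":
        abs_log = np.abs(np.log(r))
        p_full = np.log1p(abs_log.mean(axis=1))
        effect = np.empty(m)
        for j in range(m):
            p_minus = np.log1p(np.delete(abs_log, j, axis=1).mean(axis=1))
            effect[j] = np.abs(p_full - p_minus).sum()
        if effect.sum() == 0:  # all rows uniform: no removal changes anything
            effect = np.full(m, 1.0)
    else:
        raise ValueError(f"unknown removal-effect variant {variant!r}")
    return _as_weight_vector(f"merec[{variant}]" if variant != "default" else "merec",
                             problem, effect)


def cilos_weights(problem: DecisionProblem) -> WeightVector:
    """Reciprocal-sum impact-loss weights: ``T_j = Σ_i 1/x_ij``, normalized."""
    t = (1.0 / problem.scores).sum(axis=0)
    return _as_weight_vector("cilos", problem, t)


def bonferroni_fuse(vectors: Sequence[WeightVector], method_id: str = "fused") -> WeightVector:
    """Fuse K ≥ 2 weight vectors with the Bonferroni mean (p = q = 1).

    Per criterion, ``BM_j = sqrt( Σ_{k≠L} w_j^(k) w_j^(L) / (K(K−1)) )``
    over ordered pairs of distinct methods, computed via the closed form
    ``Σ_{k≠L} w^(k) w^(L) = (Σ_k w^(k))² − Σ_k (w^(k))²``, then
    renormalized to sum to one. Fusing K identical vectors returns that
    vector unchanged; the operation is symmetric in the input order.
    """
    if len(vectors) < 2:
        raise ValueError("need at least two weight vectors to fuse")
    crits = vectors[0].criterion_ids
    for wv in vectors[1:]:
        if wv.criterion_ids != crits:
            raise ValueError("weight vectors must share criterion order")
    w = np.vstack([wv.weights for wv in vectors])
    k = w.shape[0]
    pair_sum = w.sum(axis=0) ** 2 - (w**2).sum(axis=0)
    bm = np.sqrt(pair_sum / (k * (k - 1)))
    return WeightVector(method_id, crits, bm / bm.sum())


WEIGHTING_METHODS = {
    "entropy": entropy_weights,
    "critic": critic_weights,
    "merec": merec_weights,
    "cilos": cilos_weights,
}


def compute_bundle(
    problem: DecisionProblem,
    methods: Sequence[str] = ("entropy", "critic", "merec", "cilos"),
) -> WeightingBundle:
    """Run the requested weighting methods and fuse them."""
    vecs = tuple(WEIGHTING_METHODS[m](problem) for m in methods)
    return WeightingBundle(methods=vecs, fused=bonferroni_fuse(vecs))
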