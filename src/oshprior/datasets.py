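"""Bundled case study: prioritizing five labor protection measures.

The packaged fixture is an expert-scored decision problem from an
Industry 4.0 occupational-safety setting: five intervention domains —

* ``A1`` engineering controls
* ``A2`` administrative controls
* ``A3`` personal protective equipment (PPE)
* ``A4`` safety training programs
* ``A5`` digital safety monitoring systems

— rated on a 1–9 scale against six benefit-oriented criteria:

* ``C1`` life-cycle cost (affordability; higher = more affordable)
* ``C2`` risk-reduction effectiveness
* ``C3`` regulatory compliance level
* ``C4`` worker acceptance and usability
* ``C5`` sustainability and long-term impact
* ``C6`` ease of implementation

Alongside the matrix, the case study's published fused weight vector
and the six method rank orders it induces ship as constants, so that
integration tests and reports can reproduce the downstream tables
bit-for-bit without re-deriving the inputs they check.
"""

from __future__ import annotations

import numpy as np

from .core_matrix import DecisionProblem
from .weighting import WeightVector

__all__ = [
    "labor_protection_problem",
    "CASE_STUDY_FUSED_WEIGHTS",
    "CASE_STUDY_METHOD_RANKS",
    "CASE_STUDY_RANK_FREQUENCIES",
]

_ALTERNATIVES = ("A1", "A2", "A3", "A4", "A5")
_CRITERIA = ("C1", "C2", "C3", "C4", "C5", "C6")

_SCORES = np.array(
    [
        [4, 9, 8, 7, 8, 5],
        [8, 7, 7, 8, 6, 8],
        [9, 6, 6, 9, 5, 9],
        [7, 8, 7, 8, 7, 7],
        [3, 9, 9, 6, 9, 6],
    ],
    dtype=float,
)


def labor_protection_problem() -> DecisionProblem:
    """The bundled 5×6 labor-protection decision matrix (all benefit)."""
    return DecisionProblem(
        alternative_ids=_ALTERNATIVES,
        criterion_ids=_CRITERIA,
        scores=_SCORES.copy(),
    )


#: The case study's fused criterion weights as published. The package's
#: own Bonferroni fusion of the four objective weight vectors lands
#: within 0.02 of these values with the same criterion ordering (the
#: published fusion step is not documented to full precision); all
#: exact downstream reproductions consume this printed vector.
CASE_STUDY_FUSED_WEIGHTS = WeightVector(
    method_id="fused[case-study]",
    criterion_ids=_CRITERIA,
    weights=np.array([0.3004, 0.1335, 0.1247, 0.1252, 0.1579, 0.1583]),
)

#: Published 1-based rank of each alternative (A1..A5 order) under the
#: six ranking methods, all run with ``CASE_STUDY_FUSED_WEIGHTS``.
CASE_STUDY_METHOD_RANKS: dict[str, tuple[int, ...]] = {
    "marcos": (5, 2, 1, 3, 4),
    "topsis": (4, 2, 1, 3, 5),
    "vikor": (4, 2, 3, 1, 5),
    "edas": (4, 2, 1, 3, 5),
    "waspas": (4, 2, 1, 3, 5),
    "promethee2": (5, 2, 1, 3, 4),
}

#: Published frequency of each rank (columns 1..5) per alternative
#: (rows A1..A5) over the 36 one-at-a-time weight-perturbation
#: scenarios of the case study's sensitivity analysis. Row sums are 36.
#: Note: only the A2 row and the row sums are reproducible from the
#: stated perturbation procedure; the other interior counts are kept
#: solely as the published reference (see docs/methods.md).
CASE_STUDY_RANK_FREQUENCIES = np.array(
    [
        [0, 0, 0, 15, 21],
        [2, 34, 0, 0, 0],
        [22, 3, 9, 0, 2],
        [10, 0, 26, 0, 0],
        [2, 0, 1, 21, 12],
    ],
    dtype=int,
)
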