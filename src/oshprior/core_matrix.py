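"""Decision-problem data model, validation, normalization and synthetic data.

The central object is :class:`DecisionProblem`: a strictly positive
``n × m`` performance matrix of *n* alternatives scored against *m*
criteria, each criterion flagged as benefit-oriented (larger is better)
or cost-oriented (smaller is better). Strict positivity is enforced at
construction time for every matrix because downstream stages take
reciprocals (impact-loss weighting) and logarithms / fractional powers
(entropy weighting, weighted-product aggregation) of the raw scores.

Normalization maps each column onto ``(0, 1]`` — benefit columns by
``x / max(x)``, cost columns by ``min(x) / x`` — so that every column
attains 1 at its best alternative. The per-criterion maxima and minima
of the normalized matrix form the ideal and anti-ideal reference
profiles used by the compromise-ranking stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "DecisionProblem",
    "NormalizedMatrix",
    "load_problem",
    "normalize",
    "generate_synthetic",
    "parse_directions",
]

BENEFIT = 1
COST = -1


class ValidationError(ValueError):
    """Raised when a decision problem violates its structural contract."""


def parse_directions(directions: Sequence, m: int | None = None) -> np.ndarray:
    """Coerce direction flags to a ±1 integer vector.

    Accepts ``"benefit"``/``"cost"`` labels, ``"max"``/``"min"``, or
    ``+1``/``-1`` integers. With ``directions=None`` and ``m`` given,
    defaults to all-benefit.
    """
    if directions is None:
        if m is None:
            raise ValidationError("cannot default directions without criterion count")
        return np.full(m, BENEFIT, dtype=int)
    out = []
    for d in directions:
        if isinstance(d, str):
            key = d.strip().lower()
            if key in ("benefit", "max", "+", "+1"):
                out.append(BENEFIT)
            elif key in ("cost", "min", "-", "-1"):
                out.append(COST)
            else:
                raise ValidationError(f"unknown criterion direction {d!r}")
        elif int(d) in (BENEFIT, COST):
            out.append(int(d))
        else:
            raise ValidationError(f"unknown criterion direction {d!r}")
    arr = np.asarray(out, dtype=int)
    if m is not None and arr.size != m:
        raise ValidationError(f"expected {m} direction flags, got {arr.size}")
    return arr


@dataclass(frozen=True)
class DecisionProblem:
    """A validated alternatives × criteria decision matrix.

    Parameters
    ----------
    alternative_ids : labels of the n alternatives (rows), unique.
    criterion_ids : labels of the m criteria (columns), unique.
    scores : (n, m) array of strictly positive performance scores.
    directions : per-criterion ±1 flags (+1 benefit, −1 cost); defaults
        to all-benefit.
    """

    alternative_ids: tuple[str, ...]
    criterion_ids: tuple[str, ...]
    scores: np.ndarray
    directions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        alts = tuple(str(a) for a in self.alternative_ids)
        crits = tuple(str(c) for c in self.criterion_ids)
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "alternative_ids", alts)
        object.__setattr__(self, "criterion_ids", crits)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2:
            raise ValidationError("scores must be a 2-D matrix")
        n, m = scores.shape
        if n < 2 or m < 2:
            raise ValidationError(
                f"need at least 2 alternatives and 2 criteria, got {n}×{m}"
            )
        if len(alts) != n or len(crits) != m:
            raise ValidationError("id lists must match the matrix shape")
        if len(set(alts)) != n:
            raise ValidationError("duplicate alternative ids")
        if len(set(crits)) != m:
            raise ValidationError("duplicate criterion ids")
        if not np.all(np.isfinite(scores)):
            i, j = np.argwhere(~np.isfinite(scores))[0]
            raise ValidationError(
                f"non-finite score at alternative {alts[i]!r}, criterion {crits[j]!r}"
            )
        if np.any(scores <= 0):
            i, j = np.argwhere(scores <= 0)[0]
            raise ValidationError(
                f"non-positive score {scores[i, j]:g} at alternative "
                f"{alts[i]!r}, criterion {crits[j]!r} (all scores must be > 0)"
            )
        dirs = parse_directions(self.directions, m) if self.directions is not None \
            else np.full(m, BENEFIT, dtype=int)
        object.__setattr__(self, "directions", dirs)

    @property
    def n_alternatives(self) -> int:
        return self.scores.shape[0]

    @property
    def n_criteria(self) -> int:
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=list(self.alternative_ids), columns=list(self.criterion_ids)
        )

    def to_dict(self) -> dict:
        """JSON-serializable echo of the problem (used in reports)."""
        return {
            "alternative_ids": list(self.alternative_ids),
            "criterion_ids": list(self.criterion_ids),
            "scores": self.scores.tolist(),
            "directions": ["benefit" if d == BENEFIT else "cost" for d in self.directions],
        }


@dataclass(frozen=True)
class NormalizedMatrix:
    """Column-normalized scores with ideal / anti-ideal reference profiles.

    ``values`` lies in ``(0, 1]`` with each column attaining 1 at its
    best alternative; ``ideal_profile`` / ``anti_ideal_profile`` are the
    per-criterion best and worst normalized values.
    """

    values: np.ndarray
    ideal_profile: np.ndarray
    anti_ideal_profile: np.ndarray


def normalize(problem: DecisionProblem) -> NormalizedMatrix:
    """Normalize each column onto (0, 1] preserving preference orientation.

    Benefit columns use ``x / max(x)``; cost columns use ``min(x) / x``.
    The ideal profile is the per-column maximum of the result (all ones
    when every criterion is benefit) and the anti-ideal profile the
    per-column minimum.
    """
    x = problem.scores
    r = np.empty_like(x)
    benefit = problem.directions == BENEFIT
    r[:, benefit] = x[:, benefit] / x[:, benefit].max(axis=0)
    cost = ~benefit
    if cost.any():
        r[:, cost] = x[:, cost].min(axis=0) / x[:, cost]
    return NormalizedMatrix(
        values=r,
        ideal_profile=r.max(axis=0),
        anti_ideal_profile=r.min(axis=0),
    )


def load_problem(path: str | Path, directions: Iterable | None = None) -> DecisionProblem:
    """Read a decision matrix from CSV.

    The file must have a header row of criterion ids and a first column
    of alternative ids; every cell must parse as a strictly positive
    number. ``directions`` defaults to all-benefit when omitted.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] < 1:
        raise ValidationError(f"{path}: no criterion columns found")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric cell ({exc})") from exc
    if np.any(pd.isna(values)):
        i, j = np.argwhere(pd.isna(values))[0]
        raise ValidationError(
            f"{path}: missing value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return DecisionProblem(
        alternative_ids=tuple(str(a) for a in df.index),
        criterion_ids=tuple(str(c) for c in df.columns),
        scores=values,
        directions=parse_directions(directions, df.shape[1]) if directions is not None else None,
    )


def generate_synthetic(
    n_alternatives: int,
    n_criteria: int,
    seed: int,
    scale: tuple[int, int] = (1, 9),
    directions: Iterable | None = None,
) -> DecisionProblem:
    """Draw a random integer decision matrix emulating expert ratings.

    Entries are uniform integers on ``scale`` (default 1–9, the common
    nine-point expert rating scale, hence strictly positive).
    Reproducible for a fixed ``seed``.
    """
    if n_alternatives < 2 or n_criteria < 2:
        raise ValidationError("need at least 2 alternatives and 2 criteria")
    lo, hi = int(scale[0]), int(scale[1])
    if lo < 1 or hi < lo:
        raise ValidationError(f"scale must satisfy 1 <= lo <= hi, got {scale}")
    rng = np.random.default_rng(seed)
    scores = rng.integers(lo, hi + 1, size=(n_alternatives, n_criteria)).astype(float)
    return DecisionProblem(
        alternative_ids=tuple(f"A{i + 1}" for i in range(n_alternatives)),
        criterion_ids=tuple(f"C{j + 1}" for j in range(n_criteria)),
        scores=scores,
        directions=parse_directions(directions, n_criteria) if directions is not None else None,
    )
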