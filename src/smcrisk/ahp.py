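"""AHP weighting, consistency evaluation, synthesis and ranking.

The priority vector of a pairwise-comparison matrix A is its principal
eigenvector (Aw = λmax·w), computed here by power iteration; the classical
row-mean approximation (row means of the column-normalized matrix) is kept
as an alternative. λmax is estimated as the mean of (A·w)_i / w_i, which
equals the matrix order n exactly when A is consistent and exceeds n
otherwise.

Consistency is judged by Saaty's ratio CR = CI / RI with
CI = (λmax − n)/(n − 1) and RI the tabulated random index; a matrix is
acceptable when CR < 0.10. For n ≤ 2 there is no independent judgment, so
CR is defined as 0.

Global weights multiply a leaf's local weight by its parent criterion's
weight; ranking is competition-style (ties share the smallest rank, the
next rank is skipped) with ties detected after rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConvergenceError,
    IncompleteHierarchyError,
    InvalidInputError,
    MissingRandomIndexError,
)
from .pcm import PairwiseComparisonMatrix, validate

__all__ = [
    "RANDOM_INDEX",
    "EXTENDED_RANDOM_INDEX",
    "WeightVector",
    "ConsistencyReport",
    "CriterionNode",
    "Hierarchy",
    "RankRecord",
    "Ranking",
    "column_normalize",
    "weights",
    "lambda_max",
    "consistency",
    "synthesize",
    "rank",
]

# Saaty's average random consistency index by matrix order.
RANDOM_INDEX: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41,
}
# Standard continuation beyond order 8; opt-in via allow_extended.
EXTENDED_RANDOM_INDEX: dict[int, float] = {**RANDOM_INDEX, 9: 1.45, 10: 1.49}

CR_THRESHOLD = 0.10


@dataclass
class WeightVector:
    labels: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.labels) != self.weights.size:
            raise InvalidInputError("labels and weights length mismatch")
        if np.any(self.weights <= 0):
            raise InvalidInputError(f"weights must be positive, got {self.weights}")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise InvalidInputError(
                f"weights must sum to 1, got {self.weights.sum()!r}"
            )

    def __getitem__(self, label: str) -> float:
        return float(self.weights[self.labels.index(label)])

    def as_dict(self) -> dict[str, float]:
        return {l: float(w) for l, w in zip(self.labels, self.weights)}


@dataclass(frozen=True)
class ConsistencyReport:
    lambda_max: float
    n: int
    ci: float
    ri: float
    cr: float
    passed: bool
    weight_convention: str = "full-precision"

    def as_dict(self) -> dict:
        return {
            "lambda_max": self.lambda_max,
            "n": self.n,
            "ci": self.ci,
            "ri": self.ri,
            "cr": self.cr,
            "passed": self.passed,
            "weight_convention": self.weight_convention,
        }


def column_normalize(pcm: PairwiseComparisonMatrix) -> np.ndarray:
    """Divide each column by its sum; every column of the result sums to 1."""
    a = pcm.entries
    return a / a.sum(axis=0, keepdims=True)


def weights(
    pcm: PairwiseComparisonMatrix,
    method: str = "eigen",
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> WeightVector:
    """Priority weights of a PCM.

    ``eigen`` (default): power iteration from the uniform vector,
    sum-normalized each step, stopping when the largest component change
    drops below ``tol``. ``rowmean``: row means of the column-normalized
    matrix (Saaty's approximate method).
    """
    problems = validate(pcm)
    if problems:
        raise InvalidInputError(f"invalid PCM: {problems}")
    a = pcm.entries
    n = pcm.n
    if method == "rowmean":
        w = column_normalize(pcm).mean(axis=1)
        return WeightVector(labels=list(pcm.labels), weights=w / w.sum())
    if method != "eigen":
        raise InvalidInputError(f"unknown weighting method {method!r}")
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = a @ w
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - w)) < tol:
            return WeightVector(labels=list(pcm.labels), weights=nxt)
        w = nxt
    nxt = a @ w
    nxt /= nxt.sum()
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations",
        residual=float(np.max(np.abs(nxt - w))),
    )


def lambda_max(pcm: PairwiseComparisonMatrix, w: WeightVector) -> float:
    """Saaty's estimator: mean over i of (A·w)_i / w_i.

    Equals n exactly for a consistent matrix and is >= n otherwise.
    """
    wv = np.asarray(w.weights, dtype=float)
    if np.any(wv == 0):
        raise InvalidInputError("weight vector has a zero component")
    return float(np.mean((pcm.entries @ wv) / wv))


def consistency(
    lam: float,
    n: int,
    ri_table: dict[int, float] | None = None,
    *,
    allow_extended: bool = False,
    weight_convention: str = "full-precision",
) -> ConsistencyReport:
    """Consistency report from a λmax estimate and the matrix order."""
    if n < 2:
        raise InvalidInputError(f"matrix order must be >= 2, got {n}")
    table = ri_table if ri_table is not None else (
        EXTENDED_RANDOM_INDEX if allow_extended else RANDOM_INDEX
    )
    if n not in table:
        raise MissingRandomIndexError(
            f"no random index for order {n}; pass allow_extended=True or a custom table"
        )
    ci = (lam - n) / (n - 1)
    ri = table[n]
    # Order <= 2 admits no independent judgment: CR is 0 by definition.
    cr = 0.0 if n <= 2 else ci / ri
    return ConsistencyReport(
        lambda_max=lam, n=n, ci=ci, ri=ri, cr=cr,
        passed=cr < CR_THRESHOLD, weight_convention=weight_convention,
    )


@dataclass
class CriterionNode:
    """A criterion with its local weight and its leaves' local weights."""

    name: str
    local_weight: float | None = None
    leaf_labels: list[str] = field(default_factory=list)
    leaf_weights: np.ndarray | None = None


@dataclass
class Hierarchy:
    """Goal → criteria → leaves, with local weights attached per level."""

    goal: str
    criteria: list[CriterionNode]

    def leaves(self) -> list[str]:
        out: list[str] = []
        for c in self.criteria:
            out.extend(c.leaf_labels)
        if len(set(out)) != len(out):
            raise InvalidInputError(f"a leaf appears under two criteria: {out}")
        return out


def synthesize(hierarchy: Hierarchy) -> WeightVector:
    """Global leaf weights: local leaf weight × parent criterion weight."""
    labels: list[str] = []
    vals: list[float] = []
    for c in hierarchy.criteria:
        if c.local_weight is None:
            raise IncompleteHierarchyError(f"criterion {c.name!r} is unweighted")
        if c.leaf_weights is None or not c.leaf_labels:
            raise IncompleteHierarchyError(
                f"criterion {c.name!r} has no weighted leaves"
            )
        lw = np.asarray(c.leaf_weights, dtype=float)
        if abs(lw.sum() - 1.0) > 1e-6:
            raise IncompleteHierarchyError(
                f"criterion {c.name!r}: local leaf weights sum to {lw.sum()}, not 1"
            )
        labels.extend(c.leaf_labels)
        vals.extend(c.local_weight * lw)
    crit_total = sum(c.local_weight for c in hierarchy.criteria)
    if abs(crit_total - 1.0) > 1e-6:
        raise IncompleteHierarchyError(
            f"criterion weights sum to {crit_total}, not 1"
        )
    return WeightVector(labels=labels, weights=np.asarray(vals))


@dataclass(frozen=True)
class RankRecord:
    label: str
    weight: float
    percent: int
    rank: int
    tied: bool


@dataclass
class Ranking:
    records: list[RankRecord]

    def rank_of(self, label: str) -> int:
        return next(r.rank for r in self.records if r.label == label)

    def as_rows(self) -> list[dict]:
        return [
            {
                "label": r.label,
                "weight": r.weight,
                "percent": r.percent,
                "rank": r.rank,
                "tied": r.tied,
            }
            for r in self.records
        ]


def rank(global_weights: WeightVector, tie_decimals: int = 3) -> Ranking:
    """Competition ranking of leaves by global weight.

    Ties are detected after rounding to ``tie_decimals`` decimals; tied
    leaves share the smallest applicable rank and the next rank is skipped.
    """
    rounded = [round(float(w), tie_decimals) for w in global_weights.weights]
    order = sorted(
        range(len(rounded)), key=lambda i: (-rounded[i], global_weights.labels[i])
    )
    records: list[RankRecord] = []
    position = 0
    current_rank = 0
    prev_value: float | None = None
    for idx in order:
        position += 1
        if rounded[idx] != prev_value:
            current_rank = position
            prev_value = rounded[idx]
        records.append(
            RankRecord(
                label=global_weights.labels[idx],
                weight=float(global_weights.weights[idx]),
                percent=round(100.0 * global_weights.weights[idx]),
                rank=current_rank,
                tied=False,
            )
        )
    # flag ties now that all ranks are known
    counts: dict[int, int] = {}
    for r in records:
        counts[r.rank] = counts.get(r.rank, 0) + 1
    records = [
        RankRecord(r.label, r.weight, r.percent, r.rank, counts[r.rank] > 1)
        for r in records
    ]
    return Ranking(records=records)
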