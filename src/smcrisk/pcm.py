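"""Pairwise-comparison matrices and Saaty-scale quantization.

A pairwise-comparison matrix (PCM) is a positive reciprocal square matrix:
``a_ij > 0``, ``a_ji = 1/a_ij``, unit diagonal. Entry ``a_ij`` states how
much more important factor *i* is than factor *j* on Saaty's 1–9 intensity
scale (1 equal … 9 extreme, 2/4/6/8 intermediate).

Two construction routes exist: quantize ratios of importance scores (the
quantitative route for sub-criteria), or accept a matrix supplied directly
by expert judgment (the criteria level). An override map lets an expert
amend individual quantized cells; the reciprocal cell follows automatically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

from .errors import InvalidInputError, InvalidOverrideError
from .evidence import score_ratio

__all__ = [
    "PairwiseComparisonMatrix",
    "SaatyQuantizer",
    "quantize_to_saaty",
    "build_from_scores",
    "validate",
    "is_cardinally_consistent",
    "read_pcm_json",
]

SAATY_SCALE_MAX = 9


@dataclass(frozen=True)
class SaatyQuantizer:
    """Maps a positive score ratio onto the discrete Saaty scale.

    For r >= 1 the intensity is ``floor(r)`` bumped up by one when the
    fractional part reaches ``ceil_threshold``, clamped to [1, scale_max];
    ratios below 1 map to the reciprocal of the quantized inverse, so
    reciprocity holds by construction. ``overrides`` records expert
    amendments applied after quantization.
    """

    scale_max: int = SAATY_SCALE_MAX
    ceil_threshold: float = 0.25
    overrides: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale_max != SAATY_SCALE_MAX:
            raise InvalidInputError("Saaty scale maximum is 9")
        if not 0.0 <= self.ceil_threshold < 1.0:
            raise InvalidInputError(
                f"ceil_threshold must be in [0,1), got {self.ceil_threshold}"
            )


def quantize_to_saaty(ratio: float, q: SaatyQuantizer | None = None) -> float:
    """Quantize a positive ratio to an intensity in {1/9, …, 1/2, 1, 2, …, 9}."""
    q = q or SaatyQuantizer()
    if ratio <= 0:
        raise InvalidInputError(f"ratio must be positive, got {ratio}")
    if ratio < 1.0:
        return 1.0 / quantize_to_saaty(1.0 / ratio, q)
    base = math.floor(ratio)
    frac = ratio - base
    intensity = base + (1 if frac >= q.ceil_threshold else 0)
    return float(min(max(intensity, 1), q.scale_max))


@dataclass
class PairwiseComparisonMatrix:
    """Labelled positive reciprocal matrix."""

    labels: list[str]
    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        n = len(self.labels)
        if self.entries.shape != (n, n):
            raise InvalidInputError(
                f"entries shape {self.entries.shape} does not match {n} labels"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.entries[i, j])

    def to_dict(self) -> dict:
        return {"labels": list(self.labels), "entries": self.entries.tolist()}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _parse_entry(v: float | int | str) -> float:
    if isinstance(v, str):
        return float(Fraction(v))  # accepts "1/3" and "0.25"
    return float(v)


def read_pcm_json(source: str | Path | dict) -> PairwiseComparisonMatrix:
    """Read ``{"labels": [...], "entries": [[...]]}``; entries may be decimals
    or exact-rational strings such as ``"1/3"``."""
    if not isinstance(source, dict):
        source = json.loads(Path(source).read_text())
    entries = np.array(
        [[_parse_entry(v) for v in row] for row in source["entries"]], dtype=float
    )
    return PairwiseComparisonMatrix(labels=list(source["labels"]), entries=entries)


def validate(
    pcm: PairwiseComparisonMatrix,
    *,
    rtol: float = 1e-9,
    max_order: int = 9,
    allow_large: bool = False,
) -> list[str]:
    """Return a list of invariant violations; an empty list means valid.

    Checks positivity, unit diagonal, reciprocity within relative tolerance
    and the Saaty order limit (n <= 9 unless ``allow_large``).
    """
    a = pcm.entries
    n = pcm.n
    problems: list[str] = []
    if n < 2:
        problems.append(f"matrix order {n} < 2")
    if n > max_order and not allow_large:
        problems.append(f"matrix order {n} exceeds the Saaty scale limit {max_order}")
    for i in range(n):
        if not math.isclose(a[i, i], 1.0, rel_tol=rtol, abs_tol=rtol):
            problems.append(f"diagonal entry ({i},{i}) = {a[i, i]} != 1")
        for j in range(n):
            if a[i, j] <= 0:
                problems.append(f"non-positive entry ({i},{j}) = {a[i, j]}")
    for i in range(n):
        for j in range(i + 1, n):
            if a[i, j] > 0 and a[j, i] > 0:
                if not math.isclose(a[j, i], 1.0 / a[i, j], rel_tol=1e-6):
                    problems.append(
                        f"reciprocity violation at ({j},{i}): "
                        f"{a[j, i]} != 1/{a[i, j]}"
                    )
    return problems


def is_cardinally_consistent(
    pcm: PairwiseComparisonMatrix, tol: float = 1e-6
) -> tuple[bool, tuple[int, int, int], float]:
    """Check transitivity ``a_jk = a_ik / a_ij`` over all triples.

    Returns (consistent, worst (i,j,k) triple, worst relative deviation).
    Any 2x2 reciprocal matrix is consistent (no independent triple).
    """
    a = pcm.entries
    n = pcm.n
    worst = (0, 0, 0)
    worst_dev = 0.0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                expected = a[i, k] / a[i, j]
                dev = abs(a[j, k] - expected) / expected
                if dev > worst_dev:
                    worst_dev = dev
                    worst = (i, j, k)
    return worst_dev <= tol, worst, worst_dev


def build_from_scores(
    scores: dict[str, float],
    q: SaatyQuantizer | None = None,
) -> PairwiseComparisonMatrix:
    """Quantize pairwise importance-score ratios into a PCM.

    ``a_ij = quantize(score_i / score_j)`` for i < j, reciprocals filled,
    unit diagonal; overrides from the quantizer are applied last (an
    override on (i, j) forces a_ji to its reciprocal).
    """
    q = q or SaatyQuantizer()
    labels = list(scores)
    n = len(labels)
    if n < 2:
        raise InvalidInputError("need at least two factors to compare")
    for lab, s in scores.items():
        if s <= 0:
            raise InvalidInputError(f"score for {lab!r} must be positive, got {s}")
    a = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = score_ratio(scores[labels[i]], scores[labels[j]], (labels[i], labels[j]))
            a[i, j] = quantize_to_saaty(r, q)
            a[j, i] = 1.0 / a[i, j]
    for (li, lj), value in q.overrides.items():
        if value <= 0:
            raise InvalidOverrideError(
                f"override ({li},{lj})={value} is not positive"
            )
        if li not in labels or lj not in labels:
            raise InvalidOverrideError(
                f"override ({li},{lj}) references unknown labels (have {labels})"
            )
        i, j = labels.index(li), labels.index(lj)
        a[i, j] = value
        a[j, i] = 1.0 / value
    return PairwiseComparisonMatrix(labels=labels, entries=a)
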