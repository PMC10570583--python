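"""Severity cost factors and normalized severity factors.

A severity schema turns raw surveillance statistics (incident counts per
severity class, average monetary cost per event) into two derived
quantities:

* an integer *cost factor* per class — how many times costlier an event of
  that class is than one of the reference class (the cheapest, factor 1);
* a *normalized severity factor* per class — the share of total
  cost-weighted incident counts attributable to the class, i.e.
  ``factor_c * count_c / sum_k factor_k * count_k``.

For the US-2019 road-crash case study the classes are Fatal / Major
(injury) / Minor (property damage only) with cost factors 332 / 4 / 1 and
normalized factors 0.470 / 0.326 / 0.204.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import DegenerateSchemaError, InvalidInputError

__all__ = [
    "SeverityClass",
    "SeveritySchema",
    "cost_factor",
    "scale_total_cost",
    "per_event_cost",
    "normalize_severity",
    "read_severity_csv",
]


def cost_factor(avg_cost: float, reference_cost: float) -> int:
    """Integer cost multiplier of a severity class relative to the reference.

    Rounds ``avg_cost / reference_cost`` half-up to the nearest integer with
    a floor of 1 (the reference class itself has factor 1).
    """
    if avg_cost <= 0 or reference_cost <= 0:
        raise InvalidInputError(
            f"costs must be positive, got avg_cost={avg_cost}, "
            f"reference_cost={reference_cost}"
        )
    ratio = avg_cost / reference_cost
    return max(1, math.floor(ratio + 0.5))


def scale_total_cost(total_cost: float, base_count: float, target_count: float) -> float:
    """Rescale an aggregate cost reported for ``base_count`` events to
    ``target_count`` events (e.g. a 2018 national cost restated for 2019
    incident counts). Unrounded; presentation rounding is the caller's."""
    if base_count <= 0 or target_count <= 0:
        raise InvalidInputError(
            f"counts must be positive, got base={base_count}, target={target_count}"
        )
    return total_cost * target_count / base_count


def per_event_cost(total_cost: float, n_events: float) -> float:
    """Average cost per event, unrounded."""
    if n_events <= 0:
        raise InvalidInputError(f"n_events must be positive, got {n_events}")
    return total_cost / n_events


@dataclass(frozen=True)
class SeverityClass:
    """One severity class: a label, its consequence, average per-event cost
    in currency units, and the annual event count."""

    name: str
    consequence_label: str
    per_event_cost: float
    event_count: int

    def __post_init__(self) -> None:
        if self.per_event_cost <= 0:
            raise InvalidInputError(
                f"class {self.name!r}: per_event_cost must be > 0, "
                f"got {self.per_event_cost}"
            )
        if self.event_count < 0:
            raise InvalidInputError(
                f"class {self.name!r}: event_count must be >= 0, "
                f"got {self.event_count}"
            )


@dataclass
class SeveritySchema:
    """Ordered severity classes plus the derived factors.

    ``cost_factors`` and ``normalized_factors`` are filled by
    :func:`normalize_severity`; ``reference_class`` names the class whose
    cost factor is pinned to 1 (defaults to the cheapest class).
    """

    classes: list[SeverityClass]
    reference_class: str | None = None
    cost_factors: dict[str, int] = field(default_factory=dict)
    weighted_counts: dict[str, float] = field(default_factory=dict)
    normalized_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.classes:
            raise InvalidInputError("schema needs at least one severity class")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise InvalidInputError(f"duplicate class names in {names}")
        if self.reference_class is None:
            self.reference_class = min(
                self.classes, key=lambda c: c.per_event_cost
            ).name
        elif self.reference_class not in names:
            raise InvalidInputError(
                f"reference_class {self.reference_class!r} not among {names}"
            )

    @property
    def class_names(self) -> list[str]:
        return [c.name for c in self.classes]

    def to_dict(self) -> dict:
        return {
            "reference_class": self.reference_class,
            "classes": [
                {
                    "name": c.name,
                    "consequence": c.consequence_label,
                    "avg_cost": c.per_event_cost,
                    "count": c.event_count,
                }
                for c in self.classes
            ],
            "cost_factors": dict(self.cost_factors),
            "weighted_counts": dict(self.weighted_counts),
            "normalized_factors": dict(self.normalized_factors),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def normalize_severity(schema: SeveritySchema) -> SeveritySchema:
    """Fill cost factors, cost-weighted counts and normalized factors.

    The normalized factor of class *c* is its share of the total
    cost-weighted event count; the factors sum to 1.
    """
    ref = next(c for c in schema.classes if c.name == schema.reference_class)
    factors = {
        c.name: cost_factor(c.per_event_cost, ref.per_event_cost)
        for c in schema.classes
    }
    weighted = {c.name: factors[c.name] * c.event_count for c in schema.classes}
    total = sum(weighted.values())
    if total <= 0:
        raise DegenerateSchemaError(
            "all cost-weighted counts are zero; cannot normalize"
        )
    schema.cost_factors = factors
    schema.weighted_counts = weighted
    schema.normalized_factors = {k: v / total for k, v in weighted.items()}
    return schema


def _parse_number(text: str) -> float:
    # Table-style thousands separators: plain commas and the prime/apostrophe
    # family (33'244, 33′244) are all accepted.
    for sep in ("'", "′", "’", ","):
        text = text.replace(sep, "")
    return float(text)


def read_severity_csv(path: str | Path, reference: str | None = None) -> SeveritySchema:
    """Read ``class,consequence,avg_cost,count`` rows into a schema."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise InvalidInputError(f"{path}: empty severity table")
    required = {"class", "consequence", "avg_cost", "count"}
    if not required.issubset(rows[0]):
        raise InvalidInputError(
            f"{path}: expected columns {sorted(required)}, got {sorted(rows[0])}"
        )
    classes = [
        SeverityClass(
            name=r["class"].strip(),
            consequence_label=r["consequence"].strip(),
            per_event_cost=_parse_number(r["avg_cost"]),
            event_count=int(_parse_number(r["count"])),
        )
        for r in rows
    ]
    return SeveritySchema(classes=classes, reference_class=reference)
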