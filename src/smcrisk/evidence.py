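"""Severity-weighted evidence tables.

Each risk factor's raw share of incidents in a severity class is multiplied
by that class's normalized severity factor, giving a *weighted share* in
percent. Summing a factor's weighted shares over all severity classes gives
its *importance score* — the quantitative signal later quantized into
pairwise-comparison intensities.

Shares within a criterion group need not sum to 100%: each column is the
share of incidents of that severity attributable to the factor, and factors
do not partition incidents. No renormalization is performed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import IncompleteTableError, InvalidInputError
from .severity import SeveritySchema

__all__ = [
    "EvidenceTable",
    "weighted_share",
    "importance_scores",
    "score_ratio",
    "read_evidence_csv",
    "apply_severity",
]


def weighted_share(raw_share: float, severity_factor: float) -> float:
    """Weighted share in percent: ``raw_share * severity_factor * 100``.

    Both arguments are fractions in [0, 1].
    """
    if not 0.0 <= raw_share <= 1.0:
        raise InvalidInputError(f"raw_share must be in [0,1], got {raw_share}")
    if not 0.0 <= severity_factor <= 1.0:
        raise InvalidInputError(
            f"severity_factor must be in [0,1], got {severity_factor}"
        )
    return raw_share * severity_factor * 100.0


def score_ratio(score_i: float, score_j: float, labels: tuple[str, str] | None = None) -> float:
    """Raw importance-score ratio, later quantized to the Saaty scale."""
    if score_j <= 0:
        what = f" ({labels[0]} / {labels[1]})" if labels else ""
        raise InvalidInputError(f"zero or negative denominator score{what}: {score_j}")
    return score_i / score_j


@dataclass
class EvidenceTable:
    """Weighted shares for one criterion group.

    ``weighted_share[(factor, class)]`` is in percent; ``importance_score``
    is filled by :func:`importance_scores`.
    """

    group: str
    factors: list[str]
    classes: list[str]
    weighted_share: dict[tuple[str, str], float] = field(default_factory=dict)
    importance_score: dict[str, float] = field(default_factory=dict)

    def cell(self, factor: str, klass: str) -> float:
        try:
            return self.weighted_share[(factor, klass)]
        except KeyError:
            raise IncompleteTableError(
                f"group {self.group!r}: missing cell ({factor}, {klass})"
            ) from None

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "factors": list(self.factors),
            "classes": list(self.classes),
            "weighted_share": {
                f"{f}/{c}": self.weighted_share[(f, c)]
                for f in self.factors
                for c in self.classes
                if (f, c) in self.weighted_share
            },
            "importance_score": dict(self.importance_score),
        }


def importance_scores(table: EvidenceTable) -> dict[str, float]:
    """Per-factor sum of weighted shares over severity classes, in percent.

    Fills ``table.importance_score`` and returns it. Values keep full
    precision; round to 1 dp for display only.
    """
    scores: dict[str, float] = {}
    for f in table.factors:
        total = 0.0
        for c in table.classes:
            v = table.cell(f, c)
            if v < 0:
                raise InvalidInputError(
                    f"group {table.group!r}: negative share at ({f}, {c}): {v}"
                )
            total += v
        scores[f] = total
    table.importance_score = scores
    return scores


def apply_severity(
    table: EvidenceTable, schema: SeveritySchema
) -> EvidenceTable:
    """Convert a table holding *raw* shares (percent of incidents of each
    severity class) into severity-weighted shares using the schema's
    normalized factors."""
    if not schema.normalized_factors:
        raise InvalidInputError("schema has no normalized_factors; run normalize_severity first")
    out = EvidenceTable(group=table.group, factors=list(table.factors), classes=list(table.classes))
    for f in table.factors:
        for c in table.classes:
            raw_pct = table.cell(f, c)
            try:
                factor = schema.normalized_factors[c]
            except KeyError:
                raise InvalidInputError(
                    f"severity class {c!r} not in schema {schema.class_names}"
                ) from None
            out.weighted_share[(f, c)] = weighted_share(raw_pct / 100.0, factor)
    return out


def read_evidence_csv(
    path: str | Path, schema: SeveritySchema | None = None
) -> dict[str, EvidenceTable]:
    """Read ``group,factor,class,share_percent`` rows into per-group tables.

    A leading ``# weighted=true|false`` comment line says whether shares are
    already severity-weighted (the published form) or raw; raw tables
    require a severity schema and are weighted on the way in.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    weighted = True
    data_lines = []
    for ln in lines:
        stripped = ln.strip()
        if stripped.startswith("#"):
            flag = stripped.lstrip("#").strip().lower()
            if flag.startswith("weighted="):
                weighted = flag.split("=", 1)[1] in ("true", "1", "yes")
            continue
        if stripped:
            data_lines.append(ln)
    rows = list(csv.DictReader(data_lines))
    if not rows:
        raise InvalidInputError(f"{path}: empty evidence table")
    required = {"group", "factor", "class", "share_percent"}
    if not required.issubset(rows[0]):
        raise InvalidInputError(
            f"{path}: expected columns {sorted(required)}, got {sorted(rows[0])}"
        )

    tables: dict[str, EvidenceTable] = {}
    for r in rows:
        g = r["group"].strip()
        t = tables.setdefault(g, EvidenceTable(group=g, factors=[], classes=[]))
        f, c = r["factor"].strip(), r["class"].strip()
        if f not in t.factors:
            t.factors.append(f)
        if c not in t.classes:
            t.classes.append(c)
        share = float(r["share_percent"])
        if share < 0:
            raise InvalidInputError(f"{path}: negative share for ({g}, {f}, {c})")
        t.weighted_share[(f, c)] = share

    if not weighted:
        if schema is None:
            raise InvalidInputError(
                f"{path} holds raw shares (weighted=false); a severity schema is required"
            )
        tables = {g: apply_severity(t, schema) for g, t in tables.items()}
    for t in tables.values():
        importance_scores(t)
    return tables


def write_scores_json(tables: dict[str, EvidenceTable], path: str | Path) -> None:
    payload = {g: t.to_dict() for g, t in tables.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
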