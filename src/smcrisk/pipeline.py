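"""Study configuration, the end-to-end pipeline, and report rendering.

The pipeline runs the full method: normalize the severity schema, weight
the evidence shares, build one pairwise-comparison matrix per evidence
group (the criteria-level matrix is supplied by expert judgment), compute
local weights and consistency per matrix, synthesize global leaf weights
and rank them.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ahp import (
    ConsistencyReport,
    CriterionNode,
    Hierarchy,
    Ranking,
    WeightVector,
    column_normalize,
    consistency,
    lambda_max,
    rank,
    synthesize,
    weights,
)
from .errors import ConfigError, ConsistencyError
from .evidence import EvidenceTable, read_evidence_csv
from .pcm import PairwiseComparisonMatrix, SaatyQuantizer, build_from_scores, read_pcm_json
from .severity import SeveritySchema, normalize_severity, read_severity_csv

__all__ = ["StudyConfig", "Report", "run_pipeline", "render_report"]

log = logging.getLogger("smcrisk")


@dataclass
class CriterionSpec:
    name: str
    title: str = ""
    evidence_group: str | None = None
    pcm: PairwiseComparisonMatrix | None = None

    def __post_init__(self) -> None:
        if (self.evidence_group is None) == (self.pcm is None):
            raise ConfigError(
                f"criterion {self.name!r}: give exactly one of evidence_group or pcm"
            )


@dataclass
class StudyConfig:
    goal: str
    criteria_pcm: PairwiseComparisonMatrix
    criteria: list[CriterionSpec]
    severity_path: Path | None = None
    evidence_path: Path | None = None
    quantizer: SaatyQuantizer = field(default_factory=SaatyQuantizer)
    method: str = "eigen"
    strict_cr: bool = False
    tie_decimals: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: cannot parse YAML: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        base = path.parent

        def resolve(key: str) -> Path | None:
            if key not in raw or raw[key] is None:
                return None
            p = Path(raw[key])
            p = p if p.is_absolute() else base / p
            if not p.exists():
                raise ConfigError(f"{path}: referenced file {p} does not exist")
            return p

        try:
            criteria_pcm = read_pcm_json(raw["criteria_pcm"])
        except KeyError:
            raise ConfigError(f"{path}: missing criteria_pcm") from None
        criteria = []
        for c in raw.get("criteria", []):
            pcm = read_pcm_json(c["pcm"]) if "pcm" in c else None
            criteria.append(
                CriterionSpec(
                    name=c["name"],
                    title=c.get("title", c["name"]),
                    evidence_group=c.get("evidence_group"),
                    pcm=pcm,
                )
            )
        qz = raw.get("quantizer", {}) or {}
        overrides = {
            tuple(k.split("/")): float(v)
            for k, v in (qz.get("overrides") or {}).items()
        }
        return cls(
            goal=raw.get("goal", "study"),
            criteria_pcm=criteria_pcm,
            criteria=criteria,
            severity_path=resolve("severity"),
            evidence_path=resolve("evidence"),
            quantizer=SaatyQuantizer(
                ceil_threshold=float(qz.get("ceil_threshold", 0.25)),
                overrides=overrides,
            ),
            method=raw.get("method", "eigen"),
            strict_cr=bool(raw.get("strict_cr", False)),
            tie_decimals=int(raw.get("tie_decimals", 3)),
        )


@dataclass
class LevelResult:
    """Everything computed for one PCM: the matrix, its column-normalized
    form, local weights, and consistency at both precisions."""

    name: str
    pcm: PairwiseComparisonMatrix
    normalized: np.ndarray
    local_weights: WeightVector
    consistency: ConsistencyReport
    consistency_display: ConsistencyReport  # CR from λmax rounded to 4 dp


@dataclass
class Report:
    goal: str
    method: str
    quantizer_threshold: float
    severity: SeveritySchema | None
    scores: dict[str, dict[str, float]]
    levels: dict[str, LevelResult]
    global_weights: WeightVector
    ranking: Ranking

    def to_dict(self) -> dict:
        def level_dict(lv: LevelResult) -> dict:
            return {
                "labels": lv.pcm.labels,
                "pcm": lv.pcm.entries.tolist(),
                "normalized": lv.normalized.tolist(),
                "weights": lv.local_weights.as_dict(),
                "weights_display": {
                    k: round(v, 3) for k, v in lv.local_weights.as_dict().items()
                },
                "consistency": lv.consistency.as_dict(),
                "consistency_display": {
                    "lambda_max": round(lv.consistency_display.lambda_max, 4),
                    "ci": round(lv.consistency_display.ci, 6),
                    "ri": lv.consistency_display.ri,
                    "cr": round(lv.consistency_display.cr, 6),
                    "passed": lv.consistency_display.passed,
                },
            }

        return {
            "goal": self.goal,
            "settings": {
                "method": self.method,
                "quantizer_threshold": self.quantizer_threshold,
            },
            "severity": self.severity.to_dict() if self.severity else None,
            "importance_scores": {
                g: {f: s for f, s in sc.items()} for g, sc in self.scores.items()
            },
            "levels": {name: level_dict(lv) for name, lv in self.levels.items()},
            "global_weights": self.global_weights.as_dict(),
            "global_weights_display": {
                k: round(v, 3) for k, v in self.global_weights.as_dict().items()
            },
            "ranking": self.ranking.as_rows(),
        }


def _level(
    name: str,
    pcm: PairwiseComparisonMatrix,
    method: str,
) -> LevelResult:
    wv = weights(pcm, method=method)
    lam = lambda_max(pcm, wv)
    return LevelResult(
        name=name,
        pcm=pcm,
        normalized=column_normalize(pcm),
        local_weights=wv,
        consistency=consistency(lam, pcm.n),
        consistency_display=consistency(
            round(lam, 4), pcm.n, weight_convention="lambda-rounded-4dp"
        ),
    )


def run_pipeline(
    config: StudyConfig,
    evidence_tables: dict[str, EvidenceTable] | None = None,
) -> Report:
    """Execute severity → evidence → PCM → weights → consistency →
    synthesis → ranking. With ``strict_cr`` a matrix at CR >= 0.10 aborts
    the run; otherwise it is logged as a warning."""
    severity: SeveritySchema | None = None
    if config.severity_path is not None:
        severity = normalize_severity(read_severity_csv(config.severity_path))
        log.info("severity factors: %s", severity.normalized_factors)

    if evidence_tables is None:
        if config.evidence_path is None:
            evidence_tables = {}
        else:
            evidence_tables = read_evidence_csv(config.evidence_path, schema=severity)

    scores = {g: dict(t.importance_score) for g, t in evidence_tables.items()}
    log.info(
        "pipeline settings: method=%s quantizer_threshold=%s",
        config.method, config.quantizer.ceil_threshold,
    )

    levels: dict[str, LevelResult] = {"criteria": _level("criteria", config.criteria_pcm, config.method)}
    hierarchy = Hierarchy(goal=config.goal, criteria=[])
    crit_w = levels["criteria"].local_weights
    for spec in config.criteria:
        if spec.name not in config.criteria_pcm.labels:
            raise ConfigError(
                f"criterion {spec.name!r} not among criteria PCM labels "
                f"{config.criteria_pcm.labels}"
            )
        if spec.pcm is not None:
            sub_pcm = spec.pcm
        else:
            try:
                group_scores = scores[spec.evidence_group]
            except KeyError:
                raise ConfigError(
                    f"criterion {spec.name!r}: evidence group "
                    f"{spec.evidence_group!r} not found in evidence tables "
                    f"{sorted(scores)}"
                ) from None
            sub_pcm = build_from_scores(group_scores, config.quantizer)
        lv = _level(spec.name, sub_pcm, config.method)
        levels[spec.name] = lv
        hierarchy.criteria.append(
            CriterionNode(
                name=spec.name,
                local_weight=crit_w[spec.name],
                leaf_labels=list(lv.local_weights.labels),
                leaf_weights=lv.local_weights.weights,
            )
        )

    for name, lv in levels.items():
        if not lv.consistency.passed:
            msg = (
                f"stage {name!r}: CR = {lv.consistency.cr:.4f} >= 0.10 "
                f"(lambda_max = {lv.consistency.lambda_max:.4f})"
            )
            if config.strict_cr:
                raise ConsistencyError(msg)
            warnings.warn(msg, stacklevel=2)

    global_w = synthesize(hierarchy)
    ranking = rank(global_w, tie_decimals=config.tie_decimals)
    return Report(
        goal=config.goal,
        method=config.method,
        quantizer_threshold=config.quantizer.ceil_threshold,
        severity=severity,
        scores=scores,
        levels=levels,
        global_weights=global_w,
        ranking=ranking,
    )


def _text_matrix(labels: list[str], rows: np.ndarray, title: str, dp: int = 3) -> str:
    width = max(7, max(len(l) for l in labels) + 2)
    out = [title]
    out.append(" " * width + "".join(f"{l:>{width}}" for l in labels))
    for lab, row in zip(labels, rows):
        out.append(f"{lab:<{width}}" + "".join(f"{v:>{width}.{dp}f}" for v in row))
    return "\n".join(out)


def render_report(report: Report, format: str = "json") -> str:
    """Serialize a report. JSON is loss-less (full precision plus rounded
    display fields); text renders normalized matrices, weights, consistency
    and the ranking table with a ``*`` marker on tied rows."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    if format != "text":
        raise ConfigError(f"unknown report format {format!r} (use json or text)")
    parts: list[str] = [f"Goal: {report.goal}", f"Method: {report.method}"]
    for name, lv in report.levels.items():
        parts.append("")
        parts.append(_text_matrix(lv.pcm.labels, lv.normalized, f"[{name}] normalized matrix"))
        wline = ", ".join(
            f"{k}={v:.3f}" for k, v in lv.local_weights.as_dict().items()
        )
        cd = lv.consistency_display
        parts.append(f"weights: {wline}")
        parts.append(
            f"lambda_max={cd.lambda_max:.4f} CI={cd.ci:.6f} "
            f"RI={cd.ri:.2f} CR={cd.cr:.6f} "
            f"({'consistent' if cd.passed else 'INCONSISTENT'})"
        )
    parts.append("")
    parts.append("Ranking")
    parts.append(f"{'factor':<10}{'weight':>9}{'percent':>9}{'rank':>7}")
    for r in report.ranking.records:
        mark = "*" if r.tied else ""
        parts.append(
            f"{r.label:<10}{r.weight:>9.3f}{r.percent:>8d}%{r.rank:>6d}{mark}"
        )
    return "\n".join(parts) + "\n"
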