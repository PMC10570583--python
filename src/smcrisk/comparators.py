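"""Best-Worst Method (BWM) and Full Consistency Method (FUCOM) solvers.

Both are pairwise-comparison weighting methods that need far fewer
judgments than a full matrix. BWM elicits two vectors — best-to-others
a_Bj and others-to-worst a_jW — and solves

    min ξ  s.t.  |w_B/w_j − a_Bj| ≤ ξ,  |w_j/w_W − a_jW| ≤ ξ,  Σw = 1, w > 0

(the original nonlinear min-max formulation; ξ* = 0 iff the input is
perfectly consistent). FUCOM elicits a significance ordering and chained
comparative priorities φ(k/(k+1)) and solves

    min χ  s.t.  |w_k/w_{k+1} − φ(k/k+1)| ≤ χ,
                 |w_k/w_{k+2} − φ(k/k+1)·φ((k+1)/(k+2))| ≤ χ,  Σw = 1, w > 0.

Here both share the severity-weighted evidence front-end: comparison
vectors are quantized from importance-score ratios with the same Saaty
quantizer used for the AHP matrices, which is how the risk factors enter
these otherwise survey-based methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .ahp import WeightVector, rank, weights as ahp_weights
from .errors import InvalidInputError, OptimizationError
from .pcm import PairwiseComparisonMatrix, SaatyQuantizer, quantize_to_saaty

__all__ = [
    "BwmInput",
    "FucomInput",
    "derive_comparator_inputs",
    "bwm_from_pcm",
    "fucom_from_pcm",
    "bwm_weights",
    "fucom_weights",
    "MethodComparison",
    "compare_methods",
]


@dataclass
class BwmInput:
    labels: list[str]
    best_index: int
    worst_index: int
    best_to_others: np.ndarray
    others_to_worst: np.ndarray

    def __post_init__(self) -> None:
        self.best_to_others = np.asarray(self.best_to_others, dtype=float)
        self.others_to_worst = np.asarray(self.others_to_worst, dtype=float)
        n = len(self.labels)
        if self.best_to_others.shape != (n,) or self.others_to_worst.shape != (n,):
            raise InvalidInputError("comparison vectors must have one entry per label")
        if self.best_to_others[self.best_index] != 1:
            raise InvalidInputError("best-to-best comparison must be 1")
        if self.others_to_worst[self.worst_index] != 1:
            raise InvalidInputError("worst-to-worst comparison must be 1")
        if np.any(self.best_to_others < 1) or np.any(self.others_to_worst < 1):
            raise InvalidInputError("BWM intensities must be >= 1")


@dataclass
class FucomInput:
    """Labels ordered from most to least significant, with the chained
    comparative priorities φ(k/(k+1)) between consecutive criteria."""

    labels: list[str]
    comparative_priorities: np.ndarray

    def __post_init__(self) -> None:
        self.comparative_priorities = np.asarray(
            self.comparative_priorities, dtype=float
        )
        if self.comparative_priorities.shape != (len(self.labels) - 1,):
            raise InvalidInputError(
                "need exactly n-1 comparative priorities for n labels"
            )
        if np.any(self.comparative_priorities < 1):
            raise InvalidInputError("comparative priorities must be >= 1")


def derive_comparator_inputs(
    scores: dict[str, float], q: SaatyQuantizer | None = None
) -> tuple[BwmInput, FucomInput]:
    """Build BWM and FUCOM inputs from importance scores.

    Best/worst are the score argmax/argmin (ties broken by label order with
    a warning); all intensities are score ratios quantized with the same
    Saaty quantizer as the AHP matrices.
    """
    q = q or SaatyQuantizer()
    labels = list(scores)
    if len(labels) < 2:
        raise InvalidInputError("need at least two factors")
    vals = np.array([scores[l] for l in labels], dtype=float)
    if np.any(vals <= 0):
        raise InvalidInputError(f"scores must be positive, got {scores}")
    best = int(np.argmax(vals))
    worst = int(np.argmin(vals))
    if np.sum(vals == vals[best]) > 1 or np.sum(vals == vals[worst]) > 1:
        warnings.warn(
            "tied best/worst scores; ties broken by label order", stacklevel=2
        )
    bto = np.array([quantize_to_saaty(vals[best] / v, q) for v in vals])
    otw = np.array([quantize_to_saaty(v / vals[worst], q) for v in vals])
    bto[best] = 1.0
    otw[worst] = 1.0
    bwm = BwmInput(
        labels=labels, best_index=best, worst_index=worst,
        best_to_others=bto, others_to_worst=otw,
    )
    order = sorted(range(len(labels)), key=lambda i: (-vals[i], labels[i]))
    phi = np.array(
        [
            quantize_to_saaty(max(vals[order[k]] / vals[order[k + 1]], 1.0), q)
            for k in range(len(order) - 1)
        ]
    )
    fucom = FucomInput(labels=[labels[i] for i in order], comparative_priorities=phi)
    return bwm, fucom


def bwm_from_pcm(pcm: PairwiseComparisonMatrix) -> BwmInput:
    """Read BWM vectors straight off an expert PCM: the best row gives
    best-to-others, the worst column gives others-to-worst."""
    w = ahp_weights(pcm).weights
    best = int(np.argmax(w))
    worst = int(np.argmin(w))
    bto = np.maximum(pcm.entries[best, :], 1.0)
    otw = np.maximum(pcm.entries[:, worst], 1.0)
    bto[best] = 1.0
    otw[worst] = 1.0
    return BwmInput(
        labels=list(pcm.labels), best_index=best, worst_index=worst,
        best_to_others=bto, others_to_worst=otw,
    )


def fucom_from_pcm(pcm: PairwiseComparisonMatrix) -> FucomInput:
    """Chain an expert PCM's entries along its priority order into FUCOM
    comparative priorities."""
    w = ahp_weights(pcm).weights
    order = sorted(range(pcm.n), key=lambda i: (-w[i], pcm.labels[i]))
    phi = np.array(
        [
            max(pcm.entries[order[k], order[k + 1]], 1.0)
            for k in range(pcm.n - 1)
        ]
    )
    return FucomInput(
        labels=[pcm.labels[i] for i in order], comparative_priorities=phi
    )


def _minimax_solve(
    n: int,
    constraint_terms,  # list of callables w -> deviation that must be <= xi
    starts: list[np.ndarray],
) -> tuple[np.ndarray, float]:
    """Minimize the max deviation over the open simplex via SLSQP multi-start.

    Decision vector is (w_1..w_n, xi); constraints are xi - dev >= 0 plus
    the simplex equality and positivity bounds.
    """
    cons = [{"type": "eq", "fun": lambda x: np.sum(x[:-1]) - 1.0}]
    for term in constraint_terms:
        cons.append({"type": "ineq", "fun": lambda x, t=term: x[-1] - t(x[:-1])})
    bounds = [(1e-9, 1.0)] * n + [(0.0, None)]
    best: tuple[np.ndarray, float] | None = None
    for w0 in starts:
        xi0 = max(t(w0) for t in constraint_terms)
        x0 = np.concatenate([w0, [xi0]])
        res = minimize(
            lambda x: x[-1], x0, method="SLSQP", bounds=bounds, constraints=cons,
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if not res.success:
            continue
        w = np.clip(res.x[:-1], 1e-12, None)
        w = w / w.sum()
        xi = max(t(w) for t in constraint_terms)
        if best is None or xi < best[1]:
            best = (w, xi)
    if best is None:
        raise OptimizationError("min-max solver failed from every start point")
    return best


def _default_starts(n: int, hint: np.ndarray | None = None) -> list[np.ndarray]:
    starts = [np.full(n, 1.0 / n)]
    if hint is not None:
        h = np.clip(np.asarray(hint, dtype=float), 1e-6, None)
        starts.append(h / h.sum())
    # deterministic spread of corners pulled toward the interior
    for i in range(n):
        w = np.full(n, 0.5 / max(n - 1, 1))
        w[i] = 0.5
        starts.append(w / w.sum())
    return starts


def bwm_weights(inp: BwmInput) -> tuple[WeightVector, float]:
    """Solve the nonlinear BWM program; returns (weights, ξ*)."""
    n = len(inp.labels)
    b, wst = inp.best_index, inp.worst_index
    terms = []
    for j in range(n):
        if j != b:
            terms.append(
                lambda w, j=j: abs(w[b] / w[j] - inp.best_to_others[j])
            )
        if j != wst:
            terms.append(
                lambda w, j=j: abs(w[j] / w[wst] - inp.others_to_worst[j])
            )
    # consistency hint: weights proportional to 1/a_Bj reproduce the best row
    hint = 1.0 / np.asarray(inp.best_to_others, dtype=float)
    w, xi = _minimax_solve(n, terms, _default_starts(n, hint))
    return WeightVector(labels=list(inp.labels), weights=w), float(xi)


def fucom_weights(inp: FucomInput) -> tuple[WeightVector, float]:
    """Solve the FUCOM program; returns (weights, χ). χ = 0 when the
    priorities chain transitively."""
    n = len(inp.labels)
    phi = inp.comparative_priorities
    terms = []
    for k in range(n - 1):
        terms.append(lambda w, k=k: abs(w[k] / w[k + 1] - phi[k]))
    for k in range(n - 2):
        terms.append(
            lambda w, k=k: abs(w[k] / w[k + 2] - phi[k] * phi[k + 1])
        )
    # consistency hint: chain the priorities down from the top criterion
    hint = np.ones(n)
    for k in range(1, n):
        hint[k] = hint[k - 1] / phi[k - 1]
    w, chi = _minimax_solve(n, terms, _default_starts(n, hint))
    return WeightVector(labels=list(inp.labels), weights=w), float(chi)


@dataclass
class MethodComparison:
    """Per-leaf global weights and competition ranks for each method."""

    leaf_labels: list[str]
    weights_by_method: dict[str, dict[str, float]] = field(default_factory=dict)
    ranks_by_method: dict[str, dict[str, int]] = field(default_factory=dict)
    max_divergence: float = 0.0

    def as_dict(self) -> dict:
        return {
            "leaves": list(self.leaf_labels),
            "weights": self.weights_by_method,
            "ranks": self.ranks_by_method,
            "max_divergence": self.max_divergence,
        }


def compare_methods(
    criteria_pcm: PairwiseComparisonMatrix,
    group_scores: dict[str, dict[str, float]],
    criteria_groups: dict[str, str],
    q: SaatyQuantizer | None = None,
) -> MethodComparison:
    """Run the AHP route and the BWM/FUCOM routes over one hierarchy.

    ``group_scores`` maps evidence-group name → per-leaf importance scores;
    ``criteria_groups`` maps criterion label (a criteria_pcm label) → group
    name. Criteria-level BWM/FUCOM inputs come from the expert PCM itself;
    sub-criteria inputs from quantized score ratios.
    """
    q = q or SaatyQuantizer()

    def crit_weights(method: str) -> WeightVector:
        if method == "ahp":
            return ahp_weights(criteria_pcm)
        if method == "bwm":
            return bwm_weights(bwm_from_pcm(criteria_pcm))[0]
        return fucom_weights(fucom_from_pcm(criteria_pcm))[0]

    def leaf_weights(method: str, scores: dict[str, float]) -> WeightVector:
        if method == "ahp":
            from .pcm import build_from_scores

            return ahp_weights(build_from_scores(scores, q))
        bwm_in, fucom_in = derive_comparator_inputs(scores, q)
        if method == "bwm":
            return bwm_weights(bwm_in)[0]
        return fucom_weights(fucom_in)[0]

    comparison = MethodComparison(leaf_labels=[])
    all_weights: dict[str, dict[str, float]] = {}
    for method in ("ahp", "bwm", "fucom"):
        cw = crit_weights(method)
        glob: dict[str, float] = {}
        for crit_label, group in criteria_groups.items():
            lw = leaf_weights(method, group_scores[group])
            for leaf, w in lw.as_dict().items():
                glob[leaf] = w * cw[crit_label]
        all_weights[method] = glob
    leaves = list(next(iter(all_weights.values())))
    comparison.leaf_labels = leaves
    for method, glob in all_weights.items():
        total = sum(glob.values())
        glob = {k: v / total for k, v in glob.items()}
        wv = WeightVector(labels=leaves, weights=np.array([glob[l] for l in leaves]))
        rk = rank(wv)
        comparison.weights_by_method[method] = glob
        comparison.ranks_by_method[method] = {
            r.label: r.rank for r in rk.records
        }
    for la in leaves:
        vals = [all_weights[m][la] for m in all_weights]
        comparison.max_divergence = max(
            comparison.max_divergence, max(vals) - min(vals)
        )
    return comparison
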