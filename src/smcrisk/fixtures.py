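"""Packaged US-2019 case-study inputs and synthetic PCM generation.

``us2019_fixture`` loads the shipped road-crash case study: the severity
schema (fatal / major-injury / minor-property classes with their average
costs and 2019 counts), the severity-weighted evidence shares for the nine
risk factors R1–R9, and the study configuration with the expert-supplied
criteria matrix over C1 (environment), C2 (driver state), C3 (driver
behavior).

``generate_pcm`` draws synthetic matrices with controlled consistency: a
ground-truth weight vector from a Dirichlet, exact ratio entries perturbed
by a reciprocity-preserving multiplicative log-normal noise, optionally
Saaty-quantized. The log-normal perturbation keeps a_ji = 1/a_ij exact
while degrading transitivity smoothly, so sigma dials the consistency
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import InvalidInputError
from .evidence import EvidenceTable, read_evidence_csv
from .pcm import PairwiseComparisonMatrix, SaatyQuantizer, quantize_to_saaty
from .pipeline import StudyConfig
from .severity import SeveritySchema, normalize_severity, read_severity_csv

__all__ = ["SyntheticSpec", "us2019_fixture", "data_path", "generate_pcm"]


def data_path(name: str) -> Path:
    """Path of a packaged data file."""
    return Path(resources.files("smcrisk.data") / name)


def us2019_fixture() -> tuple[SeveritySchema, dict[str, EvidenceTable], StudyConfig]:
    """The complete US-2019 case study as (severity, evidence, config)."""
    schema = normalize_severity(read_severity_csv(data_path("us2019_severity.csv")))
    tables = read_evidence_csv(data_path("us2019_evidence.csv"))
    config = StudyConfig.from_yaml(data_path("us2019_study.yaml"))
    return schema, tables, config


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic PCM.

    ``dirichlet_alpha`` is the symmetric concentration of the ground-truth
    weights; ``noise_sigma`` the standard deviation of the log-normal
    multiplicative perturbation on the upper-triangle ratios.
    """

    n_factors: int
    dirichlet_alpha: float = 1.0
    noise_sigma: float = 0.0
    quantize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_factors < 2:
            raise InvalidInputError(f"n_factors must be >= 2, got {self.n_factors}")
        if self.noise_sigma < 0:
            raise InvalidInputError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.dirichlet_alpha <= 0:
            raise InvalidInputError(
                f"dirichlet_alpha must be > 0, got {self.dirichlet_alpha}"
            )


def generate_pcm(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, PairwiseComparisonMatrix]:
    """Draw (ground-truth weights, PCM) deterministically under the seed.

    Entries are a_ij = (w_i/w_j)·exp(ε_ij) with ε_ij ~ N(0, σ²) and
    ε_ji = −ε_ij, so reciprocity is exact for every σ.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_factors
    w = rng.dirichlet(np.full(n, spec.dirichlet_alpha))
    # keep ratios clear of the Saaty clamp region under quantization
    w = np.clip(w, 1e-3, None)
    w = w / w.sum()
    a = np.ones((n, n))
    q = SaatyQuantizer()
    for i in range(n):
        for j in range(i + 1, n):
            eps = rng.normal(0.0, spec.noise_sigma) if spec.noise_sigma > 0 else 0.0
            val = (w[i] / w[j]) * np.exp(eps)
            if spec.quantize:
                val = quantize_to_saaty(val, q)
            a[i, j] = val
            a[j, i] = 1.0 / val
    labels = [f"F{k + 1}" for k in range(n)]
    return w, PairwiseComparisonMatrix(labels=labels, entries=a)
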