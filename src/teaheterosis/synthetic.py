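"""Synthetic data with known ground truth for the 4-genotype design.

The expression generator plants genes into the ten expression-pattern
classes at configurable proportions.  Each class fixes an ordering of the
four genotype means on a geometric ladder with common ratio ``effect_fold``
(the true fold separation between any two "different" levels), e.g.

    C9 :  both hybrid means = baseline * fold,  parents = baseline
    C5 :  P1 = H1 = H2 = baseline * fold,       P2 = baseline
    C1 :  P1 = b*f^3 > H1 = b*f^2 > H2 = b*f > P2 = b

Replicates are drawn log-normally around the group mean with a given
coefficient of variation (mean-preserving parameterisation), so the cv -> 0
limit returns the exact group means.  The volatile generator builds a
replicate concentration table from stated per-genotype class means the same
way.  All randomness flows from a single seeded generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .patterns import ExpressionMatrix, ROLES
from .volatiles import VolatileTable

PATTERN_CLASSES = tuple(f"C{i}" for i in range(1, 11)) + ("none",)

#: group-mean exponents (powers of effect_fold) per class, role order
#: (parent1, parent2, hybrid1, hybrid2)
_CLASS_EXPONENTS: dict[str, tuple[int, int, int, int]] = {
    "C1": (3, 0, 2, 1),   # P1 > H1 > H2 > P2
    "C2": (2, 0, 1, 1),   # P1 > H1 = H2 > P2
    "C3": (0, 3, 1, 2),   # P2 > H2 > H1 > P1
    "C4": (0, 2, 1, 1),   # P2 > H1 = H2 > P1
    "C5": (1, 0, 1, 1),   # high parent P1, hybrids at P1
    "C6": (0, 1, 1, 1),   # high parent P2, hybrids at P2
    "C7": (1, 0, 0, 0),   # hybrids at the low parent (P2)
    "C8": (0, 1, 0, 0),   # hybrids at the low parent (P1)
    "C9": (0, 0, 1, 1),   # hybrids above both parents
    "C10": (1, 1, 0, 0),  # hybrids below both parents
    "none": (0, 0, 0, 0),
}


@dataclass
class SimulationConfig:
    """Study-condition knobs for the expression simulator.

    Defaults mirror a 4-genotype x 3-replicate FPKM-like design with a
    4-fold true effect and 5% replicate noise.
    """

    n_genes: int = 2000
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            # roughly the study's mixture: mostly unchanged genes, dominance
            # outweighing additivity, overdominance rarest
            "none": 0.744,
            "C1": 0.01, "C2": 0.01, "C3": 0.01, "C4": 0.01,
            "C5": 0.046, "C6": 0.045,
            "C7": 0.028, "C8": 0.028,
            "C9": 0.038, "C10": 0.031,
        }
    )
    baseline_mean: float = 10.0
    effect_fold: float = 4.0
    replicate_cv: float = 0.05
    n_replicates: int = 3
    seed: int = 0
    fc_threshold: float = 2.0  # downstream fold-change gate, for the sanity warning

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 (pairwise test undefined)")
        if not 0 <= self.replicate_cv < 1:
            raise ValueError("replicate_cv must lie in [0, 1)")
        unknown = set(self.class_proportions) - set(PATTERN_CLASSES)
        if unknown:
            raise ValueError(f"unknown pattern classes: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"class proportions sum to {total!r}, expected 1"
            )
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("negative class proportion")
        if self.effect_fold < self.fc_threshold:
            warnings.warn(
                f"effect_fold {self.effect_fold} is below the downstream "
                f"fold-change threshold {self.fc_threshold}; planted effects "
                "will not be recoverable",
                stacklevel=2,
            )


@dataclass
class LabeledMatrix:
    matrix: ExpressionMatrix
    truth: dict[str, str]

    def __post_init__(self) -> None:
        genes = set(map(str, self.matrix.gene_ids))
        if genes != set(self.truth):
            raise ValueError("truth labels do not cover the matrix genes exactly")


def _lognormal_around(
    rng: np.random.Generator, means: np.ndarray, cv: float
) -> np.ndarray:
    """Mean-preserving log-normal draws: E[X] = means, sd/mean = cv."""
    if cv == 0:
        return means.copy()
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    # E[exp(N(mu, s^2))] = exp(mu + s^2/2) -> mu = ln(mean) - s^2/2
    return means * np.exp(rng.normal(-sigma2 / 2.0, sigma, size=means.shape))


def _allot_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n genes over the classes."""
    items = [(c, proportions[c]) for c in PATTERN_CLASSES if c in proportions]
    raw = [(c, n * p) for c, p in items]
    counts = {c: int(np.floor(x)) for c, x in raw}
    short = n - sum(counts.values())
    remainders = sorted(raw, key=lambda cx: (cx[1] - np.floor(cx[1])), reverse=True)
    for c, _ in remainders[:short]:
        counts[c] += 1
    return counts


def generate_expression(config: SimulationConfig) -> LabeledMatrix:
    """Simulate a labeled 4-genotype expression matrix.

    Deterministic given the seed; at replicate_cv = 0 group means are exact.
    """
    rng = np.random.default_rng(config.seed)
    counts = _allot_counts(config.n_genes, config.class_proportions)
    truth: dict[str, str] = {}
    gene_ids: list[str] = []
    mean_rows: list[np.ndarray] = []
    i = 0
    for cls in PATTERN_CLASSES:
        for _ in range(counts.get(cls, 0)):
            gid = f"gene_{i:05d}"
            gene_ids.append(gid)
            truth[gid] = cls
            exps = np.array(_CLASS_EXPONENTS[cls], dtype=float)
            mean_rows.append(config.baseline_mean * config.effect_fold**exps)
            i += 1
    means = np.vstack(mean_rows)  # (genes, 4 roles)
    n_rep = config.n_replicates
    sample_ids = [f"{role}_r{r + 1}" for role in ROLES for r in range(n_rep)]
    per_sample_means = np.repeat(means, n_rep, axis=1)
    values = _lognormal_around(rng, per_sample_means, config.replicate_cv)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        design=pd.DataFrame(
            {
                "genotype_role": [role for role in ROLES for _ in range(n_rep)],
                "replicate": [r + 1 for _ in ROLES for r in range(n_rep)],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )
    return LabeledMatrix(matrix=matrix, truth=truth)


def generate_volatile_table(
    per_class_means: Mapping[str, tuple[float, float, float, float]],
    cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
    genotype_names: tuple[str, str, str, str] = ("parent1", "parent2", "hybrid1", "hybrid2"),
) -> VolatileTable:
    """Simulate a replicate volatile-concentration table.

    ``per_class_means`` maps a compound class to its (p1, p2, h1, h2) class
    totals; one synthetic compound carries each class, so class sums at
    cv -> 0 equal the stated means exactly.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for cls, means in per_class_means.items():
        means_arr = np.asarray(means, dtype=float)
        if means_arr.shape != (4,):
            raise ValueError(f"class {cls!r}: need exactly 4 genotype means")
        if (means_arr <= 0).any():
            raise ValueError(f"class {cls!r}: all means must be positive")
        for genotype, mean in zip(genotype_names, means_arr):
            draws = _lognormal_around(
                rng, np.full(n_replicates, mean), cv
            )
            for rep, conc in enumerate(draws, start=1):
                rows.append(
                    {
                        "compound": f"{cls}_compound",
                        "compound_class": cls,
                        "genotype": genotype,
                        "replicate": rep,
                        "concentration": float(conc),
                    }
                )
    return VolatileTable(pd.DataFrame(rows))
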