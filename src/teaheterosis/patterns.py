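"""Expression-level dominance classification for a 2-parent / 2-hybrid design.

Each gene in a four-genotype (parent1, parent2, hybrid1, hybrid2) replicated
expression matrix is assigned to one of ten expression modes:

===========  ==============================  =========================
cluster      pattern (statistical ordering)  category
===========  ==============================  =========================
C1           P1 > H1 > H2 > P2 (P1 high)     additive
C2           P1 > H1 = H2 > P2 (P1 high)     additive
C3           P2 > H2 > H1 > P1 (P2 high)     additive
C4           P2 > H1 = H2 > P1 (P2 high)     additive
C5           P1 = H1 = H2 > P2               higher-parent dominance
C6           P2 = H1 = H2 > P1               higher-parent dominance
C7           P1 > H1 = H2 = P2               lower-parent dominance
C8           P2 > H1 = H2 = P1               lower-parent dominance
C9           hybrids > both parents          up-overdominance
C10          hybrids < both parents          down-overdominance
===========  ==============================  =========================

"A > B" means statistically higher: two-sided Welch t-test on
log2(expression + pseudocount) with p below ``alpha`` AND a raw fold change
of at least ``fc_min``.  Genes whose six pairwise calls fit none of the
patterns (including hybrids with conflicting evidence) are ``unclassified``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ROLES = ("parent1", "parent2", "hybrid1", "hybrid2")

#: the six unordered genotype pairs, in canonical order
PAIRS = (
    ("parent1", "parent2"),
    ("parent1", "hybrid1"),
    ("parent1", "hybrid2"),
    ("parent2", "hybrid1"),
    ("parent2", "hybrid2"),
    ("hybrid1", "hybrid2"),
)

CLUSTERS = tuple(f"C{i}" for i in range(1, 11)) + ("unclassified",)

CATEGORY_OF_CLUSTER = {
    "C1": "additive",
    "C2": "additive",
    "C3": "additive",
    "C4": "additive",
    "C5": "higher-parent dominance",
    "C6": "higher-parent dominance",
    "C7": "lower-parent dominance",
    "C8": "lower-parent dominance",
    "C9": "up-overdominance",
    "C10": "down-overdominance",
    "unclassified": "unclassified",
}

CATEGORIES = (
    "additive",
    "higher-parent dominance",
    "lower-parent dominance",
    "up-overdominance",
    "down-overdominance",
    "unclassified",
)

NON_ADDITIVE_CLUSTERS = ("C5", "C6", "C7", "C8", "C9", "C10")

DEFAULT_PSEUDOCOUNT = 0.1


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values with a genotype design.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.
    design
        DataFrame indexed by sample id with columns ``genotype_role``
        (one of :data:`ROLES`) and ``replicate``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples absent from design: {sorted(missing)}")
        roles = self.design.loc[list(self.values.columns), "genotype_role"]
        bad = set(roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown genotype roles: {sorted(bad)}")
        absent = [r for r in ROLES if (roles == r).sum() == 0]
        if absent:
            raise ValueError("role " + ", ".join(absent) + " absent")
        few = [r for r in ROLES if (roles == r).sum() < 2]
        if few:
            raise ValueError(
                f"roles with fewer than 2 replicates: {few}; the pairwise "
                "test is undefined"
            )
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples_for(self, role: str) -> list[str]:
        """Sample ids belonging to one genotype role, in matrix column order."""
        roles = self.design.loc[list(self.values.columns), "genotype_role"]
        return [s for s, r in zip(self.values.columns, roles) if r == role]

    def role_values(self, role: str) -> np.ndarray:
        """(n_genes, n_replicates) array for one genotype role."""
        return self.values[self.samples_for(role)].to_numpy(dtype=float)

    def role_means(self) -> pd.DataFrame:
        """Per-gene genotype means, columns ordered as :data:`ROLES`."""
        return pd.DataFrame(
            {role: self.role_values(role).mean(axis=1) for role in ROLES},
            index=self.gene_ids,
        )


@dataclass
class PairwiseCall:
    """Result of one statistical comparison between two genotype groups."""

    gene_id: str
    pair: tuple[str, str]
    log2_fc: float
    p: float
    call: str  # higher | lower | similar
    q: float | None = None

    def reversed(self) -> "PairwiseCall":
        flip = {"higher": "lower", "lower": "higher", "similar": "similar"}
        return PairwiseCall(
            gene_id=self.gene_id,
            pair=(self.pair[1], self.pair[0]),
            log2_fc=-self.log2_fc,
            p=self.p,
            call=flip[self.call],
            q=self.q,
        )


@dataclass
class PatternAssignment:
    gene_id: str
    cluster: str
    category: str = field(init=False)

    def __post_init__(self) -> None:
        if self.cluster not in CATEGORY_OF_CLUSTER:
            raise ValueError(f"unknown cluster {self.cluster!r}")
        self.category = CATEGORY_OF_CLUSTER[self.cluster]


@dataclass
class PatternSummary:
    """Counts and fractions per cluster/category.

    ``fraction_of_total`` divides by all genes, ``fraction_of_classified``
    by genes that received a C1-C10 cluster, and
    ``fraction_of_non_additive`` divides the non-additive categories
    (C5-C10) by the non-additive total.
    """

    n_genes: int
    cluster_counts: dict[str, int]
    category_counts: dict[str, int]
    n_additive: int
    n_non_additive: int

    def fraction_of_total(self, key: str) -> float:
        n = self.category_counts.get(key, self.cluster_counts.get(key, 0))
        return n / self.n_genes if self.n_genes else 0.0

    def fraction_of_classified(self, key: str) -> float:
        n_classified = self.n_genes - self.category_counts.get("unclassified", 0)
        if n_classified == 0:
            return 0.0
        n = self.category_counts.get(key, self.cluster_counts.get(key, 0))
        return n / n_classified

    def fraction_of_non_additive(self, key: str) -> float:
        if self.n_non_additive == 0:
            return 0.0
        n = self.category_counts.get(key, self.cluster_counts.get(key, 0))
        return n / self.n_non_additive

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "cluster_counts": dict(self.cluster_counts),
            "category_counts": dict(self.category_counts),
            "n_additive": self.n_additive,
            "n_non_additive": self.n_non_additive,
            "fraction_of_total": {
                c: self.fraction_of_total(c) for c in CATEGORIES
            },
            "fraction_of_non_additive": {
                c: self.fraction_of_non_additive(c)
                for c in CATEGORIES
                if c not in ("additive", "unclassified")
            },
        }


@dataclass
class QpcrMeasurement:
    """Ct quadruple for relative quantification against a reference gene."""

    ct_target_test: float
    ct_ref_test: float
    ct_target_cal: float
    ct_ref_cal: float


# ---------------------------------------------------------------------------
# pairwise statistical call
# ---------------------------------------------------------------------------

def _welch_log2(a: np.ndarray, b: np.ndarray, pseudocount: float) -> float:
    """Two-sided Welch t-test p on log2(x + pseudocount); scalar groups."""
    la = np.log2(np.asarray(a, dtype=float) + pseudocount)
    lb = np.log2(np.asarray(b, dtype=float) + pseudocount)
    if la.std(ddof=1) == 0.0 and lb.std(ddof=1) == 0.0:
        # degenerate: no within-group variance, decide on means alone
        return 0.0 if not math.isclose(la.mean(), lb.mean()) else 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(la, lb, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


def pairwise_call(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
    fc_min: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    gene_id: str = "",
    pair: tuple[str, str] = ("A", "B"),
    p_value: float | None = None,
) -> PairwiseCall:
    """Call one group higher/lower/similar to another.

    ``higher`` requires both statistical evidence (p below ``alpha``) and a
    mean fold change of at least ``fc_min`` (computed on pseudocounted
    means).  ``p_value`` lets a caller plug in an externally computed
    p-value (e.g. from a count-based differential test) in place of the
    built-in Welch t-test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    mean_a = a.mean() + pseudocount
    mean_b = b.mean() + pseudocount
    log2_fc = math.log2(mean_a / mean_b)
    if not a.any() and not b.any():
        return PairwiseCall(gene_id, pair, 0.0, 1.0, "similar")
    p = _welch_log2(a, b, pseudocount) if p_value is None else float(p_value)
    call = "similar"
    if p < alpha:
        if mean_a / mean_b >= fc_min:
            call = "higher"
        elif mean_b / mean_a >= fc_min:
            call = "lower"
    return PairwiseCall(gene_id, pair, log2_fc, p, call)


# ---------------------------------------------------------------------------
# per-gene classification from the six calls
# ---------------------------------------------------------------------------

def _call_lookup(calls: Iterable[PairwiseCall]) -> dict[tuple[str, str], str]:
    table: dict[tuple[str, str], str] = {}
    for c in calls:
        table[c.pair] = c.call
        table[c.pair[::-1]] = c.reversed().call
    for pair in PAIRS:
        if pair not in table:
            raise ValueError(f"missing pairwise call for {pair}")
    return table


def classify_gene(calls: Iterable[PairwiseCall], gene_id: str | None = None) -> PatternAssignment:
    """Assign one gene to a cluster from its six pairwise calls.

    Decision order: overdominance (C9/C10) first, then dominance toward one
    parent (C5-C8), then additive (C1-C4), else unclassified.  Every mode is
    defined jointly over both hybrids; conflicting hybrids fall through to
    unclassified.
    """
    calls = list(calls)
    if gene_id is None:
        gene_id = calls[0].gene_id if calls else ""
    rel = _call_lookup(calls)

    def c(a: str, b: str) -> str:
        return rel[(a, b)]

    hyb_vs = {
        p: (c("hybrid1", p), c("hybrid2", p)) for p in ("parent1", "parent2")
    }
    # overdominance: both hybrids beyond both parents
    if all(v == "higher" for vs in hyb_vs.values() for v in vs):
        return PatternAssignment(gene_id, "C9")
    if all(v == "lower" for vs in hyb_vs.values() for v in vs):
        return PatternAssignment(gene_id, "C10")

    parents = c("parent1", "parent2")
    if parents == "similar":
        return PatternAssignment(gene_id, "unclassified")
    high, low = (
        ("parent1", "parent2") if parents == "higher" else ("parent2", "parent1")
    )
    at_high = all(v == "similar" for v in hyb_vs[high]) and all(
        v == "higher" for v in hyb_vs[low]
    )
    if at_high:
        return PatternAssignment(gene_id, "C5" if high == "parent1" else "C6")
    at_low = all(v == "similar" for v in hyb_vs[low]) and all(
        v == "lower" for v in hyb_vs[high]
    )
    if at_low:
        return PatternAssignment(gene_id, "C7" if high == "parent1" else "C8")
    between = all(v == "lower" for v in hyb_vs[high]) and all(
        v == "higher" for v in hyb_vs[low]
    )
    if between:
        hybrids_equal = c("hybrid1", "hybrid2") == "similar"
        if high == "parent1":
            return PatternAssignment(gene_id, "C2" if hybrids_equal else "C1")
        return PatternAssignment(gene_id, "C4" if hybrids_equal else "C3")
    return PatternAssignment(gene_id, "unclassified")


# ---------------------------------------------------------------------------
# whole-matrix classification (vectorised Welch t per genotype pair)
# ---------------------------------------------------------------------------

def _vector_calls(
    a: np.ndarray,
    b: np.ndarray,
    alpha: float,
    fc_min: float,
    pseudocount: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene (log2_fc, p, call-code) for two (genes x reps) blocks.

    Call codes: 1 = higher, -1 = lower, 0 = similar.
    """
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(la, lb, axis=1, equal_var=False).pvalue
    # both groups flat: p undefined -> 0 when log-means differ, 1 when equal
    flat = (la.std(axis=1, ddof=1) == 0) & (lb.std(axis=1, ddof=1) == 0)
    mean_la, mean_lb = la.mean(axis=1), lb.mean(axis=1)
    p = np.where(flat, np.where(np.isclose(mean_la, mean_lb), 1.0, 0.0), p)
    p = np.where(np.isnan(p), 1.0, p)
    ma = a.mean(axis=1) + pseudocount
    mb = b.mean(axis=1) + pseudocount
    both_zero = (a.sum(axis=1) == 0) & (b.sum(axis=1) == 0)
    p = np.where(both_zero, 1.0, p)
    log2_fc = np.log2(ma / mb)
    call = np.zeros(a.shape[0], dtype=int)
    sig = p < alpha
    call[sig & (ma / mb >= fc_min)] = 1
    call[sig & (mb / ma >= fc_min)] = -1
    return log2_fc, p, call


def classify_matrix(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    use_q: bool = False,
) -> list[PatternAssignment]:
    """Classify every gene in the matrix.

    With ``use_q`` the six per-pair p-value vectors are each BH-adjusted
    across genes before thresholding (a q < alpha gate instead of raw p).
    """
    assignments, _ = classify_matrix_with_calls(
        matrix, alpha=alpha, fc_min=fc_min, pseudocount=pseudocount, use_q=use_q
    )
    return assignments


def classify_matrix_with_calls(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    use_q: bool = False,
) -> tuple[list[PatternAssignment], pd.DataFrame]:
    """Like :func:`classify_matrix` but also return the per-gene call table."""
    blocks = {role: matrix.role_values(role) for role in ROLES}
    per_pair: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for a_role, b_role in PAIRS:
        lfc, p, call = _vector_calls(
            blocks[a_role], blocks[b_role], alpha, fc_min, pseudocount
        )
        if use_q:
            from statsmodels.stats.multitest import multipletests

            q = multipletests(p, method="fdr_bh")[1]
            ma = blocks[a_role].mean(axis=1) + pseudocount
            mb = blocks[b_role].mean(axis=1) + pseudocount
            call = np.zeros_like(call)
            sig = q < alpha
            call[sig & (ma / mb >= fc_min)] = 1
            call[sig & (mb / ma >= fc_min)] = -1
            p = q
        per_pair[(a_role, b_role)] = (lfc, p, call)

    code_to_call = {1: "higher", -1: "lower", 0: "similar"}
    assignments: list[PatternAssignment] = []
    rows = []
    for i, gene in enumerate(matrix.gene_ids):
        calls = [
            PairwiseCall(
                gene_id=str(gene),
                pair=pair,
                log2_fc=float(per_pair[pair][0][i]),
                p=float(per_pair[pair][1][i]),
                call=code_to_call[int(per_pair[pair][2][i])],
            )
            for pair in PAIRS
        ]
        assignment = classify_gene(calls, gene_id=str(gene))
        assignments.append(assignment)
        row: dict[str, object] = {"gene_id": str(gene), "cluster": assignment.cluster,
                                  "category": assignment.category}
        for call in calls:
            key = f"{call.pair[0]}_vs_{call.pair[1]}"
            row[f"{key}_log2fc"] = call.log2_fc
            row[f"{key}_p"] = call.p
            row[f"{key}_call"] = call.call
        rows.append(row)
    return assignments, pd.DataFrame(rows).set_index("gene_id")


def summarize_patterns(assignments: Sequence[PatternAssignment]) -> PatternSummary:
    """Tabulate cluster/category counts and the additive vs non-additive split."""
    if not assignments:
        raise ValueError("empty assignment list")
    cluster_counts = {c: 0 for c in CLUSTERS}
    for a in assignments:
        cluster_counts[a.cluster] += 1
    category_counts = {c: 0 for c in CATEGORIES}
    for a in assignments:
        category_counts[a.category] += 1
    n_non_additive = sum(cluster_counts[c] for c in NON_ADDITIVE_CLUSTERS)
    return PatternSummary(
        n_genes=len(assignments),
        cluster_counts=cluster_counts,
        category_counts=category_counts,
        n_additive=category_counts["additive"],
        n_non_additive=n_non_additive,
    )


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

def delta_delta_ct(m: QpcrMeasurement) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,cal - Ct_ref,cal);
    returns the fold change 2**(-ddCt) of the target in the test sample
    relative to the calibrator, normalised to the reference gene.
    """
    for v in (m.ct_target_test, m.ct_ref_test, m.ct_target_cal, m.ct_ref_cal):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (m.ct_target_test - m.ct_ref_test) - (m.ct_target_cal - m.ct_ref_cal)
    return 2.0 ** (-ddct)
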