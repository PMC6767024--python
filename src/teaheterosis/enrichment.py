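"""Over-representation analysis against user-supplied term-to-gene maps.

One-sided hypergeometric upper-tail test (equivalent to a one-sided Fisher
exact test) of a query gene set against each term, with Benjamini-Hochberg
FDR across all tested terms.  No annotation database ships with the
package: term maps are inputs (GMT format).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class TermMap:
    """term id -> member genes, with an explicit background universe."""

    terms: dict[str, set[str]]
    background: set[str]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.terms.items():
            stray = members - self.background
            if stray:
                raise ValueError(
                    f"term {term!r} has members outside the background: "
                    f"{sorted(stray)[:5]}"
                )


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    gene_ratio: int  # overlap count between query and term
    term_size: int
    p: float
    fdr: float
    overlap_genes: tuple[str, ...] = ()


def hypergeom_tail(
    overlap: int, term_size: int, query_size: int, background_size: int
) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(background, term, query).

    The chance of drawing at least ``overlap`` term members when sampling
    ``query_size`` genes without replacement from the background.
    """
    if min(overlap, term_size, query_size, background_size) < 0:
        raise ValueError("counts must be non-negative")
    if overlap > min(term_size, query_size):
        raise ValueError(
            f"overlap {overlap} exceeds min(term_size={term_size}, "
            f"query_size={query_size})"
        )
    if max(term_size, query_size) > background_size:
        raise ValueError("term/query larger than the background")
    return float(stats.hypergeom.sf(overlap - 1, background_size, term_size, query_size))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    if len(pvalues) == 0:
        raise ValueError("empty p-value list")
    if any(p < 0 or p > 1 for p in pvalues):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(list(pvalues), method="fdr_bh")[1])


def ora(
    query: Iterable[str],
    term_map: TermMap,
    min_term_size: int = 2,
) -> list[EnrichmentRow]:
    """Over-representation of a query gene set in every term, BH-adjusted.

    Query genes outside the background are dropped (count logged).  Terms
    smaller than ``min_term_size`` are skipped.  Rows sorted by ascending
    p-value.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query gene set")
    stray = query - term_map.background
    if stray:
        log.warning("dropping %d query gene(s) outside the background", len(stray))
        query -= stray
    if not query:
        raise ValueError("no query genes remain inside the background")
    bg = len(term_map.background)
    rows: list[EnrichmentRow] = []
    for term, members in term_map.terms.items():
        if len(members) < min_term_size:
            continue
        overlap = query & members
        p = hypergeom_tail(len(overlap), len(members), len(query), bg)
        rows.append(
            EnrichmentRow(
                term_id=term,
                term_name=term_map.names.get(term, term),
                gene_ratio=len(overlap),
                term_size=len(members),
                p=p,
                fdr=1.0,
                overlap_genes=tuple(sorted(overlap)),
            )
        )
    if not rows:
        return []
    fdrs = bh_adjust([r.p for r in rows])
    for row, fdr in zip(rows, fdrs):
        row.fdr = fdr
    rows.sort(key=lambda r: (r.p, r.term_id))
    return rows
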