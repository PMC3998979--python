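"""Term/pathway over-representation of gene sets against an annotation map.

For a term annotating K of the N universe genes, with n annotated genes in
the query set of which k carry the term, the enrichment p-value is the
upper-tail hypergeometric probability P(X >= k). q-values are BH-adjusted
across the tested terms; the ratio column is 100 * k / K half-up rounded to
two decimals, matching pathway-report formatting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set

from scipy import stats

from tagdge.differential import bh_adjust
from tagdge.util import percentage

logger = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """term_id -> gene set, with the universe of annotated reference genes."""

    terms: Dict[str, Set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.universe: Set[str] = set().union(*self.terms.values()) if self.terms else set()

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "AnnotationMap":
        terms: Dict[str, Set[str]] = {}
        for gene_id, term_id in pairs:
            terms.setdefault(term_id, set()).add(gene_id)
        return cls(terms=terms)


@dataclass
class EnrichmentRow:
    term_id: str
    k: int  # query genes with the term
    K: int  # universe genes with the term
    n: int  # annotated query genes
    N: int  # universe size
    p_value: float
    q_value: float = 1.0

    @property
    def ratio(self) -> float:
        """100 * k / K, half-up rounded to 2 decimals."""
        return percentage(self.k, self.K)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not 0 <= K <= N or not 0 <= n <= N or k < 0:
        raise ValueError("invalid hypergeometric parameters")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    deg_set: Set[str],
    annotation: AnnotationMap,
    report_zero_k: bool = False,
) -> List[EnrichmentRow]:
    """Test every annotation term for over-representation in `deg_set`.

    Genes outside the annotation universe are dropped from n (logged).
    Rows are sorted by ascending p-value, ties by term id.
    """
    if not annotation.universe:
        raise ValueError("annotation universe is empty")
    in_universe = deg_set & annotation.universe
    dropped = len(deg_set) - len(in_universe)
    if dropped:
        logger.info("enrich: dropped %d query genes outside the annotation universe", dropped)

    n = len(in_universe)
    N = len(annotation.universe)
    rows = []
    for term_id in sorted(annotation.terms):
        genes = annotation.terms[term_id]
        k = len(in_universe & genes)
        if k == 0 and not report_zero_k:
            continue
        rows.append(
            EnrichmentRow(
                term_id=term_id,
                k=k,
                K=len(genes),
                n=n,
                N=N,
                p_value=hypergeom_upper_tail(k, len(genes), n, N),
            )
        )
    if rows:
        q = bh_adjust([r.p_value for r in rows])
        for row, q_value in zip(rows, q):
            row.q_value = float(q_value)
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def cluster_function_profile(
    assignment,  # ClusterAssignment
    annotation: AnnotationMap,
    report_zero_k: bool = False,
) -> Dict[int, List[EnrichmentRow]]:
    """Run enrich() once per cluster, with the cluster's genes as the query set."""
    out: Dict[int, List[EnrichmentRow]] = {}
    for cluster in range(1, assignment.k + 1):
        genes = {g for g, c in assignment.labels.items() if c == cluster}
        out[cluster] = enrich(genes, annotation, report_zero_k=report_zero_k)
    return out


def write_enrichment(rows: List[EnrichmentRow], path: str) -> None:
    """Write a pathway-report-shaped TSV with p and q appended."""
    with open(path, "w") as handle:
        handle.write("term_id\tdeg_hits\treference_hits\tratio\tp\tq\n")
        for r in rows:
            handle.write(f"{r.term_id}\t{r.k}\t{r.K}\t{r.ratio:.2f}%\t{r.p_value:.6g}\t{r.q_value:.6g}\n")
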