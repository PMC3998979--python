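"""Two-library exact count test, BH FDR, DEG calling, and set intersections.

The per-gene test conditions on the total x + y: under equal relative
abundance, y | (x + y = n) ~ Binomial(n, N2 / (N1 + N2)) where N1, N2 are the
libraries' mapped totals. The two-sided p-value doubles the smaller tail and
caps at 1 (the Audic-Claverie-style conditional test for replicate-free tag
libraries). Genes are called differential at q <= fdr_max and
|log2 ratio| >= min_abs_log2, both thresholds inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
from scipy import stats


def exact_tag_test(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided conditional binomial p-value for counts x (library A) and
    y (library B) with mapped totals n1, n2.

    p = min(1, 2 * min(P(Y <= y), P(Y >= y))) with Y ~ Binom(x + y, n2 / (n1 + n2)).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    n = x + y
    if n == 0:
        return 1.0
    prob = n2 / (n1 + n2)
    lower = stats.binom.cdf(y, n, prob)
    upper = stats.binom.sf(y - 1, n, prob)
    return float(min(1.0, 2.0 * min(lower, upper)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1; order-preserving.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DgeRecord:
    """One gene's comparison record between library A (reference, e.g. the
    control line) and library B (test line)."""

    gene_id: str
    x: int
    y: int
    n1: int
    n2: int
    tpm_a: float
    tpm_b: float
    log2_ratio: float
    p_value: float
    q_value: float = 1.0
    is_deg: bool = False
    direction: str = ""


@dataclass
class Comparison:
    """All gene records for one A-vs-B library comparison."""

    label: str
    records: List[DgeRecord] = field(default_factory=list)

    @property
    def n_up(self) -> int:
        return sum(1 for r in self.records if r.is_deg and r.direction == "up")

    @property
    def n_down(self) -> int:
        return sum(1 for r in self.records if r.is_deg and r.direction == "down")

    def deg_set(self) -> Set[str]:
        return {r.gene_id for r in self.records if r.is_deg}

    def directions(self) -> Dict[str, str]:
        return {r.gene_id: r.direction for r in self.records if r.is_deg}

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as handle:
            handle.write(
                "gene_id\tcount_a\tcount_b\ttpm_a\ttpm_b\tlog2_ratio\tp\tq\tis_deg\tdirection\n"
            )
            for r in self.records:
                handle.write(
                    f"{r.gene_id}\t{r.x}\t{r.y}\t{r.tpm_a:.6f}\t{r.tpm_b:.6f}\t"
                    f"{r.log2_ratio:.6f}\t{r.p_value:.6g}\t{r.q_value:.6g}\t"
                    f"{int(r.is_deg)}\t{r.direction}\n"
                )


def compare_libraries(
    counts_a: Dict[str, int],
    counts_b: Dict[str, int],
    total_a: int,
    total_b: int,
    label: str = "",
    fdr_max: float = 0.001,
    min_abs_log2: float = 1.0,
    pseudo_tpm: float = 0.5,
) -> Comparison:
    """Full two-library comparison: test every gene seen in either library,
    adjust within the comparison, and apply the DEG thresholds."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    records = []
    for gene in sorted(set(counts_a) | set(counts_b)):
        x = counts_a.get(gene, 0)
        y = counts_b.get(gene, 0)
        tpm_a = 1e6 * x / total_a
        tpm_b = 1e6 * y / total_b
        records.append(
            DgeRecord(
                gene_id=gene,
                x=x,
                y=y,
                n1=total_a,
                n2=total_b,
                tpm_a=tpm_a,
                tpm_b=tpm_b,
                log2_ratio=math.log2((tpm_b + pseudo_tpm) / (tpm_a + pseudo_tpm)),
                p_value=exact_tag_test(x, y, total_a, total_b),
            )
        )
    return call_degs(records, label=label, fdr_max=fdr_max, min_abs_log2=min_abs_log2)


def call_degs(
    records: List[DgeRecord],
    label: str = "",
    fdr_max: float = 0.001,
    min_abs_log2: float = 1.0,
) -> Comparison:
    """Set q-values (BH within this comparison) and DEG flags on `records`.

    Thresholds are inclusive; direction is "up" when library B exceeds A.
    """
    if records:
        q = bh_adjust([r.p_value for r in records])
        for record, q_value in zip(records, q):
            record.q_value = float(q_value)
            record.is_deg = q_value <= fdr_max and abs(record.log2_ratio) >= min_abs_log2
            record.direction = "up" if record.log2_ratio > 0 else "down"
    return Comparison(label=label, records=list(records))


def common_degs(
    comparisons: Sequence[Comparison],
    mode: str = "any_direction",
) -> Dict[Tuple[str, ...], Set[str]]:
    """All Venn regions over the comparisons' DEG sets.

    Returns {tuple of comparison labels: genes that are DEGs in exactly those
    comparisons}. `same_direction_up` / `same_direction_down` restrict
    membership to genes with the stated direction wherever they are DEGs.
    """
    if len(comparisons) < 2:
        raise ValueError("at least two comparisons are required")
    if mode not in ("any_direction", "same_direction_up", "same_direction_down"):
        raise ValueError(f"unknown mode {mode!r}")

    sets: Dict[str, Set[str]] = {}
    for comp in comparisons:
        degs = comp.deg_set()
        if mode != "any_direction":
            wanted = "up" if mode == "same_direction_up" else "down"
            directions = comp.directions()
            degs = {g for g in degs if directions[g] == wanted}
        if comp.label in sets:
            raise ValueError(f"duplicate comparison label {comp.label!r}")
        sets[comp.label] = degs

    labels = list(sets)
    regions: Dict[Tuple[str, ...], Set[str]] = {}
    for r in range(1, len(labels) + 1):
        for subset in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in subset))
            for other in labels:
                if other not in subset:
                    inside = inside - sets[other]
            regions[subset] = inside
    return regions


def write_regions(regions: Dict[Tuple[str, ...], Set[str]], path: str) -> None:
    """Write intersection regions as (region label, n, gene list) TSV."""
    with open(path, "w") as handle:
        handle.write("region\tn\tgenes\n")
        for subset in sorted(regions):
            genes = sorted(regions[subset])
            handle.write("&".join(subset) + f"\t{len(genes)}\t" + ",".join(genes) + "\n")


def relative_expression(delta_ct: float) -> float:
    """Relative qRT-PCR expression level, 2 ** (-delta_ct)."""
    return 2.0 ** (-delta_ct)
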