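"""Clean-tag filtering, mismatch-tolerant tag-to-gene mapping, and library QC.

A raw library is a tag multiset. Cleaning removes tags shorter than 21 nt,
tags containing N, and tags below the singleton threshold. Clean tags are
then looked up in the index: exact matches take priority; only when a tag has
no exact hit (and one mismatch is allowed) is its Hamming-1 neighborhood
searched, with the CATG anchor positions 0-3 held fixed. A tag whose hits
span more than one distinct gene is ambiguous and contributes to no gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Set

from tagdge.tagindex import TAG_LENGTH, TagIndex
from tagdge.util import percentage

_BASES = "ACGT"


@dataclass
class TagLibrary:
    """One sequencing library after cleaning, with filtering accountancy."""

    library_id: str
    raw_total: int
    distinct_raw: int
    clean_tags: Dict[str, int] = field(default_factory=dict)

    @property
    def clean_total(self) -> int:
        return sum(self.clean_tags.values())

    @property
    def distinct_clean(self) -> int:
        return len(self.clean_tags)


@dataclass
class MappingResult:
    """Per-gene mapped counts plus the distinct-tag accounting split."""

    library_id: str
    gene_counts: Dict[str, int] = field(default_factory=dict)
    distinct_mapped: int = 0
    ambiguous_distinct: int = 0
    unmapped_distinct: int = 0

    @property
    def mapped_clean_total(self) -> int:
        return sum(self.gene_counts.values())

    @property
    def genes_hit(self) -> int:
        return len(self.gene_counts)


@dataclass
class LibraryQc:
    """The per-library summary-table quantities (totals and percentages)."""

    library_id: str
    raw_total: int
    distinct_raw: int
    clean_total: int
    distinct_clean: int
    mapped_clean_total: int
    pct_clean_mapped: float
    distinct_mapped: int
    pct_distinct_mapped: float
    genes_hit: int
    pct_reference_genes: float

    ROW_LABELS = (
        ("raw_total", "Raw Data"),
        ("distinct_raw", "Distinct Raw Tag"),
        ("clean_total", "Clean Tag"),
        ("distinct_clean", "Distinct Clean Tag"),
        ("mapped_clean_total", "Unique Clean Tag Mapping to Gene"),
        ("pct_clean_mapped", "Total % of clean tag"),
        ("distinct_mapped", "Unique Distinct Clean Tag Mapping to Gene"),
        ("pct_distinct_mapped", "Total % of distinct tag"),
        ("genes_hit", "Unambiguous Tag-mapped Genes"),
        ("pct_reference_genes", "Percentage of reference genes"),
    )


def clean_tags(raw: Mapping[str, int], library_id: str = "", min_count: int = 2) -> TagLibrary:
    """Filter a raw tag multiset into clean tags.

    Removes tags shorter than 21 nt, tags containing N, and tags whose
    library count is below `min_count` (default 2: singletons dropped).
    """
    kept: Dict[str, int] = {}
    raw_total = 0
    for tag, count in raw.items():
        if count < 0:
            raise ValueError(f"negative count for tag {tag!r}")
        raw_total += count
        if len(tag) < TAG_LENGTH or "N" in tag or count < min_count:
            continue
        kept[tag] = count
    return TagLibrary(
        library_id=library_id,
        raw_total=raw_total,
        distinct_raw=len(raw),
        clean_tags=kept,
    )


def one_mismatch_neighbors(tag: str):
    """Yield the 51 Hamming-1 variants of a 21-nt tag outside the CATG anchor."""
    for pos in range(4, TAG_LENGTH):
        original = tag[pos]
        for base in _BASES:
            if base != original:
                yield tag[:pos] + base + tag[pos + 1 :]


def _matching_genes(tag: str, index: TagIndex, max_mismatch: int) -> Set[str]:
    genes = index.genes_for(tag)
    if genes or max_mismatch == 0:
        return genes
    for variant in one_mismatch_neighbors(tag):
        genes |= index.genes_for(variant)
    return genes


def map_library(clean: TagLibrary, index: TagIndex, max_mismatch: int = 1) -> MappingResult:
    """Map clean tags to genes, excluding tags that hit more than one gene.

    Exact hits take priority: a tag present verbatim in the index is never
    also matched against its 1-mismatch neighborhood. Multiple positions
    within a single gene are fine and are summed into that gene's count.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    result = MappingResult(library_id=clean.library_id)
    for tag, count in clean.clean_tags.items():
        if len(tag) != TAG_LENGTH:
            raise ValueError(f"clean tag {tag!r} is not {TAG_LENGTH} nt")
        genes = _matching_genes(tag, index, max_mismatch)
        if len(genes) == 1:
            gene = next(iter(genes))
            result.gene_counts[gene] = result.gene_counts.get(gene, 0) + count
            result.distinct_mapped += 1
        elif len(genes) > 1:
            result.ambiguous_distinct += 1
        else:
            result.unmapped_distinct += 1
    return result


def gene_expression(mapping: MappingResult) -> Dict[str, float]:
    """Per-gene TPM: 1e6 * count / total mapped clean tags.

    TPM values over genes with nonzero counts sum to 1e6 by construction.
    """
    total = mapping.mapped_clean_total
    if total == 0:
        raise ValueError(f"library {mapping.library_id!r} has zero mapped tags")
    return {gene: 1e6 * count / total for gene, count in mapping.gene_counts.items()}


def qc_from_totals(
    library_id: str,
    raw_total: int,
    distinct_raw: int,
    clean_total: int,
    distinct_clean: int,
    mapped_clean_total: int,
    distinct_mapped: int,
    genes_hit: int,
    n_reference_genes: int,
) -> LibraryQc:
    """Build a LibraryQc directly from count totals (e.g. a published table).

    Percentages are half-up rounded to 2 decimals, matching report formatting.
    """
    if n_reference_genes <= 0:
        raise ValueError("n_reference_genes must be positive")
    return LibraryQc(
        library_id=library_id,
        raw_total=raw_total,
        distinct_raw=distinct_raw,
        clean_total=clean_total,
        distinct_clean=distinct_clean,
        mapped_clean_total=mapped_clean_total,
        pct_clean_mapped=percentage(mapped_clean_total, clean_total),
        distinct_mapped=distinct_mapped,
        pct_distinct_mapped=percentage(distinct_mapped, distinct_clean),
        genes_hit=genes_hit,
        pct_reference_genes=percentage(genes_hit, n_reference_genes),
    )


def library_qc(clean: TagLibrary, mapping: MappingResult, n_reference_genes: int) -> LibraryQc:
    """Assemble the summary-table quantities for one library."""
    if clean.library_id != mapping.library_id:
        raise ValueError(
            f"library id mismatch: {clean.library_id!r} vs {mapping.library_id!r}"
        )
    return qc_from_totals(
        library_id=clean.library_id,
        raw_total=clean.raw_total,
        distinct_raw=clean.distinct_raw,
        clean_total=clean.clean_total,
        distinct_clean=clean.distinct_clean,
        mapped_clean_total=mapping.mapped_clean_total,
        distinct_mapped=mapping.distinct_mapped,
        genes_hit=mapping.genes_hit,
        n_reference_genes=n_reference_genes,
    )


def write_qc_table(qcs: list[LibraryQc], path: str) -> None:
    """Write a summary table: one labeled row per quantity, one column per library."""
    with open(path, "w") as handle:
        handle.write("Summary\t" + "\t".join(q.library_id for q in qcs) + "\n")
        for attr, label in LibraryQc.ROW_LABELS:
            values = []
            for q in qcs:
                v = getattr(q, attr)
                values.append(f"{v:.2f}%" if attr.startswith("pct_") else str(v))
            handle.write(label + "\t" + "\t".join(values) + "\n")


def write_mapping_result(mapping: MappingResult, path: str) -> None:
    """Write (gene_id, count, tpm) rows sorted by gene id."""
    tpm = gene_expression(mapping)
    with open(path, "w") as handle:
        handle.write("gene_id\tcount\ttpm\n")
        for gene in sorted(mapping.gene_counts):
            handle.write(f"{gene}\t{mapping.gene_counts[gene]}\t{tpm[gene]:.6f}\n")
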