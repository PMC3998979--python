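"""Searchable database of 21-base CATG-anchored tags from reference transcripts.

Every CATG occurrence with at least 17 following bases contributes one tag
(windows containing N are skipped), so internal sites arising from incomplete
digestion or RT artifacts remain findable. Offsets are 0-based, half-open
windows [offset, offset + 21) on the recorded strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Set, Tuple

ANCHOR = "CATG"
TAG_LENGTH = 21

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: one tag occurrence: (gene_id, 0-based offset on the recorded strand, strand)
Occurrence = Tuple[str, int, str]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TagIndex:
    """Maps each 21-nt CATG-anchored tag to its (gene, offset, strand) occurrences."""

    entries: Dict[str, List[Occurrence]] = field(default_factory=dict)
    n_genes: int = 0
    strands: str = "sense"

    @property
    def n_tag_positions(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def genes_for(self, tag: str) -> Set[str]:
        """Distinct genes containing `tag` (empty set if absent)."""
        return {occ[0] for occ in self.entries.get(tag, ())}

    def __contains__(self, tag: str) -> bool:
        return tag in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str) -> None:
        """Serialize as sorted (tag, gene_id, offset, strand) rows for diffing."""
        with open(path, "w") as handle:
            for tag in sorted(self.entries):
                for gene_id, offset, strand in sorted(self.entries[tag]):
                    handle.write(f"{tag}\t{gene_id}\t{offset}\t{strand}\n")


def _scan_strand(seq: str, gene_id: str, strand: str, entries: Dict[str, List[Occurrence]]) -> None:
    start = seq.find(ANCHOR)
    while start != -1:
        window = seq[start : start + TAG_LENGTH]
        if len(window) == TAG_LENGTH and "N" not in window:
            entries.setdefault(window, []).append((gene_id, start, strand))
        start = seq.find(ANCHOR, start + 1)


def build_index(reference: Mapping[str, str], strands: str = "sense") -> TagIndex:
    """Build the tag database from {gene_id: transcript sequence}.

    Parameters
    ----------
    reference:
        Transcript sequences over ACGTN (any case; normalized to upper).
    strands:
        "sense" indexes the given strand only; "both" additionally scans the
        reverse complement (offsets are then relative to the scanned strand).
    """
    if not reference:
        raise ValueError("reference must contain at least one transcript")
    if strands not in ("sense", "both"):
        raise ValueError(f"strands must be 'sense' or 'both', got {strands!r}")

    entries: Dict[str, List[Occurrence]] = {}
    for gene_id in sorted(reference):
        seq = reference[gene_id].upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"transcript {gene_id} contains non-ACGTN characters")
        _scan_strand(seq, gene_id, "+", entries)
        if strands == "both":
            _scan_strand(revcomp(seq), gene_id, "-", entries)
    return TagIndex(entries=entries, n_genes=len(reference), strands=strands)


def gene_tag_sets(index: TagIndex) -> Dict[str, Set[str]]:
    """Invert the index: {gene_id: set of tag sequences occurring in it}."""
    out: Dict[str, Set[str]] = {}
    for tag, occurrences in index.entries.items():
        for gene_id, _, _ in occurrences:
            out.setdefault(gene_id, set()).add(tag)
    return out
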