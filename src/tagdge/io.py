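"""Readers and writers for the plain-text formats used across the pipeline.

FASTA handling is delegated to Biopython; everything else is two-column or
rectangular TSV so outputs diff cleanly and round-trip through the package's
own readers.
"""

from __future__ import annotations

import os
from collections import Counter
from typing import Dict, Iterable, Mapping, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a FASTA file into an ordered {gene_id: uppercase sequence} map."""
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id in FASTA: {rec.id}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(reference: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    """Write sequences as wrapped FASTA, preserving input order."""
    records = [SeqRecord(Seq(seq), id=gene_id, description="") for gene_id, seq in reference.items()]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_tag_counts(path: str | os.PathLike) -> Counter:
    """Read a raw tag library.

    Accepts either two-column TSV (tag <tab> count) or one read per line;
    the two forms may not be mixed within one file.
    """
    counts: Counter = Counter()
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                counts[fields[0].upper()] += 1
            elif len(fields) == 2:
                try:
                    n = int(fields[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{line_no}: count is not an integer: {fields[1]!r}") from exc
                if n < 0:
                    raise ValueError(f"{path}:{line_no}: negative tag count")
                counts[fields[0].upper()] += n
            else:
                raise ValueError(f"{path}:{line_no}: expected 1 or 2 tab-separated fields")
    return counts


def write_tag_counts(counts: Mapping[str, int], path: str | os.PathLike) -> None:
    """Write a tag library as sorted two-column TSV (tag, count)."""
    with open(path, "w") as handle:
        for tag in sorted(counts):
            handle.write(f"{tag}\t{counts[tag]}\n")


def read_annotation(path: str | os.PathLike) -> Dict[str, set]:
    """Read a two-column (gene_id, term_id) TSV into {term_id: set of genes}."""
    terms: Dict[str, set] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated fields")
            gene_id, term_id = fields
            terms.setdefault(term_id, set()).add(gene_id)
    return terms


def write_annotation(terms: Mapping[str, Iterable[str]], path: str | os.PathLike) -> None:
    """Write {term_id: genes} as sorted two-column (gene_id, term_id) TSV."""
    pairs: list[Tuple[str, str]] = sorted(
        (gene_id, term_id) for term_id, genes in terms.items() for gene_id in genes
    )
    with open(path, "w") as handle:
        for gene_id, term_id in pairs:
            handle.write(f"{gene_id}\t{term_id}\n")
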