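"""Multi-library expression matrix assembly, stage filtering, log transform."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from tagdge.mapping import MappingResult


@dataclass
class LibraryInfo:
    """Identity and design coordinates of one library."""

    library_id: str
    genotype: str
    stage: str


@dataclass
class ExpressionMatrix:
    """Genes x libraries counts and TPM with per-library design metadata.

    `counts` and `tpm` are pandas DataFrames sharing index (gene ids) and
    columns (library ids); TPM columns each sum to 1e6 over nonzero rows.
    """

    counts: pd.DataFrame
    tpm: pd.DataFrame
    libraries: List[LibraryInfo]
    library_totals: Dict[str, int]

    @property
    def gene_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> List[str]:
        return list(self.counts.columns)

    def stages(self) -> Dict[str, List[str]]:
        """{stage: library ids at that stage}, in column order."""
        out: Dict[str, List[str]] = {}
        for info in self.libraries:
            out.setdefault(info.stage, []).append(info.library_id)
        return out

    def to_tsv(self, path: str, which: str = "tpm") -> None:
        frame = self.tpm if which == "tpm" else self.counts
        frame.to_csv(path, sep="\t", index_label="gene_id")

    def metadata_to_tsv(self, path: str) -> None:
        pd.DataFrame(
            [(i.library_id, i.genotype, i.stage) for i in self.libraries],
            columns=["library_id", "genotype", "stage"],
        ).to_csv(path, sep="\t", index=False)


def assemble(
    mappings: Sequence[MappingResult],
    metadata: Sequence[Tuple[str, str]] | None = None,
) -> ExpressionMatrix:
    """Build the expression matrix from per-library mapping results.

    Parameters
    ----------
    mappings:
        One MappingResult per library; ids must be unique.
    metadata:
        Optional (genotype, stage) per library, aligned with `mappings`.
        Stage metadata is required later by `stage_filter`.
    """
    if not mappings:
        raise ValueError("at least one library is required")
    ids = [m.library_id for m in mappings]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate library ids in mappings")
    if metadata is not None and len(metadata) != len(mappings):
        raise ValueError("metadata length must match number of libraries")

    genes = sorted(set().union(*(m.gene_counts.keys() for m in mappings)))
    counts = pd.DataFrame(0, index=genes, columns=ids, dtype=np.int64)
    for m in mappings:
        for gene, count in m.gene_counts.items():
            counts.at[gene, m.library_id] = count

    totals = {m.library_id: m.mapped_clean_total for m in mappings}
    tpm = counts.astype(float)
    for lib in ids:
        if totals[lib] == 0:
            raise ValueError(f"library {lib!r} has zero mapped tags")
        tpm[lib] = 1e6 * tpm[lib] / totals[lib]

    infos = [
        LibraryInfo(lib, *(metadata[i] if metadata is not None else ("", "")))
        for i, lib in enumerate(ids)
    ]
    return ExpressionMatrix(counts=counts, tpm=tpm, libraries=infos, library_totals=totals)


def stage_filter(
    matrix: ExpressionMatrix,
    min_libraries: int = 3,
    expression_threshold: float = 0.0,
) -> ExpressionMatrix:
    """Keep genes expressed (TPM > threshold) in >= min_libraries at some stage."""
    if min_libraries < 1:
        raise ValueError("min_libraries must be >= 1")
    stages = matrix.stages()
    if not stages or set(stages) == {""}:
        raise ValueError("stage metadata is required for stage_filter")

    keep = pd.Series(False, index=matrix.counts.index)
    for libs in stages.values():
        expressed = (matrix.tpm[libs] > expression_threshold).sum(axis=1)
        keep |= expressed >= min_libraries

    kept = list(matrix.counts.index[keep])
    return ExpressionMatrix(
        counts=matrix.counts.loc[kept],
        tpm=matrix.tpm.loc[kept],
        libraries=list(matrix.libraries),
        library_totals=dict(matrix.library_totals),
    )


def log_transform(matrix: ExpressionMatrix, pseudo: float = 1.0) -> pd.DataFrame:
    """log2(TPM + pseudo) matrix for clustering; monotone in TPM."""
    if pseudo <= 0 and (matrix.tpm.to_numpy() == 0).any():
        raise ValueError("pseudo offset must be > 0 when zero TPMs are present")
    return np.log2(matrix.tpm + pseudo)
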