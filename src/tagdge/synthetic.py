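"""Synthetic references, tag libraries, and annotations with known ground truth.

Everything downstream (indexing, mapping, DEG calling, clustering,
enrichment) is exercised against data generated here, so each generator
plants a recoverable signal: which genes are differential (direction and
true log2 effect per contrast), which temporal cluster each gene follows,
and which annotation term overlaps a chosen gene set.

All randomness flows from one master seed; per-library streams are derived
from (seed, library_id) via :func:`tagdge.util.derive_rng`.

Count noise is gamma-Poisson (negative binomial) with variance
mu + dispersion * mu^2; dispersion == 0 is the noiseless limit and emits the
expected counts exactly (rounded), so fixtures can pin counts bit-for-bit.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from tagdge.tagindex import ANCHOR, TAG_LENGTH
from tagdge.util import derive_rng

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_EXTRACTABLE = re.compile(r"(?=(CATG[ACGT]{17}))")


@dataclass
class SyntheticDesign:
    """Parameters of a simulated multi-genotype, multi-stage tag experiment.

    The first genotype id is the control; every other genotype is contrasted
    against it at each stage, emulating introgression-line vs recurrent-parent
    comparisons across developmental stages.
    """

    n_genes: int
    genotype_ids: List[str]
    stage_ids: List[str]
    library_depth: int
    de_fraction: float = 0.0
    de_log2_effect: float = 2.0
    dispersion: float = 0.0
    error_rate: float = 0.0
    seed: int = 0
    length_range: Tuple[int, int] = (200, 1200)
    catg_fraction: float = 0.97
    n_clusters: int = 0
    libraries: Optional[List[Tuple[str, str]]] = None  # (genotype, stage) subset

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if not 0 <= self.de_fraction < 1:
            raise ValueError("de_fraction must be in [0, 1)")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not self.genotype_ids or not self.stage_ids:
            raise ValueError("genotype_ids and stage_ids must be non-empty")

    def library_plan(self) -> List[Tuple[str, str]]:
        """The (genotype, stage) pairs actually simulated.

        Defaults to the full grid; an explicit subset emulates designs where
        some genotype-stage libraries are absent.
        """
        if self.libraries is not None:
            return list(self.libraries)
        return [(g, s) for g in self.genotype_ids for s in self.stage_ids]


@dataclass
class GroundTruth:
    """What was planted: DE genes per contrast and temporal cluster labels."""

    de_genes: Dict[str, Set[Tuple[str, str, float]]] = field(default_factory=dict)
    cluster_labels: Dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "de_genes": {
                contrast: sorted([g, d, f] for g, d, f in genes)
                for contrast, genes in self.de_genes.items()
            },
            "cluster_labels": dict(sorted(self.cluster_labels.items())),
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)


def canonical_tag(seq: str) -> Optional[str]:
    """The simulated tag of a transcript: 3'-most CATG plus the next 17 bases.

    A CATG too close to the 3' end to leave 17 downstream bases falls back to
    the next site upstream. Returns None when no site qualifies.
    """
    matches = _EXTRACTABLE.findall(seq.upper())
    return matches[-1] if matches else None


def _scrub_extractable(seq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Destroy every extractable CATG window by mutating one anchor base."""
    while True:
        text = seq.tobytes().decode()
        m = _EXTRACTABLE.search(text)
        if m is None:
            return seq
        pos = m.start() + int(rng.integers(4))
        current = seq[pos]
        choices = _BASES[_BASES != current]
        seq[pos] = rng.choice(choices)


def make_reference(
    n_genes: int,
    length_range: Tuple[int, int] = (200, 1200),
    catg_fraction: float = 0.97,
    seed: int = 0,
) -> Dict[str, str]:
    """Random uppercase-ACGT transcripts with controlled tag extractability.

    Exactly round(catg_fraction * n_genes) transcripts are guaranteed to
    contain an extractable tag (a CATG with >= 17 downstream bases); the rest
    are scrubbed of every such window.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    lo, hi = length_range
    if lo < 25 or hi < lo:
        raise ValueError("length_range must satisfy 25 <= lo <= hi")
    if not 0 <= catg_fraction <= 1:
        raise ValueError("catg_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    n_with_tag = int(round(catg_fraction * n_genes))
    width = len(str(n_genes))
    reference: Dict[str, str] = {}
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(_BASES, size=length)
        if i < n_with_tag:
            if not _EXTRACTABLE.search(seq.tobytes().decode()):
                start = int(rng.integers(0, length - TAG_LENGTH + 1))
                seq[start : start + 4] = np.frombuffer(ANCHOR.encode(), dtype="S1")
        else:
            seq = _scrub_extractable(seq, rng)
        reference[f"gene{i + 1:0{width}d}"] = seq.tobytes().decode()
    return reference


@dataclass
class SimulatedLibrary:
    """Raw tag multiset for one library plus simulation bookkeeping."""

    library_id: str
    tags: Counter
    true_counts: Dict[str, int]  # gene -> emitted copies (before errors)
    unrepresentable: List[str]  # profiled genes without an extractable tag

    @property
    def raw_total(self) -> int:
        return sum(self.tags.values())


def _draw_counts(
    expected: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    if dispersion == 0:
        return np.round(expected).astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, expected * dispersion)
    return rng.poisson(lam)


def _mutate_copies(tag: str, n_errors: np.ndarray, rng: np.random.Generator, out: Counter) -> None:
    arr = np.frombuffer(tag.encode(), dtype="S1")
    for ne in n_errors:
        copy = arr.copy()
        for pos in rng.choice(TAG_LENGTH, size=ne, replace=False):
            copy[pos] = rng.choice(_BASES[_BASES != copy[pos]])
        out[copy.tobytes().decode()] += 1


def simulate_library(
    reference: Dict[str, str],
    expression_profile: Dict[str, float],
    design: SyntheticDesign,
    library_id: str,
) -> SimulatedLibrary:
    """Emit one library's raw 21-nt tag multiset from an expression profile.

    Per profiled gene, the copy number is a negative-binomial draw around the
    expected count (exact at dispersion 0); each copy is then independently
    corrupted base-by-base at the design error rate. Genes whose transcript
    has no extractable tag emit nothing and are reported as unrepresentable.
    """
    rng = derive_rng(design.seed, library_id)
    tags: Counter = Counter()
    true_counts: Dict[str, int] = {}
    unrepresentable: List[str] = []
    genes = sorted(expression_profile)
    expected = np.array([expression_profile[g] for g in genes], dtype=float)
    if (expected < 0).any():
        raise ValueError("expected counts must be non-negative")
    counts = _draw_counts(expected, design.dispersion, rng)

    for gene, count in zip(genes, counts):
        if gene not in reference:
            raise KeyError(f"profiled gene {gene!r} is not in the reference")
        tag = canonical_tag(reference[gene])
        if tag is None:
            unrepresentable.append(gene)
            continue
        count = int(count)
        if count == 0:
            continue
        true_counts[gene] = count
        if design.error_rate == 0:
            tags[tag] += count
        else:
            n_errors = rng.binomial(TAG_LENGTH, design.error_rate, size=count)
            tags[tag] += int((n_errors == 0).sum())
            _mutate_copies(tag, n_errors[n_errors > 0], rng, tags)
    return SimulatedLibrary(
        library_id=library_id, tags=tags, true_counts=true_counts, unrepresentable=unrepresentable
    )


# --- whole-experiment simulation -------------------------------------------

#: stage-multiplier shapes cycled over when planting temporal clusters; with
#: three stages these give the classic high-early / high-late / transient
#: patterns. Values are log2 offsets applied per stage.
_CLUSTER_SHAPES = [
    (2.0, 0.0, -2.0),  # falling
    (-2.0, 0.0, 2.0),  # rising
    (2.0, 2.0, -2.0),  # high early+mid
    (-2.0, 2.0, 2.0),  # high mid+late
    (-2.0, 2.0, -2.0),  # transient peak
    (2.0, -2.0, 2.0),  # transient dip
]


@dataclass
class Experiment:
    """A fully simulated experiment: inputs plus planted truth."""

    design: SyntheticDesign
    reference: Dict[str, str]
    libraries: Dict[str, SimulatedLibrary]
    profiles: Dict[str, Dict[str, float]]  # library_id -> gene -> expected count
    metadata: List[Tuple[str, str]]  # (genotype, stage) per library, plan order
    truth: GroundTruth

    @staticmethod
    def library_id(genotype: str, stage: str) -> str:
        return f"{genotype}_{stage}"


def _cluster_log2_offset(cluster: int, stage_index: int, n_stages: int) -> float:
    shape = _CLUSTER_SHAPES[(cluster - 1) % len(_CLUSTER_SHAPES)]
    if n_stages == len(shape):
        return shape[stage_index]
    # other stage counts: interpolate the shape over the stage axis
    xs = np.linspace(0, 1, len(shape))
    return float(np.interp(stage_index / max(n_stages - 1, 1), xs, shape))


def simulate_experiment(design: SyntheticDesign) -> Experiment:
    """Simulate reference + all libraries of a design with planted truth.

    Baseline abundances are log-normal. When ``n_clusters`` > 0 every gene is
    assigned a temporal shape shared by all genotypes (the planted cluster
    structure). When ``de_fraction`` > 0, for each non-control genotype and
    stage a disjoint-per-contrast random gene subset has its expected count
    shifted by +/- ``de_log2_effect`` in that genotype's library only.
    """
    rng = derive_rng(design.seed, "experiment")
    reference = make_reference(
        design.n_genes, design.length_range, design.catg_fraction, seed=design.seed
    )
    genes = sorted(reference)
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=design.n_genes)

    truth = GroundTruth()
    if design.n_clusters > 0:
        labels = rng.integers(1, design.n_clusters + 1, size=design.n_genes)
        truth.cluster_labels = {g: int(c) for g, c in zip(genes, labels)}

    plan = design.library_plan()
    control = design.genotype_ids[0]
    n_stages = len(design.stage_ids)

    # plant DE: per (genotype != control, stage) contrast
    de_by_contrast: Dict[str, Dict[str, float]] = {}
    for genotype, stage in plan:
        if genotype == control or design.de_fraction == 0:
            continue
        contrast = f"{genotype}_vs_{control}@{stage}"
        n_de = int(round(design.de_fraction * design.n_genes))
        chosen = rng.choice(design.n_genes, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        effects = {genes[i]: s * design.de_log2_effect for i, s in zip(chosen, signs)}
        de_by_contrast[contrast] = effects
        truth.de_genes[contrast] = {
            (g, "up" if e > 0 else "down", e) for g, e in effects.items()
        }

    profiles: Dict[str, Dict[str, float]] = {}
    libraries: Dict[str, SimulatedLibrary] = {}
    for genotype, stage in plan:
        stage_index = design.stage_ids.index(stage)
        log2_shift = np.zeros(design.n_genes)
        if design.n_clusters > 0:
            for i, g in enumerate(genes):
                log2_shift[i] += _cluster_log2_offset(
                    truth.cluster_labels[g], stage_index, n_stages
                )
        contrast = f"{genotype}_vs_{control}@{stage}"
        if contrast in de_by_contrast:
            for i, g in enumerate(genes):
                log2_shift[i] += de_by_contrast[contrast].get(g, 0.0)
        w = weights * np.exp2(log2_shift)
        mu = design.library_depth * w / w.sum()
        lib_id = Experiment.library_id(genotype, stage)
        profiles[lib_id] = dict(zip(genes, mu))
        libraries[lib_id] = simulate_library(reference, profiles[lib_id], design, lib_id)

    return Experiment(
        design=design,
        reference=reference,
        libraries=libraries,
        profiles=profiles,
        metadata=plan,
        truth=truth,
    )


def make_annotation(
    reference: Dict[str, str],
    n_terms: int,
    genes_per_term: int | Tuple[int, int] = (5, 50),
    seed: int = 0,
    forced_overlap: Optional[Tuple[str, int, Set[str], int]] = None,
) -> Dict[str, Set[str]]:
    """Random gene -> term annotation map as {term_id: gene set}.

    ``forced_overlap = (term_id, term_size, target_genes, k_overlap)`` adds a
    designated term with exactly ``k_overlap`` members drawn from
    ``target_genes`` and the remainder from outside it, for planting an
    enriched term against a known DE set.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    genes = sorted(reference)
    if isinstance(genes_per_term, int):
        lo = hi = genes_per_term
    else:
        lo, hi = genes_per_term
    if lo < 1 or hi < lo or hi > len(genes):
        raise ValueError("genes_per_term out of range")

    terms: Dict[str, Set[str]] = {}
    width = len(str(n_terms))
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        terms[f"term{t + 1:0{width}d}"] = {genes[i] for i in members}

    if forced_overlap is not None:
        term_id, size, targets, k_overlap = forced_overlap
        targets = set(targets) & set(genes)
        if k_overlap > min(size, len(targets)):
            raise ValueError("forced overlap larger than term or target set")
        inside = rng.choice(sorted(targets), size=k_overlap, replace=False)
        outside_pool = sorted(set(genes) - targets)
        outside = rng.choice(outside_pool, size=size - k_overlap, replace=False)
        terms[term_id] = set(inside) | set(outside)
    return terms
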