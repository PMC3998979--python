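"""Configuration-driven end-to-end driver: simulate/load -> index -> map ->
matrix -> DEG -> cluster -> enrich, with a reproducibility manifest.

Defaults reproduce the canonical analysis thresholds: singleton removal,
one mismatch, FDR <= 0.001 with |log2 ratio| >= 1, the expressed-in->=3-
libraries-at-one-stage filter, and six clusters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple

import yaml

from tagdge import io as tio
from tagdge.clustering import hier_cluster, linkage_to_newick, sota_cluster
from tagdge.differential import Comparison, common_degs, compare_libraries, write_regions
from tagdge.enrichment import AnnotationMap, enrich, write_enrichment
from tagdge.expression import assemble, log_transform, stage_filter
from tagdge.mapping import clean_tags, library_qc, map_library, write_mapping_result, write_qc_table
from tagdge.synthetic import SyntheticDesign, simulate_experiment
from tagdge.tagindex import build_index

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: Dict[str, Any] = {
    "max_mismatch": 1,
    "min_tag_count": 2,
    "fdr_max": 0.001,
    "min_abs_log2": 1.0,
    "pseudo_tpm": 0.5,
    "filter_min_libraries": 3,
    "expression_threshold": 0.0,
    "clustering_k": 6,
    "log2_pseudo": 1.0,
    "strands": "sense",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; see `from_yaml` for the file schema."""

    seed: int = 0
    output_dir: str = "out"
    simulate: Optional[Dict[str, Any]] = None
    reference_fasta: Optional[str] = None
    libraries: Optional[List[Dict[str, str]]] = None  # id, genotype, stage, path
    annotation_path: Optional[str] = None
    annotation_simulate: Optional[Dict[str, Any]] = None
    params: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params or {})
        unknown = set(merged) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        self.params = merged
        if self.simulate is None and (self.reference_fasta is None or self.libraries is None):
            raise ValueError("config needs either a 'simulate' block or reference + libraries")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        ref = raw.get("reference", {}) or {}
        ann = raw.get("annotation", {}) or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "out")),
            simulate=raw.get("simulate"),
            reference_fasta=ref.get("fasta"),
            libraries=raw.get("libraries"),
            annotation_path=ann.get("path"),
            annotation_simulate=ann.get("simulate"),
            params=raw.get("params", {}) or {},
        )


def _design_from_config(config: PipelineConfig) -> SyntheticDesign:
    s = dict(config.simulate or {})
    return SyntheticDesign(
        n_genes=int(s.get("n_genes", 200)),
        genotype_ids=list(s.get("genotypes", ["CTRL", "LINE1"])),
        stage_ids=list(s.get("stages", ["S1", "S2", "S3"])),
        library_depth=int(s.get("depth", 10000)),
        de_fraction=float(s.get("de_fraction", 0.0)),
        de_log2_effect=float(s.get("de_log2_effect", 2.0)),
        dispersion=float(s.get("dispersion", 0.0)),
        error_rate=float(s.get("error_rate", 0.0)),
        seed=config.seed,
        n_clusters=int(s.get("n_clusters", 0)),
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory.

    Identical config + seed produces byte-identical artifacts; the manifest
    records per-file SHA-256 hashes plus a combined run hash.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    manifest: Dict[str, Any] = {
        "seed": config.seed,
        "params": dict(sorted(p.items())),
        "stages": {},
    }

    # --- inputs: simulate or load ------------------------------------------
    if config.simulate is not None:
        design = _design_from_config(config)
        experiment = simulate_experiment(design)
        reference = experiment.reference
        tio.write_fasta(reference, out / "reference.fasta")
        raw_libraries: List[Tuple[str, str, str, Dict[str, int]]] = []
        for genotype, stage in experiment.metadata:
            lib_id = experiment.library_id(genotype, stage)
            tags = dict(experiment.libraries[lib_id].tags)
            tio.write_tag_counts(tags, out / f"{lib_id}.tags.tsv")
            raw_libraries.append((lib_id, genotype, stage, tags))
        experiment.truth.to_json(str(out / "ground_truth.json"))
        control = design.genotype_ids[0]
    else:
        reference = tio.read_fasta(config.reference_fasta)  # type: ignore[arg-type]
        raw_libraries = []
        for spec in config.libraries or []:
            for key in ("id", "genotype", "stage", "path"):
                if key not in spec:
                    raise ValueError(f"library entry missing key {key!r}: {spec}")
            raw_libraries.append(
                (spec["id"], spec["genotype"], spec["stage"], dict(tio.read_tag_counts(spec["path"])))
            )
        control = raw_libraries[0][1]
    manifest["stages"]["input"] = {
        "n_reference_genes": len(reference),
        "n_libraries": len(raw_libraries),
        "control_genotype": control,
    }

    # --- index, clean, map --------------------------------------------------
    index = build_index(reference, strands=p["strands"])
    index.to_tsv(str(out / "tag_index.tsv"))
    manifest["stages"]["index"] = {
        "distinct_tags": len(index),
        "tag_positions": index.n_tag_positions,
    }

    qcs = []
    mappings = []
    metadata = []
    for lib_id, genotype, stage, tags in raw_libraries:
        clean = clean_tags(tags, library_id=lib_id, min_count=p["min_tag_count"])
        mapping = map_library(clean, index, max_mismatch=p["max_mismatch"])
        qcs.append(library_qc(clean, mapping, n_reference_genes=len(reference)))
        write_mapping_result(mapping, str(out / f"{lib_id}.mapped.tsv"))
        mappings.append(mapping)
        metadata.append((genotype, stage))
        logger.info(
            "library %s: raw=%d clean=%d mapped=%d genes=%d",
            lib_id, clean.raw_total, clean.clean_total,
            mapping.mapped_clean_total, mapping.genes_hit,
        )
    write_qc_table(qcs, str(out / "library_qc.tsv"))
    manifest["stages"]["mapping"] = {
        q.library_id: {"clean_total": q.clean_total, "mapped": q.mapped_clean_total}
        for q in qcs
    }

    # --- matrix + stage filter ---------------------------------------------
    matrix = assemble(mappings, metadata=metadata)
    matrix.to_tsv(str(out / "matrix_counts.tsv"), which="counts")
    matrix.to_tsv(str(out / "matrix_tpm.tsv"), which="tpm")
    matrix.metadata_to_tsv(str(out / "matrix_metadata.tsv"))
    filtered = stage_filter(
        matrix,
        min_libraries=p["filter_min_libraries"],
        expression_threshold=p["expression_threshold"],
    )
    manifest["stages"]["matrix"] = {
        "genes": len(matrix.gene_ids),
        "genes_after_stage_filter": len(filtered.gene_ids),
    }

    # --- DEG calling: each non-control genotype vs control per stage --------
    by_stage: Dict[str, Dict[str, Any]] = {}
    for mapping, (genotype, stage) in zip(mappings, metadata):
        by_stage.setdefault(stage, {})[genotype] = mapping
    comparisons: List[Comparison] = []
    for stage in sorted(by_stage):
        libs = by_stage[stage]
        if control not in libs:
            continue
        base = libs[control]
        for genotype in sorted(libs):
            if genotype == control:
                continue
            comp = compare_libraries(
                base.gene_counts,
                libs[genotype].gene_counts,
                base.mapped_clean_total,
                libs[genotype].mapped_clean_total,
                label=f"{genotype}_vs_{control}@{stage}",
                fdr_max=p["fdr_max"],
                min_abs_log2=p["min_abs_log2"],
                pseudo_tpm=p["pseudo_tpm"],
            )
            comp.to_tsv(str(out / f"dge_{comp.label}.tsv"))
            comparisons.append(comp)
            logger.info("comparison %s: %d up, %d down", comp.label, comp.n_up, comp.n_down)
    manifest["stages"]["differential"] = {
        c.label: {"n_up": c.n_up, "n_down": c.n_down} for c in comparisons
    }
    if len(comparisons) >= 2:
        write_regions(common_degs(comparisons), str(out / "deg_intersections.tsv"))

    # --- clustering on the stage-filtered matrix ----------------------------
    cluster_summary: Dict[str, Any] = {}
    if len(filtered.gene_ids) >= 2:
        logm = log_transform(filtered, pseudo=p["log2_pseudo"])
        k = min(p["clustering_k"], len(filtered.gene_ids))
        _, sota = sota_cluster(logm, max_clusters=k, seed=config.seed)
        sota.to_tsv(str(out / "clusters_sota.tsv"))
        hier, merge_tree = hier_cluster(logm, k=k)
        hier.to_tsv(str(out / "clusters_hier.tsv"))
        (out / "clusters_hier.newick").write_text(
            linkage_to_newick(merge_tree, list(logm.index)) + "\n"
        )
        cluster_summary = {"k_sota": sota.k, "k_hier": hier.k}
    manifest["stages"]["clustering"] = cluster_summary

    # --- enrichment of the pooled DEG set ----------------------------------
    annotation: Optional[AnnotationMap] = None
    if config.annotation_path:
        annotation = AnnotationMap(terms=tio.read_annotation(config.annotation_path))
    elif config.annotation_simulate is not None:
        from tagdge.synthetic import make_annotation

        terms = make_annotation(
            reference,
            n_terms=int(config.annotation_simulate.get("n_terms", 20)),
            seed=config.seed,
        )
        tio.write_annotation(terms, out / "annotation.tsv")
        annotation = AnnotationMap(terms=terms)
    if annotation is not None and comparisons:
        pooled = set().union(*(c.deg_set() for c in comparisons))
        if pooled & annotation.universe:
            rows = enrich(pooled, annotation)
            write_enrichment(rows, str(out / "enrichment.tsv"))
            manifest["stages"]["enrichment"] = {"n_degs": len(pooled), "n_terms": len(rows)}

    # --- manifest -----------------------------------------------------------
    files = sorted(f for f in out.iterdir() if f.is_file() and f.name != "manifest.json")
    manifest["files"] = {f.name: _sha256(f) for f in files}
    manifest["run_hash"] = hashlib.sha256(
        json.dumps(manifest["files"], sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out
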