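# tagdge

Tag-based digital gene expression (DGE) analysis for NlaIII tag-seq: build a
database of 21-base CATG-anchored tags from reference transcripts, clean and
map tag libraries with at most one mismatch (multi-gene hits excluded),
quantify expression as TPM, call differentially expressed genes with an exact
two-library count test and Benjamini–Hochberg FDR, cluster expression
profiles with a from-scratch self-organizing tree algorithm (SOTA) or
hierarchical clustering, and test gene sets for term/pathway
over-representation. A synthetic-data module simulates references, libraries,
and annotations with planted ground truth so the whole pipeline is testable
offline.

## Modules

| module | contents |
| --- | --- |
| `tagdge.synthetic` | `make_reference`, `simulate_library`, `simulate_experiment`, `make_annotation`, planted ground truth |
| `tagdge.tagindex` | `build_index`, `gene_tag_sets`, TSV serialization |
| `tagdge.mapping` | `clean_tags`, `map_library`, `gene_expression` (TPM), `library_qc` |
| `tagdge.expression` | `assemble`, `stage_filter`, `log_transform` |
| `tagdge.differential` | `exact_tag_test`, `bh_adjust`, `call_degs`, `common_degs`, `relative_expression` |
| `tagdge.clustering` | `sota_cluster`, `hier_cluster`, `cluster_profile_summary` |
| `tagdge.enrichment` | `enrich`, `cluster_function_profile` |
| `tagdge.pipeline` / `tagdge.cli` | YAML-config driver and `tagdge` CLI |

Default parameters reproduce the canonical thresholds: singleton removal
(count ≥ 2), one mismatch outside the CATG anchor, FDR ≤ 0.001 with
|log2 ratio| ≥ 1, expressed-in-≥3-libraries-at-one-stage filtering, and six
clusters.

## CLI

```sh
tagdge all --config config.yaml          # simulate -> index -> map -> matrix
                                         #   -> DEG -> cluster -> enrich
tagdge simulate --config config.yaml
tagdge index --reference ref.fasta --out index.tsv
tagdge map --reference ref.fasta --library lib.tsv --out mapped.tsv --qc qc.tsv
tagdge dge --a ctrl.mapped.tsv --b line.mapped.tsv --out dge.tsv
tagdge cluster --matrix log2tpm.tsv --method sota --k 6 --out clusters.tsv
tagdge enrich --genes degs.txt --annotation ann.tsv --out enrichment.tsv
```

Example config:

```yaml
seed: 1
output_dir: out
simulate:
  n_genes: 200
  genotypes: [CTRL, LINE1]      # first genotype is the control
  stages: [s15, s20, s25]
  depth: 10000
  de_fraction: 0.05
  de_log2_effect: 2.0
  dispersion: 0.05
  error_rate: 0.005
  n_clusters: 6
annotation:
  simulate: {n_terms: 15}
params:
  filter_min_libraries: 2       # only 2 libraries per stage in this design
```

Instead of the `simulate` block, real inputs can be given as
`reference: {fasta: path}` plus a `libraries:` list of
`{id, genotype, stage, path}` entries (two-column tag/count TSV or
one-read-per-line text) and `annotation: {path: two_column.tsv}`.
Identical config + seed produces byte-identical outputs; `manifest.json`
records per-file SHA-256 hashes.

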