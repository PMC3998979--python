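import numpy as np
import pytest

from oracles import map_tags_all_pairs
from tagdge.mapping import (
    TagLibrary,
    clean_tags,
    gene_expression,
    library_qc,
    map_library,
    one_mismatch_neighbors,
    write_qc_table,
)
from tagdge.synthetic import SyntheticDesign, canonical_tag, make_reference, simulate_library
from tagdge.tagindex import build_index

TAG = "CATG" + "A" * 17


class TestCleanTags:
    def test_short_tag_dropped(self):
        lib = clean_tags({TAG: 5, "CATGCCC": 3})
        assert set(lib.clean_tags) == {TAG}
        assert lib.raw_total == 8 and lib.distinct_raw == 2

    def test_singleton_dropped(self):
        assert clean_tags({TAG: 1}).clean_tags == {}

    def test_n_containing_dropped(self):
        lib = clean_tags({"CATG" + "N" + "A" * 16: 10})
        assert lib.clean_tags == {}

    def test_min_count_boundary(self):
        assert clean_tags({TAG: 2}).clean_tags == {TAG: 2}

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            clean_tags({TAG: -1})

    def test_random_refilter_oracle(self):
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGTN"))
        raw = {}
        for _ in range(10_000):
            length = int(rng.choice([18, 21, 21, 21]))
            tag = "".join(rng.choice(bases, size=length, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            raw[tag] = raw.get(tag, 0) + int(rng.choice([1, 1, 1, 2, 5]))
        lib = clean_tags(raw)
        expected = {
            t: c for t, c in raw.items() if len(t) >= 21 and "N" not in t and c >= 2
        }
        assert lib.clean_tags == expected
        assert lib.clean_total == sum(expected.values())
        assert lib.distinct_clean == len(expected)
        assert lib.clean_total <= lib.raw_total
        assert lib.distinct_clean <= lib.distinct_raw


class TestMapLibrary:
    def test_exact_unique_hit(self):
        index = build_index({"g1": TAG})
        result = map_library(TagLibrary("x", 7, 1, {TAG: 7}), index)
        assert result.gene_counts == {"g1": 7}
        assert (result.distinct_mapped, result.ambiguous_distinct, result.unmapped_distinct) == (1, 0, 0)

    def test_two_gene_tag_is_ambiguous(self):
        index = build_index({"g1": TAG, "g2": TAG})
        result = map_library(TagLibrary("x", 7, 1, {TAG: 7}), index)
        assert result.gene_counts == {}
        assert result.ambiguous_distinct == 1

    def test_two_positions_one_gene_summed(self):
        seq = TAG + "C" * 9 + TAG
        index = build_index({"g1": seq})
        result = map_library(TagLibrary("x", 3, 1, {TAG: 3}), index)
        assert result.gene_counts == {"g1": 3}

    def test_one_mismatch_rescue(self):
        mutant = TAG[:10] + "C" + TAG[11:]
        index = build_index({"g1": TAG})
        assert map_library(TagLibrary("x", 4, 1, {mutant: 4}), index, max_mismatch=0).gene_counts == {}
        assert map_library(TagLibrary("x", 4, 1, {mutant: 4}), index, max_mismatch=1).gene_counts == {"g1": 4}

    def test_anchor_mismatch_not_allowed(self):
        mutant = "AATG" + TAG[4:]
        index = build_index({"g1": TAG})
        result = map_library(TagLibrary("x", 4, 1, {mutant: 4}), index, max_mismatch=1)
        assert result.gene_counts == {} and result.unmapped_distinct == 1

    def test_exact_match_priority_over_neighborhood(self):
        # TAG exactly matches g1; its 1-mismatch neighbor belongs to g2 only.
        other = TAG[:20] + "C"
        index = build_index({"g1": TAG, "g2": other})
        result = map_library(TagLibrary("x", 5, 1, {TAG: 5}), index, max_mismatch=1)
        assert result.gene_counts == {"g1": 5} and result.ambiguous_distinct == 0

    def test_wrong_length_rejected(self):
        index = build_index({"g1": TAG})
        with pytest.raises(ValueError):
            map_library(TagLibrary("x", 2, 1, {"CATGAA": 2}), index)

    def test_neighborhood_size(self):
        neighbors = list(one_mismatch_neighbors(TAG))
        assert len(neighbors) == 51 == len(set(neighbors))
        assert all(n[:4] == "CATG" for n in neighbors)

    @pytest.mark.parametrize("max_mismatch", [0, 1])
    def test_against_all_pairs_hamming_oracle(self, max_mismatch):
        reference = make_reference(50, length_range=(300, 500), seed=21)
        index = build_index(reference)
        rng = np.random.default_rng(22)
        keys = sorted(index.entries)
        clean = {}
        for _ in range(500):
            tag = keys[rng.integers(len(keys))]
            roll = rng.random()
            if roll < 0.5:  # mutate one base anywhere
                pos = int(rng.integers(21))
                alt = "ACGT".replace(tag[pos], "")[rng.integers(3)]
                tag = tag[:pos] + alt + tag[pos + 1 :]
            elif roll < 0.6:  # mutate two bases
                for pos in rng.choice(21, size=2, replace=False):
                    alt = "ACGT".replace(tag[pos], "")[rng.integers(3)]
                    tag = tag[:pos] + alt + tag[pos + 1 :]
            clean[tag] = clean.get(tag, 0) + int(rng.integers(2, 30))
        lib = TagLibrary("x", sum(clean.values()), len(clean), clean)
        result = map_library(lib, index, max_mismatch=max_mismatch)
        key_genes = {tag: index.genes_for(tag) for tag in index.entries}
        counts, n_map, n_amb, n_unm = map_tags_all_pairs(clean, key_genes, max_mismatch)
        assert result.gene_counts == counts
        assert (result.distinct_mapped, result.ambiguous_distinct, result.unmapped_distinct) == (
            n_map, n_amb, n_unm,
        )
        assert result.distinct_mapped + result.ambiguous_distinct + result.unmapped_distinct == lib.distinct_clean


class TestMappingProperties:
    def test_error_free_canonical_tags_all_map(self, small_experiment, small_index):
        design = SyntheticDesign(
            n_genes=150, genotype_ids=["C"], stage_ids=["s"], library_depth=5000,
            dispersion=0.0, error_rate=0.0, seed=2,
        )
        profile = {g: 40.0 for g in small_experiment.reference}
        lib = simulate_library(small_experiment.reference, profile, design, "C_s")
        clean = clean_tags(dict(lib.tags), library_id="C_s")
        result = map_library(clean, small_index, max_mismatch=0)
        assert result.unmapped_distinct == 0  # every canonical tag is indexed
        for tag in clean.clean_tags:
            assert len(small_index.genes_for(tag)) >= 1

    def test_mismatch_1_never_decreases_mapped_total(self, small_experiment, small_index):
        for lib_id, lib in small_experiment.libraries.items():
            clean = clean_tags(dict(lib.tags), library_id=lib_id)
            m0 = map_library(clean, small_index, max_mismatch=0)
            m1 = map_library(clean, small_index, max_mismatch=1)
            assert m1.mapped_clean_total >= m0.mapped_clean_total

    def test_mismatch_1_no_change_on_exact_unique_libraries(self, small_index, small_experiment):
        # a library made only of uniquely-mapping exact keys
        unique_keys = {
            tag: 5 for tag, occs in small_experiment.reference.items() if False
        }
        unique_keys = {}
        for tag in sorted(small_index.entries):
            if len(small_index.genes_for(tag)) == 1:
                unique_keys[tag] = 5
            if len(unique_keys) == 50:
                break
        lib = TagLibrary("u", 250, 50, unique_keys)
        m0 = map_library(lib, small_index, max_mismatch=0)
        m1 = map_library(lib, small_index, max_mismatch=1)
        assert m0.gene_counts == m1.gene_counts

    def test_accounting_identity_on_fixture(self, small_mappings):
        for clean, mapping in small_mappings.values():
            assert (
                mapping.distinct_mapped + mapping.ambiguous_distinct + mapping.unmapped_distinct
                == clean.distinct_clean
            )


class TestGeneExpression:
    def test_symmetry(self):
        from tagdge.mapping import MappingResult

        tpm = gene_expression(MappingResult("x", {"g1": 50, "g2": 50}))
        assert tpm == {"g1": 500000.0, "g2": 500000.0}

    def test_definition_single_count(self):
        from tagdge.mapping import MappingResult

        m = MappingResult("x", {"g1": 1, "g2": 10**6 - 1})
        assert gene_expression(m)["g1"] == 1.0

    def test_sum_conservation(self, small_mappings):
        for _, mapping in small_mappings.values():
            total = sum(gene_expression(mapping).values())
            assert total == pytest.approx(1e6, rel=1e-6)

    def test_zero_mapped_rejected(self):
        from tagdge.mapping import MappingResult

        with pytest.raises(ValueError):
            gene_expression(MappingResult("x", {}))


class TestLibraryQc:
    def test_printed_clean_pct(self):
        clean = TagLibrary("lib", 8374304, 389162, {})
        clean_total = 8144920
        from tagdge.mapping import MappingResult
        from tagdge.util import percentage

        assert percentage(3983215, clean_total) == 48.90

    def test_qc_from_objects(self, small_mappings):
        for clean, mapping in small_mappings.values():
            qc = library_qc(clean, mapping, n_reference_genes=150)
            assert qc.pct_clean_mapped == pytest.approx(
                round(100 * mapping.mapped_clean_total / clean.clean_total, 2), abs=0.01
            )
            assert 0 <= qc.pct_reference_genes <= 100

    def test_reference_gene_pct_printed(self):
        from tagdge.util import percentage

        assert percentage(22594, 37505) == 60.24
        assert percentage(48147, 188639) == 25.52

    def test_zero_reference_rejected(self, small_mappings):
        clean, mapping = next(iter(small_mappings.values()))
        with pytest.raises(ValueError):
            library_qc(clean, mapping, n_reference_genes=0)

    def test_mismatched_ids_rejected(self, small_mappings):
        (c1, m1), (c2, m2) = list(small_mappings.values())[:2]
        with pytest.raises(ValueError):
            library_qc(c1, m2, n_reference_genes=150)

    def test_qc_table_shape(self, tmp_path, small_mappings):
        qcs = [library_qc(c, m, 150) for c, m in small_mappings.values()]
        path = tmp_path / "qc.tsv"
        write_qc_table(qcs, str(path))
        lines = path.read_text().splitlines()
        assert len(lines) == 11  # header + 10 labeled rows
        assert lines[0].startswith("Summary\t")
        assert lines[6].startswith("Total % of clean tag\t")
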