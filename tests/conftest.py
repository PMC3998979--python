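import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tagdge.mapping import clean_tags, map_library
from tagdge.synthetic import SyntheticDesign, simulate_experiment
from tagdge.tagindex import build_index


@pytest.fixture(scope="session")
def small_experiment():
    """150 genes, 2 genotypes x 3 stages, noisy counts and sequencing errors."""
    design = SyntheticDesign(
        n_genes=150,
        genotype_ids=["CTRL", "LINE1"],
        stage_ids=["s15", "s20", "s25"],
        library_depth=8000,
        de_fraction=0.05,
        de_log2_effect=2.0,
        dispersion=0.05,
        error_rate=0.005,
        seed=11,
        n_clusters=6,
    )
    return simulate_experiment(design)


@pytest.fixture(scope="session")
def small_index(small_experiment):
    return build_index(small_experiment.reference)


@pytest.fixture(scope="session")
def small_mappings(small_experiment, small_index):
    out = {}
    for lib_id, lib in small_experiment.libraries.items():
        clean = clean_tags(dict(lib.tags), library_id=lib_id)
        out[lib_id] = (clean, map_library(clean, small_index, max_mismatch=1))
    return out
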