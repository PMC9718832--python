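import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from nccescan import SimulationConfig, generate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """The standard desk-scale study bundle: 1 Mb over two chromosomes,
    200 conserved islands, ten planted composites per class, no synteny
    breaking, no decoys."""
    return generate_bundle(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_config():
    """A fast bundle for tests that generate several of them."""
    return dict(
        genome_length=200_000,
        chrom_count=2,
        element_count=40,
        planted_per_class={cls: 4 for cls in
                           ("NCCE", "WIDE-CONTROL", "SCRAMBLE-1", "SCRAMBLE-2", "SCRAMBLE-3")},
        gene_count=30,
        term_count=8,
    )
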