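import warnings

import pytest

from splicefid.genome_annotation import GenomeSequence
from splicefid.synthetic_data import SimConfig, generate_counts, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A 30-gene synthetic world shared by read-only tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_world(SimConfig(seed=7, n_genes=30))


@pytest.fixture(scope="session")
def small_counts(small_world):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_counts(small_world, depth=200)


@pytest.fixture()
def toy_genome():
    return GenomeSequence({
        "chr1": "ACGT" * 250,          # 1000 bp
        "chr2": "GT" * 100 + "A" * 50,  # 250 bp
    })
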