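import numpy as np
import pytest

import breakprox as bp


@pytest.fixture(scope="session")
def excerpt_bprs():
    """The bundled 13-region published breakpoint excerpt."""
    return bp.example_bpr_table()


@pytest.fixture(scope="session")
def mammal_tree():
    return bp.example_phylogeny()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_genes():
    return [
        bp.GeneRecord("GENEA", "chr3", 127500000, 127501000, "+"),
        bp.GeneRecord("GENEB", "chr1", 10382300, 10382400, "-"),
        bp.GeneRecord("GENEC", "chr9", 1000, 2000, "."),
    ]
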