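import numpy as np
import pytest

from mutread.enzymes import load_catalog
from mutread.synthdata import (
    SynthesisConfig,
    make_genome,
    synthetic_signature_matrix,
)


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def pst(catalog):
    return catalog["PstI"]


@pytest.fixture(scope="session")
def apo(catalog):
    return catalog["ApoI"]


@pytest.fixture(scope="session")
def sigs6():
    """Six mutually dissimilar synthetic signatures."""
    return synthetic_signature_matrix(k=6)


@pytest.fixture(scope="session")
def planted_genome(catalog):
    """A 40 kb genome with two PstI/ApoI fragment pairs planted, plus truth."""
    config = SynthesisConfig(
        length=40_000,
        site_plan=[("PstI", 1_000), ("ApoI", 1_400), ("PstI", 5_000), ("ApoI", 5_380)],
        seed=11,
    )
    return make_genome(config, catalog)


@pytest.fixture(scope="session")
def context_genome():
    """A random genome long enough to carry every trinucleotide context."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=60_000))
    return {"chr1": seq}
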