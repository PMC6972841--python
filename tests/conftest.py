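import numpy as np
import pytest

from mirflux.quant import Locus, MatureMiRNAAnnotation
from mirflux.synthetic import SimulationConfig, make_mirna_reference


@pytest.fixture
def config():
    return SimulationConfig(seed=42, n_mirnas=20)


@pytest.fixture
def reference(config):
    return make_mirna_reference(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def single_mirna_annotation():
    return MatureMiRNAAnnotation(
        "mir-x", "TACGTACGTACGTACGTACGT", (Locus("chr1", "+", 100),))


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
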