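import pytest

from junctura import ChromosomeModel
from junctura.index_case import index_chromosome, index_junctions


@pytest.fixture(scope="session")
def chr6():
    return index_chromosome()


@pytest.fixture(scope="session")
def toy_model():
    """A small chromosome with a centrally placed centromere."""
    return ChromosomeModel("toy", 1000, centromere=(450, 550))


@pytest.fixture(scope="session")
def patient_junctions():
    return index_junctions()
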