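import random

import pytest

from attenkit.thermo import EnergyModel


@pytest.fixture(scope="session")
def rna_model():
    return EnergyModel.load("RNA")


@pytest.fixture(scope="session")
def dna_model():
    return EnergyModel.load("DNA")


@pytest.fixture()
def rng():
    return random.Random(20240117)


def random_stem(rng, length):
    return "".join(rng.choice("ACGT") for _ in range(length))
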