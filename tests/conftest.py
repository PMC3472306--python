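import numpy as np
import pytest

from tfbslens.features import PWM, DinucleotidePropertyTable, MotifCatalog
from tfbslens.io import load_default_property_table


@pytest.fixture(scope="session")
def default_table() -> DinucleotidePropertyTable:
    return load_default_property_table()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_pwm(length: int, rng: np.random.Generator, sharpness: float = 1.0) -> PWM:
    return PWM(rng.dirichlet(np.full(4, sharpness), size=length))


def random_table(n_attr: int, rng: np.random.Generator) -> DinucleotidePropertyTable:
    names = [f"attr{i}" for i in range(n_attr)]
    return DinucleotidePropertyTable(names, rng.normal(size=(n_attr, 16)) * 5)


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture()
def small_catalog() -> MotifCatalog:
    return MotifCatalog([("TGACTCA", 5.2), ("ACGTACGT", 7.4), ("GGGCGG", 3.1)])
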