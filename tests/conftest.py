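import numpy as np
import pytest

from piriminer.datasets import expand_bloom_clones, load_bloom_catalog, load_strain_cores


@pytest.fixture(scope="session")
def strain_cores() -> list[tuple[str, str]]:
    """Cores detected in cultured strains, with modification codes."""
    return load_strain_cores()


@pytest.fixture(scope="session")
def bloom_catalog() -> list[tuple[int, str]]:
    """(clone count, core) rows of the bloom metagenome library."""
    return load_bloom_catalog()


@pytest.fixture(scope="session")
def bloom_clones() -> list[tuple[str, str]]:
    """One (core, clone id) record per sequenced clone."""
    return expand_bloom_clones()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20120831)
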