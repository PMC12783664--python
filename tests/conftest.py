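import numpy as np
import pytest

from sonoglyph import (
    build_dictionary,
    canonical_stimulus_set,
    reversed_preset,
    split_familiar_novel,
    traditional_preset,
)


@pytest.fixture(scope="session")
def canonical_set():
    return canonical_stimulus_set()


@pytest.fixture(scope="session")
def trad_spec():
    return traditional_preset()


@pytest.fixture(scope="session")
def rev_spec():
    return reversed_preset()


@pytest.fixture(scope="session")
def trad_dict(trad_spec):
    return build_dictionary(trad_spec)


@pytest.fixture(scope="session")
def rev_dict(rev_spec):
    return build_dictionary(rev_spec)


@pytest.fixture(scope="session")
def partition(canonical_set):
    return split_familiar_novel(canonical_set, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_binary_image(rng, n=64, density=0.1):
    return (rng.random((n, n)) < density).astype(float)
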