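import numpy as np
import pytest

from persevo import Engine, PharmacodynamicParams, build_classes, build_mutation_kernel


@pytest.fixture(scope="session")
def params():
    return PharmacodynamicParams()


@pytest.fixture(scope="session")
def classes():
    return build_classes()


@pytest.fixture(scope="session")
def kernel():
    return build_mutation_kernel()


@pytest.fixture(scope="session")
def engine():
    return Engine()


@pytest.fixture(scope="session")
def engine_m0():
    """Engine with de novo mutation disabled."""
    return Engine(kernel=build_mutation_kernel(m=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
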