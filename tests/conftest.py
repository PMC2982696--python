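"""Shared fixtures: bundled models, reference curves, eliminated systems.

Expensive artefacts (Model 2's symbolic elimination, optimisation
campaigns) are session-scoped so every test file shares one instance.
"""

import warnings

import numpy as np
import pytest

from defit.elimination import get_system
from defit.models import boulier_example, model1, model2
from defit.simulate import simulate


@pytest.fixture(scope="session")
def m1():
    return model1()


@pytest.fixture(scope="session")
def m2():
    return model2()


@pytest.fixture(scope="session")
def mb():
    return boulier_example()


@pytest.fixture(scope="session")
def all_models(m1, m2, mb):
    return [m1, m2, mb]


@pytest.fixture(scope="session")
def ref1(m1):
    """Noiseless Model 1 reference curve (all states, tight tolerance)."""
    return simulate(m1, rtol=1e-12, atol=1e-12)


@pytest.fixture(scope="session")
def ref2(m2):
    return simulate(m2, rtol=1e-12, atol=1e-12)


@pytest.fixture(scope="session")
def refb(mb):
    return simulate(mb, rtol=1e-12, atol=1e-12)


@pytest.fixture(scope="session")
def sys1(m1):
    return get_system(m1)


@pytest.fixture(scope="session")
def sys2(m2):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return get_system(m2)


@pytest.fixture(scope="session")
def sysb(mb):
    return get_system(mb)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
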