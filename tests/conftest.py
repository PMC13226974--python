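import dataclasses

import pytest

from markovcea import ankle_fragility_model, run_psa
from markovcea.evidence import ParameterSet


@pytest.fixture(scope="session")
def ankle():
    """The packaged ankle-fragility base case: (ModelSpec, ParameterSet)."""
    return ankle_fragility_model()


@pytest.fixture(scope="session")
def ankle_spec(ankle):
    return ankle[0]


@pytest.fixture(scope="session")
def ankle_params(ankle):
    return ankle[1]


@pytest.fixture(scope="session")
def ankle_psa(ankle):
    """One shared 10 000-iteration PSA on the packaged model."""
    spec, params = ankle
    draws, summary = run_psa(spec, params, n=10_000, seed=1234)
    return draws, summary


@pytest.fixture(scope="session")
def fixed_params(ankle_params):
    """The packaged parameter set with every family forced to 'fixed'."""
    return ParameterSet(
        dataclasses.replace(d, family="fixed") for d in ankle_params.values()
    )
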