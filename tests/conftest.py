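import numpy as np
import pytest

from ldlresponse import bempedoic_model, population_params, statin_names, statin_profile


@pytest.fixture(scope="session")
def ba_model():
    """Bempedoic acid Emax model as fixed in the combination analysis."""
    return bempedoic_model("combination")


@pytest.fixture(scope="session")
def profiles():
    return {name: statin_profile(name) for name in statin_names()}


@pytest.fixture(scope="session")
def atorva_pop():
    """Baseline population shared by the goal-attainment simulations."""
    return population_params("atorvastatin")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
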