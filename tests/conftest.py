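import numpy as np
import pytest

from bridgetox.inference import McmcSettings
from bridgetox.model_core import (
    AnimalStudyData,
    ExchangeabilityWeights,
    HumanTrialData,
    ModelConfig,
    default_config,
    DEFAULT_TRANSLATION,
)
from bridgetox.synthetic_data import default_fixture
from bridgetox.trial_sim import preset_weights


@pytest.fixture(scope="session")
def animal_fixture():
    """The calibrated five-study rat/monkey dataset (session-cached)."""
    return default_fixture()


@pytest.fixture(scope="session")
def config_t1():
    """Single-subgroup config with the worked example's trial-1 weights."""
    return default_config([preset_weights("A", 1)])


@pytest.fixture(scope="session")
def config_robust_only():
    """Single-subgroup, non-exchangeable-only config (no animal species)."""
    return ModelConfig(
        species=(),
        translation={},
        weights=(ExchangeabilityWeights({}, human=0.0, robust=1.0),),
    )


@pytest.fixture(scope="session")
def fast_mcmc():
    return McmcSettings(chains=2, iterations=6000, burnin=1000, seed=123)


@pytest.fixture
def toy_animal():
    return [
        AnimalStudyData("m1", "monkey", [1.0, 10.0, 100.0], [4, 6, 6], [0, 1, 4]),
        AnimalStudyData("r1", "rat", [0.5, 5.0, 50.0], [5, 5, 5], [0, 2, 4]),
    ]


@pytest.fixture
def toy_human():
    return [HumanTrialData(1, [0.1, 0.5, 1.0], [3, 3, 6], [0, 0, 1])]
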