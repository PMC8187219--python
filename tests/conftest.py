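import numpy as np
import pytest

from toricratio import (
    DEFAULT_CONSTANTS,
    PopulationParams,
    ToricTranslationModel,
)


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def default_model():
    """Default synthetic cohort (full study size), truth attached."""
    return ToricTranslationModel.from_synthetic(PopulationParams())


@pytest.fixture(scope="session")
def default_results(default_model):
    return default_model.fit()


@pytest.fixture(scope="session")
def small_results():
    """Quick fitted cohort for structural checks."""
    m = ToricTranslationModel.from_synthetic(PopulationParams(n=400, seed=11))
    return m.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
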