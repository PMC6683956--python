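import numpy as np
import pytest

from radscav.model import ModelConfig, RateConstants, SpeciesState
from radscav.synthetic import default_sample_times
from radscav.units import ug_per_ml_to_uM


@pytest.fixture
def default_k() -> RateConstants:
    return RateConstants()


@pytest.fixture
def aaph_10mM_state() -> SpeciesState:
    """10 mM AAPH, nothing else — the baseline medium."""
    return SpeciesState(C_A=10000.0)


@pytest.fixture
def free_curcumin_config() -> ModelConfig:
    """Free curcumin (50 µg/ml ≈ 135.7 µM) in 10 mM AAPH, k_C = 200."""
    return ModelConfig(
        rate_constants=RateConstants(k_C=200.0),
        initial_state=SpeciesState(C_A=10000.0, C_C=ug_per_ml_to_uM(50.0)),
        mode="quasi-steady-radical",
    )


@pytest.fixture
def sample_times() -> np.ndarray:
    return default_sample_times()


@pytest.fixture
def minute_grid() -> np.ndarray:
    return np.arange(0.0, 1441.0)
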