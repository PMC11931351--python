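import numpy as np
import pytest
from hypothesis import settings

from nsdquant import synthetic_data as synth

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def metabolite_params() -> synth.ReleaseParams:
    return synth.METABOLITE_RELEASE


@pytest.fixture
def single_pool_truth() -> list[synth.GroundTruth]:
    """One analyte living purely in the cytoplasm: its normalized release
    share follows the release logistic exactly (no leakage term)."""
    return [synth.GroundTruth("solo", pool_cp=100.0, pool_ga=0.0)]


@pytest.fixture
def fine_grid() -> tuple[float, ...]:
    return tuple(np.arange(0.0, 401.0, 25.0))
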