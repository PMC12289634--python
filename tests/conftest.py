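import numpy as np
import pytest
from hypothesis import settings

from larynxseg.model import ModelConfig, SegmentationModel
from larynxseg.synthetic import generate_dataset

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def micro_model():
    return SegmentationModel(ModelConfig.micro(), seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """Twelve 64x64 scenes across the three obstruction strata."""
    return generate_dataset(12, seed=0, image_size=(64, 64))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
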