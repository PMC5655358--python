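import numpy as np
import pytest

from sdglu import SDModel
from sdglu.model import default_morphology


@pytest.fixture(scope="session")
def model() -> SDModel:
    """Default model with the packaged parameterization."""
    return SDModel()


@pytest.fixture(scope="session")
def morph():
    return default_morphology()


@pytest.fixture(scope="session")
def rest_state(model):
    return model.resting_state()
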