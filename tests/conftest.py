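import numpy as np
import pytest

from leeac import LesionSpec, generate, run_pipeline
from leeac.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def sharp_case():
    """Sharp, high-contrast synthetic lesion with ground truth."""
    return generate(LesionSpec(blur_sigma=0.5, seed=1))


@pytest.fixture(scope="session")
def sharp_run(sharp_case):
    """Default-config pipeline result on the sharp fixture (shared: ~5 s)."""
    image, truth = sharp_case
    return run_pipeline(image, PipelineConfig()), truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
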