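import numpy as np
import pytest

from lesionstretch import (
    BatConfig,
    ABCConfig,
    PipelineConfig,
    SyntheticLesionSpec,
    generate_lesion,
)


@pytest.fixture(scope="session")
def small_lesion():
    """A 32x32 low-contrast lesion sample for fast pipeline tests."""
    spec = SyntheticLesionSpec(
        height=32,
        width=32,
        center=(16.0, 16.0),
        semi_axes=(7.0, 5.0),
        blur_sigma=1.0,
        seed=7,
    )
    return generate_lesion(spec)


@pytest.fixture(scope="session")
def fast_config():
    """A reduced optimization budget for pipeline-level tests."""
    return PipelineConfig(
        bat=BatConfig(n_bats=6, n_iterations=5),
        abc=ABCConfig(n_iterations=5, limit=5),
    )
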