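import numpy as np
import pytest

from killfrac import ModelParams, SyntheticConfig


@pytest.fixture
def reference_params() -> ModelParams:
    """Study-typical reference: pooled treated BVF, rb 5 um, L 40 um."""
    return ModelParams(bvf=0.038, rb_um=5.0, L_um=40.0, fkill_m=0.25)


@pytest.fixture
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1234)


@pytest.fixture
def bvf_grid() -> np.ndarray:
    return np.array([0.005, 0.01, 0.05, 0.1, 0.3, 0.5])


@pytest.fixture
def rb_grid() -> np.ndarray:
    return np.array([0.01, 0.068, 0.2, 1.0])
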