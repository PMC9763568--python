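import numpy as np
import pytest

from seuneter.phantom import PhantomConfig, generate_phantom
from seuneter.postprocess import PostprocessConfig
from seuneter.schema_io import default_schema

EIGHT = np.ones((3, 3), dtype=bool)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def phantom_128(schema):
    """A clean 128x128 phantom used by the post-processing fixtures."""
    cfg = PhantomConfig(height=128, width=128, seed=3)
    return generate_phantom(cfg, schema)


@pytest.fixture(scope="session")
def pp_cfg_128():
    """Thresholds calibrated to the 128x128 phantom geometry."""
    return PostprocessConfig(ker_l=5, ker_s=3, eta_l=125, eta_s=20, eta_d=10)
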