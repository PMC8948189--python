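import numpy as np
import pytest

from cyclescope.protocol import ExperimentConfig, ROI
from cyclescope.synthetic import PhantomSpec, make_phantom


@pytest.fixture
def small_config() -> ExperimentConfig:
    return ExperimentConfig(
        n_cycles=1,
        port_map={"blocking": 1, "imaging": 2, "elution": 3,
                  "primary_1": 4, "secondary_1": 5, "wash": 6},
        rois=(ROI(2.0, 5.0, 5.0, 8.0, z_planes=1, label="section"),),
        flow_rate=500.0,
    )


@pytest.fixture
def textured_frame() -> np.ndarray:
    """A 128x128 textured 12-bit frame with reproducible content."""
    spec = PhantomSpec(shape=(128, 128), n_channels=1,
                       structures=("blobs",), rng_seed=7)
    return make_phantom(spec).observed[0]
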