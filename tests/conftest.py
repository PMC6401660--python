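import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import synquant as sq

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

VOXEL_DIAGONAL = float(np.linalg.norm((0.5, 0.1, 0.1)))


@pytest.fixture(scope="session")
def noiseless_truth() -> sq.SceneTruth:
    """A representative conjugate truth rendered without noise."""
    return sq.SceneTruth.with_polarity(
        0.5,
        perpendicular_offset=0.6,
        seed=11,
        extraction_fraction_true=0.5,
        lysosome_polarization_true=0.7,
    )


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_truth) -> sq.ImageStack:
    return sq.generate_conjugate(noiseless_truth)


@pytest.fixture(scope="session")
def noiseless_segmentation(noiseless_scene, noiseless_truth) -> sq.ConjugateSegmentation:
    return sq.ConjugateSegmentation.from_stack(
        noiseless_scene, noiseless_truth.bead_center, noiseless_truth.bead_radius
    )
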