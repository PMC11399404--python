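import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from tmaquant.quantify import GroundTruthBackend, QuantifyConfig, quantify_core
from tmaquant.synthetic import SyntheticCoreSpec, render_core


@pytest.fixture(scope="session")
def small_spec():
    """A fast 512-px core used by most unit tests."""
    return SyntheticCoreSpec(
        image_size=512, core_radius=200, n_cells=60, positive_fraction=0.3, seed=42
    )


@pytest.fixture(scope="session")
def small_core(small_spec):
    return render_core(small_spec, sample_id="S1", core_id="1", marker="CD3")


@pytest.fixture(scope="session")
def small_result(small_core):
    image, gt = small_core
    cfg = QuantifyConfig(backend=GroundTruthBackend(ground_truth=gt))
    return quantify_core(image, cfg)


def random_binary_mask(rng: np.random.Generator, shape=(64, 64), density=None):
    density = rng.uniform(0.0, 0.4) if density is None else density
    return rng.random(shape) < density
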