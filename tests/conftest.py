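import numpy as np
import pytest

from idifpet import FrameSchedule, PhantomSpec, TracerTemplate
from idifpet.synthetic import simulate_study


@pytest.fixture(scope="session")
def roli():
    return TracerTemplate.rolipram_like()


@pytest.fixture(scope="session")
def pbr():
    return TracerTemplate.pbr28_like()


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.clinical_default()


@pytest.fixture(scope="session")
def study_noisy(roli):
    """One full simulated study with calibrated noise (punctual sampling)."""
    return simulate_study(roli, PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def study_noiseless(roli):
    """Noiseless study for ROI-geometry and oracle comparisons."""
    return simulate_study(roli, PhantomSpec(seed=2, noise_alpha=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
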