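import numpy as np
import pytest

from wristemg.synthetic import (
    SynthConfig,
    default_contraction,
    generate_angle_trajectories,
    generate_markers_from_angles,
    generate_session,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """A short 3-trial bilateral session for plumbing tests."""
    cfg = SynthConfig(trial_duration=6.0, rest_duration=0.5)
    return generate_session(cfg, contraction_ids=(1, 2, 4), seed=99)


@pytest.fixture(scope="session")
def flexion_markers():
    """Noiseless markers for a 1 Hz flexion sinusoid trial."""
    spec = default_contraction(1, duration=8.0)
    angles = generate_angle_trajectories(spec, seed=5)
    return spec, angles, generate_markers_from_angles(angles, side="right", seed=5)
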