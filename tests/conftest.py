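import numpy as np
import pytest

from mtvalidate.protocol import Movement, MovementProtocolEntry
from mtvalidate.synthetic import ScenarioConfig, SensorPhysics, generate_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def ideal_scenario():
    """Small noiseless study configuration: 3 participants, ideal sensors."""
    return ScenarioConfig(
        n_participants=3,
        physics=SensorPhysics.ideal(),
        marker_noise_mm=0.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def ideal_dataset(tmp_path_factory, ideal_scenario):
    """On-disk noiseless dataset shared by pipeline-level tests."""
    out = tmp_path_factory.mktemp("ideal_dataset")
    manifest = generate_scenario(ideal_scenario, out)
    return out, manifest


@pytest.fixture
def flexion_entry():
    return MovementProtocolEntry(
        movement=Movement.FORWARD_FLEXION, position="standing",
        repetitions=3, amplitude_fractions=(0.5, 0.5, 1.0), end_range_deg=40.0)
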