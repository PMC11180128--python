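import numpy as np
import pytest

from flydense import BottleGeometry, SimConfig, default_stereo_rig


@pytest.fixture(scope="session")
def bottle():
    return BottleGeometry()


@pytest.fixture(scope="session")
def rig(bottle):
    return default_stereo_rig(bottle)


@pytest.fixture(scope="session")
def clean_sim_config():
    """Noise-free generator settings: exact projections, no dropout, no clutter."""
    return SimConfig(
        seed=1, pixel_noise_sd=0.0, dropout_rate=0.0, false_positive_rate=0.0
    )


@pytest.fixture(scope="session")
def noiseless_he_ground_truth(clean_sim_config, bottle):
    """Ground-truth trajectories of a full He recovery run, no observation noise."""
    from flydense.simulate import simulate_flies, simulate_o2_timecourse

    o2 = simulate_o2_timecourse("He", duration=clean_sim_config.duration)
    gt = simulate_flies(clean_sim_config, o2, bottle, "He")
    return o2, gt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
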