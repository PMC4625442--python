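import numpy as np
import pytest

from pilisort.config import ColonySimConfig, CloneEvent, TrapSimConfig


@pytest.fixture(scope="session")
def small_colony_config() -> ColonySimConfig:
    """Compact colony movie: one near-front clone, fast to render."""
    return ColonySimConfig(
        image_shape=(256, 256),
        n_frames=14,
        grid_shape=(4, 3),
        generation_time=41.0,
        initial_radius=4.0,
        clone_events=(CloneEvent(t0=60.0, r_norm=0.6, theta=1.1, phenotype="P+"),),
        seed=11,
    )


@pytest.fixture(scope="session")
def quiet_trap_config() -> TrapSimConfig:
    """Event-free 20 s trace at the default trap settings."""
    return TrapSimConfig(event_rate=0.0, duration=20.0, seed=4)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
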