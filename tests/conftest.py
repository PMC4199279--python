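import pytest

from msp.config import MSPConfig, NetworkConfig, ScheduleConfig
from msp.experiment import init_state


@pytest.fixture(scope="session")
def default_config() -> MSPConfig:
    return MSPConfig().validate()


def tiny_config(**schedule_overrides) -> MSPConfig:
    """A 4x4 excitatory grid with 4 inhibitory neurons, short windows.

    Small enough for fast mechanistic tests; not meant to reach
    homeostatic equilibrium.
    """
    kwargs = dict(
        lesion_onset=5,
        total_updates=10,
        lpz_rect=(150.0, 150.0, 300.0, 300.0),
        window_ms=100.0,
        dt_ms=1.0,
    )
    kwargs.update(schedule_overrides)
    schedule = ScheduleConfig(**kwargs)
    return MSPConfig(
        network=NetworkConfig(grid_nx=4, grid_ny=4, n_inhibitory=4),
        schedule=schedule,
    ).validate()


@pytest.fixture
def tiny_state():
    return init_state(tiny_config(), seed=123)


def make_state(config: MSPConfig, seed: int = 0):
    return init_state(config, seed)


def clear_connectivity(state) -> None:
    """Zero all synapses and elements (used to build frozen scenarios)."""
    state.w[:] = 0
    state.elements.a[:] = 0.0
    state.elements.d_ex[:] = 0.0
    state.elements.d_in[:] = 0.0
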