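"""Shared fixtures: one moderately long synthetic recording reused across tests."""

import numpy as np
import pytest

import swarmstate as ss


@pytest.fixture(scope="session")
def sim_config():
    """Stationary reference conditions: N=50, gamma=2/s, sigma_v=200 mm/s, k=4/s^2."""
    return ss.SimulationConfig(
        n_midges=50,
        gamma=2.0,
        sigma_v_target=200.0,
        spring_law=ss.SpringLaw.constant(4.0),
        duration=100.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def sim_recording(sim_config):
    """Simulated, differentiated and flight-filtered 10^4-frame recording."""
    rec = ss.simulate_swarm(sim_config)
    return ss.flight_filter(ss.differentiate(rec))


@pytest.fixture(scope="session")
def sim_snapshots(sim_recording):
    lo, hi = sim_recording.frame_range
    return [ss.snapshot(sim_recording, f) for f in range(lo, hi)]


@pytest.fixture(scope="session")
def sim_series(sim_recording, sim_config):
    return ss.compute_state_series(sim_recording, sim_config.spring_law)


def random_snapshot(rng, n=12, with_acc=True):
    """A generic random snapshot for oracle-equivalence tests."""
    return ss.FrameSnapshot(
        time=0.0,
        positions=rng.normal(0, 50, (n, 3)),
        velocities=rng.normal(0, 200, (n, 3)),
        accelerations=rng.normal(0, 500, (n, 3)) if with_acc else None,
        ids=np.arange(n),
    )
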