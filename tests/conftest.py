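"""Shared fixtures: phantom runs and synthetic beats used across the suite."""

import numpy as np
import pytest

import wavesep as ws
from wavesep.phantom import PhantomConfig, Segment
from wavesep.waveform import make_beat


@pytest.fixture(scope="session")
def default_output():
    """Steady-state run of the reference two-segment phantom, with provenance."""
    return ws.simulate(ws.default_config())


@pytest.fixture(scope="session")
def default_beat(default_output):
    return default_output.to_beat()


@pytest.fixture(scope="session")
def default_analysis(default_beat):
    return ws.analyse_beat(default_beat)


@pytest.fixture(scope="session")
def oracle_config():
    """Single-segment phantom in the leak-dominated regime.

    Weak terminal reflection and a long diastole make the diastolic decay
    a clean single exponential, so the fitted microcirculation/history
    extrapolation can be compared against the simulator's beat-of-origin
    tags at tight tolerance.
    """
    return PhantomConfig(
        segments=(Segment(0.24, 6.0, 4.5e-4),),
        terminal_reflection=0.15,
        distributed_loss_rate=3.0,
        leak_rate=2.5,
        heart_period_s=1.2,
        n_beats=12,
    )


@pytest.fixture(scope="session")
def oracle_output(oracle_config):
    return ws.simulate(oracle_config)


@pytest.fixture(scope="session")
def reflection_free_output():
    """Single-segment totally absorbent phantom (no backward waves)."""
    return ws.simulate(ws.single_segment_config())


def exact_decay_beat(p_mu=40.0, b=1.5, noise_sd=0.0, rng=None):
    """A beat whose diastole is an exact monoexponential decay.

    The diastolic limb is rewritten as p_mu + (P_es − p_mu)·exp(−b·t′)
    anchored at the *detected* valve-closure sample, so the fit recipe
    sees data exactly on its model manifold.
    """
    dt = 1e-3
    t = np.arange(0, 0.85, dt)
    u = np.where(t < 0.3, np.sin(np.pi * t / 0.3), 0.0)
    p = 70 + 30 * np.sin(np.pi * np.minimum(t, 0.45) / 0.9)
    beat = make_beat(t, p, u, 1060.0, 4.5e-4)
    i_vc = beat.fiducials.i_vc
    p = p.copy()
    p_es = p[i_vc]
    tail = t[i_vc:] - t[i_vc]
    p[i_vc:] = p_mu + (p_es - p_mu) * np.exp(-b * tail)
    if noise_sd > 0:
        p = p + rng.normal(0.0, noise_sd, p.shape)
    return make_beat(t, p, u, 1060.0, 4.5e-4)


@pytest.fixture
def decay_beat():
    return exact_decay_beat()
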