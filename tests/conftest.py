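import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from melanotrack import AcquisitionSettings, SimulationParams, Trajectory, simulate

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture
def settings():
    """The standard acquisition: 0.5 s cadence, 601 frames, 0.16 μm pixel."""
    return AcquisitionSettings()


@pytest.fixture
def short_settings():
    """A short recording for cheap tests (same cadence and pixel)."""
    return AcquisitionSettings(frame_interval=0.5, n_frames=81, pixel_size=0.16)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_trajectory(positions, settings=None, track_id="t0"):
    positions = np.asarray(positions, dtype=float)
    settings = settings or AcquisitionSettings(n_frames=max(2, len(positions)))
    return Trajectory(
        track_id=track_id,
        frames=np.arange(len(positions)),
        positions=positions,
        settings=settings,
    )


def brownian(D, settings, seed, **kw):
    return simulate(
        SimulationParams("brownian", D=D, **kw), settings, rng=np.random.default_rng(seed)
    )


def directional(V, settings, heading=0.0, **kw):
    return simulate(SimulationParams("directional", V=V, heading=heading, **kw), settings)
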