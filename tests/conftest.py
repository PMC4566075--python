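import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gliawave.config import SimulationConfig
from gliawave.simulate import generate_experiment

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A down-scaled experiment for fast unit tests (128 px field, 10 ROIs)."""
    return SimulationConfig(
        n_frames=80, field_size=(128, 128), n_stalks=5, n_lateral=5, seed=7
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return generate_experiment(small_config)


@pytest.fixture(scope="session")
def default_experiment():
    """One experiment at the standard acquisition scale (256 px, 40 ROIs)."""
    return generate_experiment(SimulationConfig(seed=11))


def make_single_event_experiment(
    noise_sd=0.0, sensor="calcium", frame_rate_hz=0.74, onset_s=60.0, seed=3, peak_dff=0.5
):
    """One stalk ROI firing exactly one transient; used as a known signal."""
    from gliawave.core import GroundTruth
    from gliawave.simulate import make_layout, render_movie

    cfg = SimulationConfig(
        n_frames=100,
        frame_rate_hz=frame_rate_hz,
        field_size=(64, 64),
        n_stalks=1,
        n_lateral=0,
        noise_sd=noise_sd,
        sensor=sensor,
        peak_dff=peak_dff,
        seed=seed,
    )
    layout = make_layout(cfg, seed)
    truth = GroundTruth(
        wave_onsets_s=np.array([onset_s]),
        recruited=[{1}],
        event_onsets={1: [onset_s]},
        n_rois=1,
    )
    movie = render_movie(layout, truth, cfg, seed)
    return cfg, layout, truth, movie
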