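import numpy as np
import pytest

from lapkit.core import EventSeries, PoseTrack, TimeSeries
from lapkit.synthetic import CalciumKernel, GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def short_bundle():
    """A 60 s default-condition session used by several read-only tests."""
    return generate_session(GeneratorConfig(duration_s=60.0, seed=7),
                            session_id="s0", animal_id="a0")


@pytest.fixture
def clean_config():
    """Noise- and artifact-free conditions: every planted feature is exact."""
    return GeneratorConfig(
        duration_s=30.0,
        bout_structure=[(2.0, 8), (10.0, 6), (20.0, 10)],
        noise_sd=0.0,
        motion_amp=0.0,
        pose_noise_px=0.0,
        bleach_tau_s=float("inf"),
        seed=0,
    )


@pytest.fixture
def gaussian_kernel():
    return CalciumKernel(shape="gaussian", width_s=0.4, amplitude=2.0)


def make_series(values, rate_hz=120.0, t0_s=0.0):
    return TimeSeries(np.asarray(values, dtype=float), rate_hz=rate_hz, t0_s=t0_s)


def make_track(y, rate_hz=120.0, likelihood=None, body_part="jaw", units="px"):
    y = np.asarray(y, dtype=float)
    lk = np.ones_like(y) if likelihood is None else np.asarray(likelihood, dtype=float)
    return PoseTrack(body_part=body_part, x=np.zeros_like(y), y=y,
                     likelihood=lk, rate_hz=rate_hz, units=units)


def make_events(times, kind="contact"):
    return EventSeries(np.asarray(times, dtype=float), kind=kind)
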