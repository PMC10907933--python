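import numpy as np
import pytest

from radarbreath import BreathingProfile, PipelineConfig, RoomScenario, simulate_recording

RADARS = ((0.0, 0.0), (4.0, 0.0), (0.0, 4.0))


def make_scenario(rr_bpm=12.0, subject=(1.2, 1.5), noise_sd=0.01, amplitude_m=0.005, **kwargs):
    """Stationary single-subject scene with two clutter scatterers."""
    kwargs.setdefault("clutter", [(0.5, 2.0, 2.0), (3.0, 1.0, 1.5)])
    return RoomScenario.stationary(
        subject,
        BreathingProfile.constant(rr_bpm, amplitude_m=amplitude_m),
        radar_positions_m=RADARS,
        noise_sd=noise_sd,
        **kwargs,
    )


@pytest.fixture(scope="session")
def clean_recording():
    """Three-window 12 bpm recording at 10 Hz with light noise."""
    return simulate_recording(make_scenario(), scan_rate_hz=10.0, n_scans=100 + 3 * 300, seed=7)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig(seed=1)


def sine_signal(freq_hz, duration_s=30.0, rate_hz=10.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration_s * rate_hz)) / rate_hz
    return amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
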