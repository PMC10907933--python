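"""Ground-truthed synthetic radargrams and paired-measurement tables.

The simulator emulates what a UWB impulse radar actually records in a
patient room: per-scan reflected-amplitude profiles over range bins,
containing static clutter, a breathing target whose range oscillates
with chest-wall displacement, and additive Gaussian receiver noise.
Three radars share one timestamp grid (perfect synchronization), with
independent noise streams derived from a single seed.

None of the study's raw recordings are deposited, so every pipeline
stage is exercised against these scenes, whose ground truth (true range,
true respiratory rate) is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .types import BreathingProfile, Radargram, RoomScenario, SynchronizedRecording

__all__ = [
    "simulate_displacement",
    "simulate_radargram",
    "simulate_recording",
    "DeviceErrorLaw",
    "generate_paired_measurements",
]

#: Default range-bin pitch, 45 cm / 50 bins.
DEFAULT_BIN_SPACING_M = 0.009

#: Default number of range bins per scan (covers 0 .. ~4.6 m at 9 mm pitch).
DEFAULT_N_BINS = 512

#: Gaussian pulse-response template width (std. dev., in bins).
DEFAULT_KERNEL_WIDTH_BINS = 3.0

#: Hard range ceiling of the device class.
MAX_RANGE_M = 30.0


def simulate_displacement(breathing: BreathingProfile, times_s: np.ndarray) -> np.ndarray:
    """Chest-wall displacement d(t) = A sin(2*pi * integral f dt + phase).

    The instantaneous breathing frequency f(t) (Hz) is linearly
    interpolated from the profile's ``rate_trace`` (bpm / 60) and
    integrated by the trapezoid rule, so rate drifts produce the correct
    cumulative phase.

    Parameters
    ----------
    breathing:
        Motion model (rate knots, half-amplitude, initial phase).
    times_s:
        Strictly increasing sample times (seconds).

    Returns
    -------
    Displacement in meters, same length as ``times_s``;
    ``|d(t)| <= amplitude_m`` everywhere.
    """
    t = np.asarray(times_s, dtype=float)
    if t.size == 0:
        raise ValueError("times must be nonempty")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    knots = np.asarray(breathing.rate_trace, dtype=float).reshape(-1, 2)
    f_hz = np.interp(t, knots[:, 0], knots[:, 1]) / 60.0
    phase = 2.0 * np.pi * cumulative_trapezoid(f_hz, t, initial=0.0) + breathing.phase_rad
    return breathing.amplitude_m * np.sin(phase)


def _gaussian_kernel(bin_centers: np.ndarray, n_bins: int, width_bins: float) -> np.ndarray:
    """Pulse-response template: unit-amplitude Gaussian at each center.

    ``bin_centers`` may be fractional; returns (n_centers, n_bins).
    """
    bins = np.arange(n_bins, dtype=float)
    return np.exp(-0.5 * ((bins[None, :] - np.asarray(bin_centers)[:, None]) / width_bins) ** 2)


def _target_ranges(
    scenario: RoomScenario, radar_index: int, times_s: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """True radar-to-chest range over time, incl. breathing and artifacts.

    Scenario clocks (rate knots, subject track, artifact segments) are
    relative to the start of the recording, not to the UNIX epoch.
    """
    rel = np.asarray(times_s, dtype=float) - times_s[0]
    pos = scenario.subject_position(rel)
    radar = scenario.radar_positions_m[radar_index]
    base = np.linalg.norm(pos - radar[None, :], axis=1)
    disp = simulate_displacement(scenario.breathing, rel)
    for start_s, end_s, scale_m in scenario.artifact_segments:
        mask = (rel >= start_s) & (rel < end_s)
        disp = disp + np.where(mask, rng.normal(0.0, scale_m, size=rel.size), 0.0)
    return base + disp


def simulate_radargram(
    scenario: RoomScenario,
    radar_index: int,
    scan_rate_hz: float = 20.0,
    n_scans: int = 600,
    seed: int | np.random.SeedSequence = 0,
    *,
    n_bins: int = DEFAULT_N_BINS,
    bin_spacing_m: float = DEFAULT_BIN_SPACING_M,
    kernel_width_bins: float = DEFAULT_KERNEL_WIDTH_BINS,
    target_amplitude: float = 1.0,
    start_time_s: float = 1.6e9,
) -> Radargram:
    """Render one radar's radargram of the scenario.

    Each scan is the superposition of fixed clutter kernels, a target
    kernel centered at ``(range + chest displacement) / bin_spacing``,
    and i.i.d. Gaussian noise of standard deviation ``scenario.noise_sd``.
    Deterministic given the seed.
    """
    if radar_index not in (0, 1, 2):
        raise ValueError("radar_index must be 0, 1 or 2")
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    rng = np.random.default_rng(seed)
    times = start_time_s + np.arange(n_scans) / scan_rate_hz
    ranges = _target_ranges(scenario, radar_index, times, rng)
    max_range = min(n_bins * bin_spacing_m, MAX_RANGE_M)
    if np.any(ranges < 0) or np.any(ranges >= max_range):
        raise ValueError(
            f"subject range outside representable span [0, {max_range:.2f}) m "
            f"for radar {radar_index}"
        )
    scans = target_amplitude * _gaussian_kernel(ranges / bin_spacing_m, n_bins, kernel_width_bins)
    radar = scenario.radar_positions_m[radar_index]
    for cx, cy, reflectivity in scenario.clutter:
        r = float(np.hypot(cx - radar[0], cy - radar[1]))
        if r < max_range:
            scans += reflectivity * _gaussian_kernel(
                np.array([r / bin_spacing_m]), n_bins, kernel_width_bins
            )
    if scenario.noise_sd > 0:
        scans = scans + rng.normal(0.0, scenario.noise_sd, size=scans.shape)
    return Radargram(
        scans=scans,
        timestamps_s=times,
        scan_rate_hz=scan_rate_hz,
        bin_spacing_m=bin_spacing_m,
        radar_position_m=radar,
    )


def simulate_recording(
    scenario: RoomScenario,
    scan_rate_hz: float = 20.0,
    n_scans: int = 600,
    seed: int = 0,
    **kwargs,
) -> SynchronizedRecording:
    """Render all three radars on one shared timestamp grid.

    Per-radar noise streams are independent, spawned from the single seed
    so the whole recording is reproducible from ``(scenario, seed)``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3)
    radargrams = [
        simulate_radargram(scenario, i, scan_rate_hz, n_scans, seed=children[i], **kwargs)
        for i in range(3)
    ]
    return SynchronizedRecording(radargrams=radargrams, sync_tolerance_s=0.0)


@dataclass(frozen=True)
class DeviceErrorLaw:
    """Additive error model for the device's RR readings.

    device = reference + bias + slope * (reference - center) + N(0, sd).

    A negative ``slope`` reproduces the over-reading at low rates and
    under-reading at high rates seen with radar-derived RR.
    """

    bias_bpm: float = 0.0
    sd_bpm: float = 0.0
    slope: float = 0.0
    center_bpm: float = 18.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.bias_bpm, self.sd_bpm, self.slope, self.center_bpm]).all():
            raise ValueError("error-law parameters must be finite")
        if self.sd_bpm < 0:
            raise ValueError("sd_bpm must be non-negative")


def generate_paired_measurements(
    n_subjects: int,
    pairs_per_subject: int = 8,
    rr_mean_bpm: float = 18.0,
    rr_sd_bpm: float = 4.0,
    device_error: DeviceErrorLaw = DeviceErrorLaw(),
    p_female: float = 0.5,
    p_cardiopulmonary: float = 0.5,
    interval_s: float = 900.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Device-vs-reference RR pairs with subject covariates.

    Reference rates are drawn per reading from a normal law truncated to
    the analysis band [6, 30] bpm; device readings follow
    ``device_error``.  Readings are spaced at 15-minute intervals per
    subject, mirroring bedside spot checks.  Deterministic given seed.

    Returns a DataFrame with columns ``subject_id, time_s, rr_device,
    rr_reference, sex, dx_group``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if pairs_per_subject < 1:
        raise ValueError("pairs_per_subject must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        sex = "female" if rng.random() < p_female else "male"
        dx = "cardiopulmonary" if rng.random() < p_cardiopulmonary else "noncardiopulmonary"
        for k in range(pairs_per_subject):
            ref = float(np.clip(rng.normal(rr_mean_bpm, rr_sd_bpm), 6.0, 30.0))
            dev = (
                ref
                + device_error.bias_bpm
                + device_error.slope * (ref - device_error.center_bpm)
                + (rng.normal(0.0, device_error.sd_bpm) if device_error.sd_bpm > 0 else 0.0)
            )
            rows.append(
                {
                    "subject_id": f"S{s:03d}",
                    "time_s": k * interval_s,
                    "rr_device": max(dev, 0.1),
                    "rr_reference": ref,
                    "sex": sex,
                    "dx_group": dx,
                }
            )
    return pd.DataFrame(rows)
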