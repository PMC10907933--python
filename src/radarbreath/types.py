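"""Core data containers shared across the pipeline.

A *radargram* is one radar's record of reflected amplitude versus range
bin (fast time) over successive scans (slow time).  Breathing appears as
a slow-time oscillation of the target's range, so every downstream stage
operates on the slow-time axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BreathingProfile",
    "RoomScenario",
    "Radargram",
    "SynchronizedRecording",
    "collinear",
]


def collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    """True if three planar points lie on one line (degenerate geometry)."""
    p = np.asarray(points, dtype=float)
    area2 = abs(
        (p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1])
        - (p[2, 0] - p[0, 0]) * (p[1, 1] - p[0, 1])
    )
    return area2 <= tol


@dataclass(frozen=True)
class BreathingProfile:
    """Quasi-periodic chest-wall motion model.

    Parameters
    ----------
    rate_trace:
        Sequence of ``(time_s, rr_bpm)`` knots; the instantaneous rate is
        linearly interpolated between them (held constant outside).
    amplitude_m:
        Chest displacement half-amplitude in meters; typical adult values
        are 2-10 mm.
    phase_rad:
        Initial phase of the oscillation.
    """

    rate_trace: Sequence[tuple[float, float]]
    amplitude_m: float = 0.005
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_m <= 0:
            raise ValueError("amplitude_m must be positive")
        rates = np.asarray([r for _, r in self.rate_trace], dtype=float)
        if rates.size == 0:
            raise ValueError("rate_trace must contain at least one knot")
        if np.any(rates <= 0):
            raise ValueError("all breathing rates must be positive (bpm)")

    @classmethod
    def constant(
        cls, rr_bpm: float, amplitude_m: float = 0.005, phase_rad: float = 0.0
    ) -> "BreathingProfile":
        return cls(rate_trace=[(0.0, rr_bpm)], amplitude_m=amplitude_m, phase_rad=phase_rad)


@dataclass
class RoomScenario:
    """Ground-truth description of a monitored room.

    Three radars in a non-collinear (triangulated) placement observe a
    single breathing subject plus static clutter.  ``clutter`` entries are
    ``(x_m, y_m, reflectivity)`` fixed planar scatterers.  Optional
    ``artifact_segments`` are ``(start_s, end_s, displacement_scale_m)``
    intervals of gross-motion noise added to the chest displacement.
    """

    radar_positions_m: np.ndarray
    subject_track: Sequence[tuple[float, float, float]]
    breathing: BreathingProfile
    clutter: Sequence[tuple[float, float, float]] = field(default_factory=list)
    noise_sd: float = 0.0
    artifact_segments: Sequence[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.radar_positions_m = np.asarray(self.radar_positions_m, dtype=float)
        if self.radar_positions_m.shape != (3, 2):
            raise ValueError("exactly 3 planar radar positions required")
        if collinear(self.radar_positions_m):
            raise ValueError("radar positions are collinear; triangulated placement required")
        track = np.asarray(self.subject_track, dtype=float)
        if track.ndim != 2 or track.shape[1] != 3 or track.shape[0] < 1:
            raise ValueError("subject_track must be rows of (time_s, x_m, y_m)")
        if track.shape[0] > 1 and np.any(np.diff(track[:, 0]) <= 0):
            raise ValueError("subject_track times must be strictly increasing")
        self.subject_track = track
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def subject_position(self, times_s: np.ndarray) -> np.ndarray:
        """Interpolated planar subject position at each time (n, 2)."""
        track = np.asarray(self.subject_track, dtype=float)
        t = np.asarray(times_s, dtype=float)
        x = np.interp(t, track[:, 0], track[:, 1])
        y = np.interp(t, track[:, 0], track[:, 2])
        return np.column_stack([x, y])

    @classmethod
    def stationary(
        cls,
        subject_xy: tuple[float, float],
        breathing: BreathingProfile,
        radar_positions_m: Sequence[Sequence[float]] = ((0.0, 0.0), (4.0, 0.0), (0.0, 4.0)),
        **kwargs,
    ) -> "RoomScenario":
        """Convenience constructor for a non-moving subject."""
        return cls(
            radar_positions_m=np.asarray(radar_positions_m, dtype=float),
            subject_track=[(0.0, subject_xy[0], subject_xy[1])],
            breathing=breathing,
            **kwargs,
        )


@dataclass
class Radargram:
    """One radar's slow-time x range-bin amplitude record."""

    scans: np.ndarray  # (n_scans, n_bins)
    timestamps_s: np.ndarray  # UNIX seconds, strictly increasing
    scan_rate_hz: float
    bin_spacing_m: float
    radar_position_m: np.ndarray  # planar (2,)

    def __post_init__(self) -> None:
        self.scans = np.asarray(self.scans, dtype=float)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.radar_position_m = np.asarray(self.radar_position_m, dtype=float)
        if self.scans.ndim != 2:
            raise ValueError("scans must be a 2D (n_scans, n_bins) array")
        if self.timestamps_s.shape != (self.scans.shape[0],):
            raise ValueError("one timestamp per scan required")
        if self.timestamps_s.size > 1 and np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.scan_rate_hz <= 0:
            raise ValueError("scan_rate_hz must be positive")
        if self.bin_spacing_m <= 0:
            raise ValueError("bin_spacing_m must be positive")

    @property
    def n_scans(self) -> int:
        return self.scans.shape[0]

    @property
    def n_bins(self) -> int:
        return self.scans.shape[1]

    def replace_scans(self, scans: np.ndarray) -> "Radargram":
        """New radargram sharing metadata, with different scan data."""
        return Radargram(
            scans=np.asarray(scans, dtype=float),
            timestamps_s=self.timestamps_s,
            scan_rate_hz=self.scan_rate_hz,
            bin_spacing_m=self.bin_spacing_m,
            radar_position_m=self.radar_position_m,
        )


@dataclass
class SynchronizedRecording:
    """Three time-aligned radargrams observing the same scene."""

    radargrams: Sequence[Radargram]
    sync_tolerance_s: float = 0.0

    def __post_init__(self) -> None:
        if len(self.radargrams) != 3:
            raise ValueError("exactly 3 radargrams required")
        r0 = self.radargrams[0]
        for r in self.radargrams[1:]:
            if r.n_scans != r0.n_scans:
                raise ValueError("radargrams must share n_scans")
            if r.scan_rate_hz != r0.scan_rate_hz or r.bin_spacing_m != r0.bin_spacing_m:
                raise ValueError("radargrams must share scan_rate_hz and bin_spacing_m")
            offset = (
                np.max(np.abs(r.timestamps_s - r0.timestamps_s)) if r.n_scans else 0.0
            )
            if offset > self.sync_tolerance_s + 1e-12:
                raise ValueError(
                    f"timestamps desynchronized by {offset:.6g} s "
                    f"(tolerance {self.sync_tolerance_s:.6g} s)"
                )

    @property
    def scan_rate_hz(self) -> float:
        return self.radargrams[0].scan_rate_hz

    @property
    def bin_spacing_m(self) -> float:
        return self.radargrams[0].bin_spacing_m

    @property
    def n_scans(self) -> int:
        return self.radargrams[0].n_scans

    @property
    def radar_positions_m(self) -> np.ndarray:
        return np.stack([r.radar_position_m for r in self.radargrams])
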