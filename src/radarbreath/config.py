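"""Pipeline configuration: every stage parameter in one validated record."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Stage parameters for the end-to-end RR pipeline.

    Attributes
    ----------
    n_background_scans:
        Scans at the head of the recording used as the clutter background.
    window_s:
        Analysis window length in seconds.
    low_bpm, high_bpm:
        Breathing-band edges in breaths per minute.
    transition_hz, stopband_db:
        Band-pass transition width and stopband attenuation.
    focus_bins:
        Range bins in the focus window around the location bin.
    max_lag_s:
        Largest alignment shift allowed in sum-align.
    process_noise, measurement_noise:
        Kalman constant-velocity model noises (m^2/s^3, m^2).
    hop_s:
        Window hop; ``None`` means non-overlapping windows.
    seed:
        Root seed; per-stage streams are derived from it.
    """

    n_background_scans: int = 100
    window_s: float = 30.0
    low_bpm: float = 6.0
    high_bpm: float = 30.0
    transition_hz: float = 0.05
    stopband_db: float = 40.0
    focus_bins: int = 50
    max_lag_s: float = 2.0
    process_noise: float = 0.01
    measurement_noise: float = 0.05
    hop_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_scans < 1:
            raise ValueError("n_background_scans must be >= 1")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not (0 < self.low_bpm < self.high_bpm):
            raise ValueError("need 0 < low_bpm < high_bpm")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)
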