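"""Recording container I/O and scenario configuration.

Recordings are stored in an HDF5 container with groups ``radar0..2``
(datasets ``scans``, ``timestamps_s``) and root attributes
``scan_rate_hz``, ``bin_spacing_m``, ``radar_positions_m`` and
``schema_version``.  Scenarios are described in YAML.
"""

from __future__ import annotations

import numpy as np
import yaml

import h5py

from .types import BreathingProfile, Radargram, RoomScenario, SynchronizedRecording

__all__ = ["read_recording", "write_recording", "scenario_from_yaml", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"


def write_recording(recording: SynchronizedRecording, path) -> None:
    """Write a synchronized recording to the HDF5 container format."""
    if recording.n_scans == 0:
        raise ValueError("refusing to write an empty recording (n_scans = 0)")
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["scan_rate_hz"] = recording.scan_rate_hz
        fh.attrs["bin_spacing_m"] = recording.bin_spacing_m
        fh.attrs["radar_positions_m"] = recording.radar_positions_m
        fh.attrs["sync_tolerance_s"] = recording.sync_tolerance_s
        for i, rg in enumerate(recording.radargrams):
            grp = fh.create_group(f"radar{i}")
            grp.create_dataset("scans", data=rg.scans)
            grp.create_dataset("timestamps_s", data=rg.timestamps_s)


def read_recording(path, sync_tolerance_s: float | None = None) -> SynchronizedRecording:
    """Read and validate a recording container.

    Raises a ``ValueError`` naming the violated invariant for missing
    groups, shape mismatches, unsupported schema versions, or
    desynchronized timestamps.
    """
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {version!r}; expected {SCHEMA_VERSION!r}")
        for key in ("scan_rate_hz", "bin_spacing_m", "radar_positions_m"):
            if key not in fh.attrs:
                raise ValueError(f"container missing root attribute {key!r}")
        scan_rate = float(fh.attrs["scan_rate_hz"])
        bin_spacing = float(fh.attrs["bin_spacing_m"])
        positions = np.asarray(fh.attrs["radar_positions_m"], dtype=float)
        if sync_tolerance_s is None:
            sync_tolerance_s = float(fh.attrs.get("sync_tolerance_s", 0.5 / scan_rate))
        radargrams = []
        for i in range(3):
            name = f"radar{i}"
            if name not in fh:
                raise ValueError(f"container missing group {name!r}")
            grp = fh[name]
            for ds in ("scans", "timestamps_s"):
                if ds not in grp:
                    raise ValueError(f"group {name!r} missing dataset {ds!r}")
            scans = np.asarray(grp["scans"], dtype=float)
            ts = np.asarray(grp["timestamps_s"], dtype=float)
            if scans.ndim != 2 or ts.shape != (scans.shape[0],):
                raise ValueError(f"group {name!r}: scans/timestamps shape mismatch")
            radargrams.append(
                Radargram(
                    scans=scans,
                    timestamps_s=ts,
                    scan_rate_hz=scan_rate,
                    bin_spacing_m=bin_spacing,
                    radar_position_m=positions[i],
                )
            )
    return SynchronizedRecording(radargrams=radargrams, sync_tolerance_s=sync_tolerance_s)


def scenario_from_yaml(path) -> tuple[RoomScenario, dict]:
    """Load a RoomScenario plus run settings from a scenario YAML file.

    Recognized keys: ``radars`` (3 x [x, y] m), ``subject_track`` (rows
    of [t, x, y] or a single [x, y]), ``breathing`` (``rates`` as bpm or
    [t, bpm] rows, ``amplitude_m``, ``phase_rad``), ``clutter`` (rows of
    [x, y, reflectivity]), ``noise_sd``, ``artifacts``, and run settings
    ``scan_rate_hz``, ``n_scans``, ``seed``, ``n_bins``,
    ``bin_spacing_m``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    breathing_raw = data.get("breathing", {})
    rates = breathing_raw.get("rates", 15.0)
    if isinstance(rates, (int, float)):
        rate_trace = [(0.0, float(rates))]
    else:
        rate_trace = [(float(t), float(r)) for t, r in rates]
    breathing = BreathingProfile(
        rate_trace=rate_trace,
        amplitude_m=float(breathing_raw.get("amplitude_m", 0.005)),
        phase_rad=float(breathing_raw.get("phase_rad", 0.0)),
    )
    track = data["subject_track"]
    if len(track) and isinstance(track[0], (int, float)):
        track = [[0.0, track[0], track[1]]]
    scenario = RoomScenario(
        radar_positions_m=np.asarray(data["radars"], dtype=float),
        subject_track=[(float(t), float(x), float(y)) for t, x, y in track],
        breathing=breathing,
        clutter=[tuple(map(float, c)) for c in data.get("clutter", [])],
        noise_sd=float(data.get("noise_sd", 0.0)),
        artifact_segments=[tuple(map(float, a)) for a in data.get("artifacts", [])],
    )
    run = {
        "scan_rate_hz": float(data.get("scan_rate_hz", 20.0)),
        "n_scans": int(data.get("n_scans", 600)),
        "seed": int(data.get("seed", 0)),
    }
    if "n_bins" in data:
        run["n_bins"] = int(data["n_bins"])
    if "bin_spacing_m" in data:
        run["bin_spacing_m"] = float(data["bin_spacing_m"])
    return scenario, run
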