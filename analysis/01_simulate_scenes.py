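"""Render the benchmark radar scenes used by the downstream analyses.

Simulates a stationary breathing subject observed by three radars in a
triangulated placement, across the 6-30 bpm analysis band, and writes
one recording container plus ground-truth CSV per rate under
scratch/scenes/ (bulky intermediates).  A clean 14 bpm scene is also written at three noise
levels for the degradation analysis.

Run from the repository root:  python analysis/01_simulate_scenes.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from radarbreath import BreathingProfile, RoomScenario, simulate_recording, write_recording

OUT = Path("scratch/scenes")
SCAN_RATE_HZ = 10.0
N_SCANS = 100 + 3 * 300  # 100 background scans + three 30 s windows
RADARS = ((0.0, 0.0), (4.0, 0.0), (0.0, 4.0))
SUBJECT = (1.2, 1.5)
CLUTTER = [(0.5, 2.0, 2.0), (3.0, 1.0, 1.5)]


def scene(rr_bpm: float, noise_sd: float = 0.01) -> RoomScenario:
    return RoomScenario.stationary(
        SUBJECT,
        BreathingProfile.constant(rr_bpm),
        radar_positions_m=RADARS,
        clutter=CLUTTER,
        noise_sd=noise_sd,
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, rr in enumerate(range(6, 31, 2)):
        rec = simulate_recording(scene(float(rr)), SCAN_RATE_HZ, N_SCANS, seed=100 + i)
        path = OUT / f"rate_{rr:02d}bpm.h5"
        write_recording(rec, path)
        manifest.append({"file": path.name, "true_rr_bpm": rr, "noise_sd": 0.01, "seed": 100 + i})
    for level, noise in enumerate((0.02, 0.2, 0.8)):
        for seed in (1, 2, 3):
            rec = simulate_recording(scene(14.0, noise), SCAN_RATE_HZ, N_SCANS, seed=seed)
            path = OUT / f"noise_l{level}_s{seed}.h5"
            write_recording(rec, path)
            manifest.append(
                {"file": path.name, "true_rr_bpm": 14.0, "noise_sd": noise, "seed": seed}
            )
    pd.DataFrame(manifest).to_csv(OUT / "manifest.csv", index=False)
    print(f"wrote {len(manifest)} scenes to {OUT} "
          f"({SCAN_RATE_HZ:g} Hz, {N_SCANS} scans, subject at {SUBJECT})")


if __name__ == "__main__":
    main()
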