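# radarbreath

Contactless respiratory-rate (RR) estimation from ultrawideband (UWB)
impulse-radar recordings, with the method-comparison statistics used to
validate such devices against manual counting.

## The problem

Respiratory rate is the most informative and most neglected vital sign;
current bedside methods are either labor-intensive (manual counting) or
motion-sensitive (transthoracic impedance plethysmography). A UWB impulse
radar measures the distance to a reflecting target by two-way
time-of-flight, so the millimetre-scale motion of the chest wall appears as
a slow oscillation of the target's range. This package implements the full
chain from raw three-radar *radargrams* (slow-time × range-bin amplitude
records) to per-window RR estimates, and the agreement analysis comparing
device readings against a reference method.

## Pipeline

For each 30 s analysis window:

1. **Clutter removal** — subtract the per-bin mean of the first 100 scans
   recorded with no subject present (static walls/furniture vanish).
2. **Breathing band-pass** — equiripple FIR over 6–30 breaths/min
   = [0.1, 0.5] Hz, applied zero-phase along slow time; DC sits in the
   stopband.
3. **Localization** — per-radar range from the slow-time variance profile,
   least-squares trilateration of the three ranges, constant-velocity
   Kalman filtering of the planar track.
4. **Sum-align fusion** — 50 range bins (45 cm) centred on the subject's
   location bin; the highest-RMS bin series is the reference, the other 49
   are lag-aligned to it by cross-correlation and summed.
5. **ICA selection** — FastICA unmixes the three radars' fused signals;
   the component with the strongest spectral peak inside [0.1, 0.5] Hz is
   the breathing signal.
6. **Rate estimation** — two methods: the interpolated in-band FFT peak
   (`rr_fft`), and the hysteresis zero-crossing rate (`rr_zc`),
   `RR = 60 · f` where `f = crossings / (2 · duration)`.

Agreement statistics (module `radarbreath.agreement`): Bland–Altman bias
`b = mean(d)` with limits of agreement `b ± 1.96 · SD(d)` for differences
`d = device − reference`, the fraction of `|d| ≤ 2` bpm (clinical limit),
ICC(2,1) (two-way random effects, absolute agreement, single measures) with
its F-based 95 % CI, and per-subject mean absolute error.

Because clinical radar recordings are rarely shareable, the package ships a
ground-truthed simulator (`radarbreath.synthetic`): three synchronized
radars rendering a breathing subject (sinusoidal chest displacement,
default half-amplitude 5 mm), static clutter and receiver noise, plus a
generator of paired device/reference RR tables with a configurable
bias/spread/slope error law.

## Worked example

```python
import radarbreath as rb

scene = rb.RoomScenario.stationary(
    (1.2, 1.5),                       # subject position (m)
    rb.BreathingProfile.constant(12), # 12 breaths/min, 5 mm amplitude
    clutter=[(0.5, 2.0, 2.0), (3.0, 1.0, 1.5)],
    noise_sd=0.01,
)
rec = rb.simulate_recording(scene, scan_rate_hz=10.0, n_scans=1000, seed=7)
print(rb.estimate_rr_series(rec, rb.PipelineConfig(seed=1)))
```

prints one row per 30 s window (after the 100 background scans):

```
   window_start_s  rr_fft_bpm  rr_zc_bpm  selected_component_index flags
0    1.600000e+09   11.964121       12.0                         1
1    1.600000e+09   11.979921       13.0                         1
2    1.600000e+09   11.981119       12.0                         0
```

Both estimators recover the commanded 12 bpm: the spectral estimate to
within 0.04 bpm, the zero-crossing estimate to its 1 bpm counting
granularity.

The same workflow is available from the shell:

```sh
radarbreath simulate --scenario examples/room_scenario.yaml --out rec.h5 --truth truth.csv
radarbreath estimate --in rec.h5 --out rr.csv
radarbreath agree --pairs pairs.csv --out report.json
```

## Analysis scripts

The `analysis/` drivers reproduce the package's benchmark study:

- `01_simulate_scenes.py` — renders the 6–30 bpm scene grid and a
  three-level noise ladder into `scratch/scenes/`.
- `02_estimate_rates.py` — runs the pipeline on every scene; writes
  `results/rate_recovery.csv` (100 % of window estimates within ±1 bpm on
  the clean grid) and `results/noise_ladder.csv` (spectral RMSE 0.041 →
  0.128 → 10.975 bpm as noise grows).
- `03_agreement_stats.py` — generates paired readings whose error law
  echoes a radar-vs-manual agreement level (pooled bias −0.76 bpm, LoA
  span ±10.4, diagnosis-group biases −2.39 / +1.21) and recomputes
  Bland–Altman, ICC(2,1), MAE and subgroup reports from the sample
  (`results/agreement_report.json`).

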