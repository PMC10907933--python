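# Stationary subject breathing at 14 bpm, two static clutter scatterers.
radars: [[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]]
subject_track: [[0.0, 1.2, 1.5]]
breathing:
  rates: 14.0
  amplitude_m: 0.005
clutter:
  - [0.5, 2.0, 2.0]
  - [3.0, 1.0, 1.5]
noise_sd: 0.01
scan_rate_hz: 10.0
n_scans: 1000     # 100 background scans + three 30 s windows
seed: 3
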