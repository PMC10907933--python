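# Methods

## Sensing model

A UWB impulse radar emits short pulses and records the reflected amplitude
as a function of round-trip delay, discretized into range bins (here
9 mm/bin, so the standard 50-bin focus window spans 45 cm). Across
successive scans (slow time) a breathing subject produces a quasi-periodic
oscillation of the target's apparent range with the chest-wall
displacement, typically 2–10 mm half-amplitude, in the 6–30 breaths/min
band (0.1–0.5 Hz). Static reflectors (clutter) are constant in slow time.
Three radars in a non-collinear placement view the same subject so that at
least one has a favourable aspect on the chest wall and the subject can be
trilaterated.

## Synthetic scenes

The simulator renders each scan as a superposition of:

- a target kernel — a Gaussian pulse-response template (default width
  σ = 3 bins) centred at `(‖radar − subject‖ + d(t)) / bin_spacing`, where
  `d(t) = A sin(2π ∫ f dt + φ)` with the instantaneous frequency `f`
  linearly interpolated from the commanded rate trace (so rate drifts
  accumulate the correct phase);
- fixed clutter kernels at each static scatterer's range;
- i.i.d. Gaussian receiver noise.

All three radars share one timestamp grid (perfect synchronization);
per-radar noise streams are spawned from a single seed, so a recording is
a pure function of (scenario, seed). Optional artifact segments add
broadband displacement noise to emulate gross body motion.

What the simulator does *not* model: electromagnetic propagation detail,
antenna patterns, multipath, cardiac micro-motion, multiple people,
radar-to-radar clock skew, and non-Gaussian interference. Passing tests
therefore demonstrate that the algorithm chain is correct under its stated
signal model, not that the device performs clinically; quantitative
agreement with bedside readings cannot be established from simulation.

Default study conditions: scan rate 10 Hz in simulations (the hardware
scans at up to 125 Hz, but the breathing band tops out at 0.5 Hz, so 10 Hz
is already 10× oversampled and keeps benchmark runtimes in seconds; the
filter-design contract is additionally exercised at 125 Hz), recordings of
100 background scans plus three 30 s windows, subject at (1.2, 1.5) m
inside a radar triangle of 4 m sides, two clutter scatterers, noise SD
0.01 in target-amplitude units.

## Pipeline choices

**Clutter removal.** Per-bin mean of the first 100 scans (no subject
present), subtracted window-by-window of 30 s. The same global background
is reused for every window by default; a per-window re-estimate is
available behind a flag. Linear, idempotent on static scenes.

**Band-pass.** One equiripple FIR stage covers both stated goals (DC
rejection and band restriction): passband [0.1, 0.5] Hz, transition
0.05 Hz, stopband 40 dB, tap count from the Kaiser estimate forced odd.
Applied forward–backward (zero phase) via FFT convolution with the
squared impulse response and zero-padded edges, so window timing is
preserved exactly. Zero-phase application doubles the dB attenuation;
single-pass numbers are quoted in the filter contract.

**Range detection.** After clutter removal, the breathing subject is the
dominant dynamic scatterer, so range is read off the slow-time variance
profile. With a smooth pulse kernel the variance peaks on the kernel
*flanks* (largest amplitude gradient), symmetrically about the true bin —
a raw argmax is biased by about one kernel width. The detector therefore
takes the variance-weighted centroid of the bins within half of the
profile maximum, which centres the flank pair on the target and stays
within ±1 bin of truth on noiseless scenes.

**Trilateration and tracking.** The three circle equations are linearized
by subtracting the first from the others; least squares is exact on
consistent ranges. The track is smoothed by a constant-velocity Kalman
*filter* (forward pass only — no backward smoothing), per axis, with
white-acceleration process noise 0.01 m²/s³ and measurement variance
0.05 m²; the Kalman state persists across windows.

**Sum-align.** Within the 50-bin focus window the highest-RMS series is
the reference; each other series is shifted by the integer lag (|lag| ≤
2 s) maximizing its cross-correlation with the reference (ties toward the
smallest shift), with zero-padded overhang, then all 50 are summed. The
2 s lag bound is shorter than the slowest breath period (10 s at 6 bpm),
preventing cycle-skipping.

**ICA selection.** The three fused signals are standardized and unmixed
by FastICA (fixed seed; deterministic). Each component's zero-padded
magnitude spectrum is evaluated inside [0.1, 0.5] Hz and the component
with the largest single peak wins; ties break toward the lower frequency.
ICA's sign/scale ambiguity is resolved by unit-variance normalization
with positive peak-frequency phase — rate estimates are unaffected either
way. Mutually (anti)correlated inputs (rank-one) skip ICA and return the
standardized common signal with a `rank_deficient` flag.

**Rate estimators.** A 30 s window resolves 1/30 Hz = 2 bpm natively;
the spectral estimator zero-pads ×8 and refines the in-band peak with
3-point parabolic interpolation to reach sub-bpm granularity, and reports
a missing value when the in-band peak does not exceed 3× the median
in-band magnitude (no detectable breathing). The zero-crossing estimator
counts Schmitt-trigger transitions at ±0.1 RMS hysteresis (guards against
noise chatter) and converts `crossings/2` per duration to bpm; it is
inherently quantized to 1 bpm per 30 s window (integer counts). Windows
are consecutive and non-overlapping by default (`hop_s` enables overlap).

## Agreement statistics

Differences `d = device − reference`: bias = mean, SD with the n−1
denominator, limits of agreement bias ± 1.96 SD, percentage of |d| within
the ±2 bpm clinical limit, and the least-squares slope of `d` on the pair
means as the proportional-bias trend. ICC(2,1) is computed from the
two-way ANOVA mean squares

    ICC = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE)),

the absolute-agreement single-measures form — chosen because the question
is interchangeability of device and reference, which must penalize a
systematic offset — with the standard F-based 95 % CI (verified exactly
against an independent implementation). MAE is averaged within subject
first, then across subjects unweighted, so a heavily sampled subject does
not dominate. Repeated measures within subject are not corrected for in
the Bland–Altman SD; all pairs pool.

The paired-measurement generator draws reference rates from a normal law
truncated to [6, 30] bpm (mean 18, SD 4 — a plausible acutely-ill adult
case mix) and applies `device = reference + bias + slope·(reference −
center) + noise`; a negative slope reproduces the over-reading at low
rates and under-reading at high rates characteristic of radar-derived RR.

## Numerical and testing notes

- Benchmarks use a 13-point rate grid (6–30 bpm, step 2) with three
  windows per rate; both estimators stay within ±1 bpm of truth on all
  windows at the default noise level.
- The noise-degradation ladder reports *spectral*-estimate RMSE pooled
  over seeds {1, 2, 3} at noise SD {0.02, 0.2, 0.8}: the zero-crossing
  estimator's 1 bpm quantization gives it a phase-dependent error floor
  that masks small degradations, so it is excluded from the ladder.
- Parameter-recovery checks at n = 2000 pairs compare the limits of
  agreement at 5 % relative tolerance; the recovered bias is compared at
  5 % of the generating SD of differences, because the sampling SE of a
  near-zero mean (sd/√n ≈ 0.12 bpm) exceeds any small relative band
  around it.
- The LoA midpoint equals the bias by construction; numerically the
  identity holds to ~1 ulp and is asserted at 1e−12.
- Degenerate inputs (all-zero windows, rank-deficient ICA inputs,
  zero-variance signals, groups of one subject) are flagged or reported
  missing, never silently imputed; a failed window never aborts the
  recording.

## Known limitations

- Single-target scenes only; no data association for multiple people.
- 2D (plan-view) geometry; height is ignored.
- The ICC of the synthetic agreement study depends on the generated
  case-mix variance, so it is a property of the generator settings, not a
  reproduction of any clinical value.
- Recordings read from disk tolerate radar-to-radar timestamp skew up to
  half a scan interval (the container's stored tolerance); larger
  desynchronization is rejected at read time rather than resampled.
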