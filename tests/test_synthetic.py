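"""Simulator contracts: displacement model, radargram rendering, pairs."""

import numpy as np
import pandas as pd
import pytest

from radarbreath import (
    BreathingProfile,
    DeviceErrorLaw,
    RoomScenario,
    generate_paired_measurements,
    simulate_displacement,
    simulate_radargram,
    simulate_recording,
)
from radarbreath.synthetic import DEFAULT_BIN_SPACING_M

from .conftest import make_scenario


class TestSimulateDisplacement:
    def test_sinusoid_values_at_quarter_period(self):
        bp = BreathingProfile.constant(15.0, amplitude_m=0.005)  # 0.25 Hz
        d = simulate_displacement(bp, np.array([0.0, 1.0]))
        assert d[0] == pytest.approx(0.0, abs=1e-12)
        assert d[1] == pytest.approx(0.005, abs=1e-9)

    def test_bounded_by_amplitude(self):
        bp = BreathingProfile(rate_trace=[(0.0, 10.0), (30.0, 25.0)], amplitude_m=0.004)
        d = simulate_displacement(bp, np.linspace(0, 60, 6000))
        assert np.max(np.abs(d)) <= 0.004 + 1e-12

    def test_piecewise_rate_crossing_count_matches_phase_integral(self):
        """Zero crossings over 60 s agree with a fine-grid phase-integral oracle."""
        bp = BreathingProfile(rate_trace=[(0.0, 12.0), (60.0, 20.0)], amplitude_m=0.005)
        # independent oracle: integrate f(t) on a 1 kHz grid, count sign
        # changes of sin(phase) directly
        t_fine = np.arange(0, 60.0, 0.001)
        f = np.interp(t_fine, [0.0, 60.0], [12.0, 20.0]) / 60.0
        phase = 2 * np.pi * np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) / 2 * 0.001)])
        oracle = np.count_nonzero(np.diff(np.sign(np.sin(phase))) != 0)
        d = simulate_displacement(bp, t_fine)
        crossings = np.count_nonzero(np.diff(np.sign(d)) != 0)
        assert abs(crossings - oracle) <= 1

    def test_nonincreasing_times_rejected(self):
        bp = BreathingProfile.constant(15.0)
        with pytest.raises(ValueError, match="increasing"):
            simulate_displacement(bp, np.array([0.0, 1.0, 1.0]))

    def test_spectrum_peaks_at_commanded_rate(self):
        """Displacement power spectrum peaks at the commanded rate within one bin."""
        rate_bpm = 18.0
        bp = BreathingProfile.constant(rate_bpm)
        fs, dur = 10.0, 120.0
        t = np.arange(0, dur, 1 / fs)
        d = simulate_displacement(bp, t)
        spec = np.abs(np.fft.rfft(d - d.mean()))
        freqs = np.fft.rfftfreq(t.size, 1 / fs)
        assert freqs[np.argmax(spec)] == pytest.approx(rate_bpm / 60.0, abs=freqs[1])


class TestSimulateRadargram:
    def test_static_scene_all_scans_identical(self):
        scn = make_scenario(noise_sd=0.0, amplitude_m=1e-12)
        rg = simulate_radargram(scn, 0, scan_rate_hz=10.0, n_scans=20, seed=0)
        assert np.allclose(rg.scans, rg.scans[0])

    def test_determinism_same_seed(self):
        scn = make_scenario(noise_sd=0.1)
        a = simulate_radargram(scn, 1, scan_rate_hz=10.0, n_scans=50, seed=42)
        b = simulate_radargram(scn, 1, scan_rate_hz=10.0, n_scans=50, seed=42)
        assert np.array_equal(a.scans, b.scans)

    def test_target_centroid_oscillates_with_breathing(self):
        """Centroid-tracking oracle: 5 mm motion over 9 mm bins = +-0.56 bins."""
        scn = make_scenario(noise_sd=0.0, clutter=[], amplitude_m=0.005)
        rg = simulate_radargram(scn, 0, scan_rate_hz=10.0, n_scans=600, seed=0)
        bins = np.arange(rg.n_bins)
        centroid = (rg.scans * bins).sum(axis=1) / rg.scans.sum(axis=1)
        half_swing = (centroid.max() - centroid.min()) / 2
        assert half_swing == pytest.approx(0.005 / DEFAULT_BIN_SPACING_M, rel=0.05)

    def test_argmax_bin_matches_true_range(self):
        scn = make_scenario(noise_sd=0.0, clutter=[], amplitude_m=1e-6)
        for idx in range(3):
            rg = simulate_radargram(scn, idx, scan_rate_hz=10.0, n_scans=5, seed=0)
            true_range = np.linalg.norm(
                np.array([1.2, 1.5]) - scn.radar_positions_m[idx]
            )
            assert abs(np.argmax(rg.scans[0]) - round(true_range / rg.bin_spacing_m)) <= 1

    def test_out_of_range_subject_rejected(self):
        scn = make_scenario(subject=(40.0, 40.0), clutter=[])
        with pytest.raises(ValueError, match="range"):
            simulate_radargram(scn, 0, scan_rate_hz=10.0, n_scans=5, seed=0)


class TestSimulateRecording:
    def test_three_synchronized_radargrams(self, clean_recording):
        shapes = {rg.scans.shape for rg in clean_recording.radargrams}
        assert len(shapes) == 1
        t0 = clean_recording.radargrams[0].timestamps_s
        for rg in clean_recording.radargrams[1:]:
            assert np.array_equal(rg.timestamps_s, t0)

    def test_nearer_radar_sees_lower_bin(self):
        scn = make_scenario(subject=(0.5, 0.5), noise_sd=0.0, clutter=[])
        rec = simulate_recording(scn, scan_rate_hz=10.0, n_scans=5, seed=0)
        bin0 = np.argmax(rec.radargrams[0].scans[0])
        bin1 = np.argmax(rec.radargrams[1].scans[0])
        assert bin0 < bin1  # radar 0 at origin is nearer

    def test_collinear_radars_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            RoomScenario.stationary(
                (1.0, 1.0),
                BreathingProfile.constant(12.0),
                radar_positions_m=((0.0, 0.0), (1.0, 0.0), (2.0, 0.0)),
            )

    def test_recording_determinism(self):
        scn = make_scenario(noise_sd=0.05)
        a = simulate_recording(scn, scan_rate_hz=10.0, n_scans=30, seed=3)
        b = simulate_recording(scn, scan_rate_hz=10.0, n_scans=30, seed=3)
        for ra, rb in zip(a.radargrams, b.radargrams):
            assert np.array_equal(ra.scans, rb.scans)


class TestGeneratePairedMeasurements:
    def test_zero_error_law_gives_perfect_agreement(self):
        pairs = generate_paired_measurements(5, 4, device_error=DeviceErrorLaw(), seed=0)
        d = pairs.rr_device - pairs.rr_reference
        assert np.allclose(d, 0.0)
        assert set(pairs.columns) >= {"subject_id", "time_s", "rr_device", "rr_reference", "sex", "dx_group"}

    def test_rate_dependent_slope_recovered_by_least_squares(self):
        law = DeviceErrorLaw(bias_bpm=0.0, sd_bpm=0.0, slope=-0.4, center_bpm=18.0)
        pairs = generate_paired_measurements(50, 8, device_error=law, seed=5)
        d = (pairs.rr_device - pairs.rr_reference).to_numpy()
        ref = pairs.rr_reference.to_numpy()
        slope = np.polyfit(ref - 18.0, d, 1)[0]
        assert slope == pytest.approx(-0.4, abs=1e-9)

    def test_determinism_and_positive_rates(self):
        law = DeviceErrorLaw(bias_bpm=-0.76, sd_bpm=5.3)
        a = generate_paired_measurements(20, 8, device_error=law, seed=11)
        b = generate_paired_measurements(20, 8, device_error=law, seed=11)
        pd.testing.assert_frame_equal(a, b)
        assert (a.rr_device > 0).all() and (a.rr_reference > 0).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_paired_measurements(0, 4)
        with pytest.raises(ValueError):
            DeviceErrorLaw(bias_bpm=float("nan"))
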