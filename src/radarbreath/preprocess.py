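"""Static-clutter removal and slow-time breathing-band filtering.

Clutter (walls, stretchers, furniture) is static, so it is removed by
background subtraction: the per-bin mean of the first scans recorded
with no participant present is subtracted from every scan.  Slow-time
content is then restricted to the normal breathing band, 6-30 breaths
per minute = 0.1-0.5 Hz, by an equiripple FIR band-pass whose stopband
includes DC.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml
from scipy import signal

from .types import Radargram

__all__ = [
    "FilterSpec",
    "remove_clutter",
    "design_breathing_filter",
    "apply_slow_time_filter",
]


@dataclass(frozen=True)
class FilterSpec:
    """Designed equiripple FIR band-pass with its taps and provenance."""

    low_cut_hz: float
    high_cut_hz: float
    transition_hz: float
    n_taps: int
    scan_rate_hz: float
    taps: np.ndarray
    kind: str = "bandpass_fir"
    design: str = "equiripple"

    def frequency_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Magnitude response at the given frequencies (single pass)."""
        w, h = signal.freqz(self.taps, worN=np.asarray(freqs_hz, dtype=float), fs=self.scan_rate_hz)
        return np.abs(h)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["taps"] = [float(x) for x in self.taps]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "FilterSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["taps"] = np.asarray(d["taps"], dtype=float)
        return cls(**d)


def remove_clutter(
    radargram: Radargram,
    n_background_scans: int = 100,
    window_s: float = 30.0,
    *,
    recompute_per_window: bool = False,
) -> Radargram:
    """Subtract the static background from every scan.

    The background is the per-bin mean of the first ``n_background_scans``
    scans (taken with no participant in front of the radar).  It is
    subtracted window-by-window of ``window_s``; by default the same
    global background is reused for every window.  With
    ``recompute_per_window`` each window instead subtracts its own
    per-bin mean (a per-window background re-estimate).

    Shape and metadata are preserved.
    """
    if radargram.n_scans < n_background_scans:
        raise ValueError(
            f"insufficient background: {radargram.n_scans} scans < "
            f"{n_background_scans} background scans"
        )
    scans = radargram.scans
    window_len = max(int(round(window_s * radargram.scan_rate_hz)), 1)
    out = np.empty_like(scans)
    background = scans[:n_background_scans].mean(axis=0)
    for start in range(0, scans.shape[0], window_len):
        block = scans[start : start + window_len]
        bg = block.mean(axis=0) if recompute_per_window else background
        out[start : start + block.shape[0]] = block - bg
    return radargram.replace_scans(out)


def design_breathing_filter(
    scan_rate_hz: float,
    low_bpm: float = 6.0,
    high_bpm: float = 30.0,
    transition_hz: float = 0.05,
    stopband_db: float = 40.0,
    n_taps: int | None = None,
) -> FilterSpec:
    """Equiripple FIR band-pass over the breathing band.

    Passband ``[low_bpm, high_bpm] / 60`` Hz (defaults to [0.1, 0.5] Hz);
    both stopbands, including DC, are attenuated by ``stopband_db``.
    The tap count defaults to the Kaiser estimate for the requested
    transition width, forced odd (type-I linear phase).
    """
    low_hz, high_hz = low_bpm / 60.0, high_bpm / 60.0
    nyq = scan_rate_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError("need 0 < low cut < high cut < scan_rate/2")
    if low_hz - transition_hz <= 0 or high_hz + transition_hz >= nyq:
        raise ValueError("transition band does not fit between DC and Nyquist")
    if n_taps is None:
        n_taps, _ = signal.kaiserord(stopband_db, transition_hz / nyq)
    if n_taps % 2 == 0:
        n_taps += 1
    bands = [0.0, low_hz - transition_hz, low_hz, high_hz, high_hz + transition_hz, nyq]
    try:
        taps = signal.remez(n_taps, bands, [0.0, 1.0, 0.0], fs=scan_rate_hz, maxiter=50)
    except Exception as exc:  # pragma: no cover - scipy raises on non-convergence
        raise RuntimeError(f"equiripple design failed for {bands} at {n_taps} taps") from exc
    if not np.all(np.isfinite(taps)):
        raise RuntimeError("equiripple design failed: non-finite taps")
    return FilterSpec(
        low_cut_hz=low_hz,
        high_cut_hz=high_hz,
        transition_hz=transition_hz,
        n_taps=int(n_taps),
        scan_rate_hz=float(scan_rate_hz),
        taps=taps,
    )


def _zero_phase_apply(x: np.ndarray, taps: np.ndarray, axis: int = 0) -> np.ndarray:
    """Forward-backward FIR filtering along ``axis`` (zero phase).

    Equivalent to convolving with the filter's squared zero-phase
    response; implemented by FFT convolution with zero-padded edges so
    window timing is preserved exactly.
    """
    h2 = np.convolve(taps, taps[::-1])  # combined forward+backward impulse response
    x = np.moveaxis(np.asarray(x, dtype=float), axis, 0)
    n = x.shape[0]
    pad = (len(h2) - 1) // 2
    padded = np.concatenate([np.zeros((pad,) + x.shape[1:]), x, np.zeros((pad,) + x.shape[1:])])
    out = signal.fftconvolve(padded, h2.reshape((-1,) + (1,) * (x.ndim - 1)), mode="valid", axes=0)
    assert out.shape[0] == n
    return np.moveaxis(out, 0, axis)


def apply_slow_time_filter(radargram: Radargram, spec: FilterSpec) -> Radargram:
    """Filter every range bin's slow-time series with the band-pass.

    Applied forward-backward (zero phase) so the breathing waveform is
    not delayed relative to the scan timestamps.  Shape preserved.
    """
    if abs(spec.scan_rate_hz - radargram.scan_rate_hz) > 1e-9:
        raise ValueError(
            f"filter designed for {spec.scan_rate_hz} Hz cannot be applied "
            f"to a {radargram.scan_rate_hz} Hz recording"
        )
    return radargram.replace_scans(_zero_phase_apply(radargram.scans, spec.taps, axis=0))


def apply_slow_time_filter_1d(values: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase band-pass of a single slow-time series."""
    return _zero_phase_apply(np.asarray(values, dtype=float), spec.taps, axis=0)
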