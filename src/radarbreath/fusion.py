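"""Focus-window extraction, sum-align fusion, and ICA component selection.

Each radar's 50-bin window around the subject's location bin is
collapsed to one slow-time series by *sum-align*: the highest-RMS bin
series is the reference, every other series is shifted by the lag that
best cross-correlates it with the reference, and the aligned series are
summed.  The three radars' fused signals are then unmixed by FastICA and
the component with the strongest in-band spectral peak is kept as the
breathing signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from sklearn.decomposition import FastICA

from .types import Radargram

__all__ = ["FocusWindow", "FusedSignal", "extract_focus_window", "sum_align", "ica_select"]

#: Breathing analysis band in Hz (6-30 breaths per minute).
BREATHING_BAND_HZ = (0.1, 0.5)


@dataclass
class FocusWindow:
    """50 slow-time series around the subject's location bin."""

    series: np.ndarray  # (50, n_samples)
    start_time_s: float
    center_bin: int
    radar_index: int
    window_s: float = 30.0
    first_bin: int = 0  # absolute bin index of series[0]
    clamped: bool = False

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[0] != 50:
            raise ValueError("focus window must hold exactly 50 series")


@dataclass
class FusedSignal:
    """A single slow-time breathing candidate signal."""

    values: np.ndarray
    scan_rate_hz: float
    start_time_s: float = 0.0
    source: str = "sum_aligned"
    radar_index: int | None = None
    component_index: int | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fused signal must be finite")


def extract_focus_window(
    radargram: Radargram,
    center_bin: int,
    start_time_s: float,
    n_bins: int = 50,
    window_s: float = 30.0,
) -> FocusWindow:
    """Cut the (window_s x 50-bin) patch around the location bin.

    Bins span ``[center - 25, center + 24]``; windows that would cross
    the edge of the scan are clamped to the valid bin range and flagged.
    """
    start_idx = int(round((start_time_s - radargram.timestamps_s[0]) * radargram.scan_rate_hz))
    n_samples = int(round(window_s * radargram.scan_rate_hz))
    if start_idx < 0 or start_idx + n_samples > radargram.n_scans:
        raise ValueError("requested window lies outside the recording")
    half = n_bins // 2
    first = center_bin - half
    clamped = False
    if first < 0:
        first, clamped = 0, True
    if first + n_bins > radargram.n_bins:
        first, clamped = radargram.n_bins - n_bins, True
    if first < 0:
        raise ValueError("radargram has fewer bins than the focus window")
    patch = radargram.scans[start_idx : start_idx + n_samples, first : first + n_bins]
    return FocusWindow(
        series=patch.T,
        start_time_s=start_time_s,
        center_bin=center_bin,
        radar_index=-1,
        window_s=window_s,
        first_bin=first,
        clamped=clamped,
    )


def _best_lag(reference: np.ndarray, series: np.ndarray, max_lag: int) -> int:
    """Integer shift of ``series`` (in samples) maximizing correlation.

    A returned lag ``l`` means ``aligned[n] = series[n + l]`` matches the
    reference best; ties break toward the smallest |lag|, then negative.
    """
    lags = np.arange(-max_lag, max_lag + 1)
    scores = np.empty(lags.size)
    n = reference.size
    for j, l in enumerate(lags):
        if l >= 0:
            scores[j] = float(reference[: n - l] @ series[l:])
        else:
            scores[j] = float(reference[-l:] @ series[: n + l])
    order = np.lexsort((lags, np.abs(lags), -scores))
    return int(lags[order[0]])


def sum_align(window: FocusWindow, max_lag_s: float = 2.0, scan_rate_hz: float | None = None) -> FusedSignal:
    """Collapse the 50 bin series to one signal by align-and-sum.

    The series with the highest RMS energy is the reference; each of the
    other 49 is shifted by the lag (|lag| <= ``max_lag_s``) that maximizes
    its cross-correlation with the reference, overhanging samples are
    zero-padded, and all 50 are summed sample-wise.
    """
    s = window.series
    rms = np.sqrt(np.mean(s**2, axis=1))
    if np.all(rms == 0):
        raise ValueError("degenerate focus window: all series are zero")
    if scan_rate_hz is None:
        scan_rate_hz = s.shape[1] / window.window_s
    ref_idx = int(np.argmax(rms))
    reference = s[ref_idx]
    max_lag = int(round(max_lag_s * scan_rate_hz))
    n = reference.size
    total = np.zeros(n)
    for i in range(s.shape[0]):
        if i == ref_idx:
            total += reference
            continue
        l = _best_lag(reference, s[i], max_lag)
        aligned = np.zeros(n)
        if l >= 0:
            aligned[: n - l] = s[i][l:]
        else:
            aligned[-l:] = s[i][: n + l]
        total += aligned
    return FusedSignal(
        values=total,
        scan_rate_hz=scan_rate_hz,
        start_time_s=window.start_time_s,
        source="sum_aligned",
        radar_index=window.radar_index,
    )


def _peak_in_band(values: np.ndarray, scan_rate_hz: float, pad_factor: int = 8):
    """(peak magnitude, peak frequency) of the spectrum inside the band."""
    x = values - values.mean()
    nfft = pad_factor * x.size
    spectrum = np.abs(sp_fft.rfft(x, n=nfft))
    freqs = sp_fft.rfftfreq(nfft, d=1.0 / scan_rate_hz)
    mask = (freqs >= BREATHING_BAND_HZ[0]) & (freqs <= BREATHING_BAND_HZ[1])
    if not np.any(mask):
        return 0.0, np.nan
    mags, fs = spectrum[mask], freqs[mask]
    best = int(np.argmax(mags))  # argmax returns the lowest index on ties
    return float(mags[best]), float(fs[best])


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def ica_select(signals: list[FusedSignal], seed: int = 0) -> FusedSignal:
    """Unmix the three radars' signals and keep the breathing component.

    Signals are standardized, FastICA estimates 3 independent
    components, each component's zero-padded magnitude spectrum is
    evaluated inside 0.1-0.5 Hz, and the component with the largest
    single in-band spectral peak is returned (ties toward the lower
    frequency).  The component is normalized to unit variance with its
    spectral-peak phase made positive.  If the inputs are mutually
    (anti)correlated to near rank one, ICA is degenerate; the
    standardized common signal is returned with a ``rank_deficient``
    flag.
    """
    if len(signals) != 3:
        raise ValueError("exactly 3 fused signals required")
    lengths = {s.values.size for s in signals}
    if len(lengths) != 1:
        raise ValueError("fused signals must have equal length")
    scan_rate = signals[0].scan_rate_hz
    x = np.stack([_standardize(s.values) for s in signals], axis=1)  # (n, 3)
    corr = np.corrcoef(x.T)
    if np.all(np.abs(corr) > 1.0 - 1e-10):
        return FusedSignal(
            values=x[:, 0],
            scan_rate_hz=scan_rate,
            start_time_s=signals[0].start_time_s,
            source="ica_selected",
            component_index=0,
            flags=["rank_deficient"],
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ica = FastICA(n_components=3, random_state=int(seed), whiten="unit-variance", max_iter=500)
        components = ica.fit_transform(x)  # (n, 3)
    best_idx, best_peak, best_freq = 0, -np.inf, np.inf
    for i in range(3):
        peak, freq = _peak_in_band(components[:, i], scan_rate)
        if peak > best_peak or (peak == best_peak and freq < best_freq):
            best_idx, best_peak, best_freq = i, peak, freq
    comp = _standardize(components[:, best_idx])
    # resolve ICA's sign ambiguity: make the dominant in-band oscillation
    # start with positive correlation against its own peak-frequency cosine
    t = np.arange(comp.size) / scan_rate
    if np.isfinite(best_freq) and comp @ np.cos(2 * np.pi * best_freq * t) < 0:
        comp = -comp
    return FusedSignal(
        values=comp,
        scan_rate_hz=scan_rate,
        start_time_s=signals[0].start_time_s,
        source="ica_selected",
        component_index=best_idx,
    )
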