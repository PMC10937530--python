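"""First-order band-power time series from sliding-window Welch spectra.

EEG power is tracked over time by running Welch's PSD estimate (1-s
non-overlapping Hann segments) on 20-s windows advanced in 1-s steps. Within
each window, alpha (8–13 Hz) and theta (4–7 Hz) power are normalized by total
4–30 Hz power, giving a unitless fraction per window and channel — the
"first-order time series" sampled at the window-shift rate (1 Hz).

Band power is the trapezoidal integral of the PSD between the band edges
(values at the edges linearly interpolated), so a spectrally flat signal
yields a fraction equal to the bandwidth ratio, independent of the frequency
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import rfft, rfftfreq

from cogload.io import MultiChannelRecording


@dataclass(frozen=True)
class BandDef:
    """A named frequency band [low_hz, high_hz]."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not self.low_hz < self.high_hz:
            raise ValueError("band edges must satisfy low < high")


ALPHA = BandDef("alpha", 8.0, 13.0)
THETA = BandDef("theta", 4.0, 7.0)
TOTAL = BandDef("total", 4.0, 30.0)


@dataclass
class PowerTimeSeries:
    """Per-window, per-channel power values at the window-shift rate.

    ``values`` has shape (n_windows, n_channels); each window's value is
    stamped at the *window start*: sample k is at ``t0_s + k * dt_s``.
    """

    values: np.ndarray
    band: BandDef
    dt_s: float
    t0_s: float
    channel_labels: tuple

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        if self.values.shape[1] != len(self.channel_labels):
            raise ValueError("label count does not match channel count")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_windows) * self.dt_s


def _interp_at(freqs: np.ndarray, values: np.ndarray, f: float) -> np.ndarray:
    """Linear interpolation of ``values`` (frequency on the last axis) at f."""
    j = int(np.searchsorted(freqs, f))
    if freqs[j] == f:
        return values[..., j]
    w = (f - freqs[j - 1]) / (freqs[j] - freqs[j - 1])
    return (1 - w) * values[..., j - 1] + w * values[..., j]


def integrate_band(freqs, values, low_hz, high_hz, axis=-1):
    """Trapezoidal integral of a PSD between band edges.

    ``values`` may have any shape with frequency along ``axis``; the edges
    are linearly interpolated so the result is exact for piecewise-linear
    spectra and resolution-robust in general.
    """
    freqs = np.asarray(freqs, dtype=float)
    values = np.moveaxis(np.asarray(values, dtype=float), axis, -1)
    if low_hz < freqs[0] or high_hz > freqs[-1]:
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz outside spectrum support "
            f"[{freqs[0]}, {freqs[-1]}] Hz"
        )
    inner = (freqs > low_hz) & (freqs < high_hz)
    grid = np.concatenate([[low_hz], freqs[inner], [high_hz]])
    v_lo = _interp_at(freqs, values, low_hz)[..., None]
    v_hi = _interp_at(freqs, values, high_hz)[..., None]
    vals = np.concatenate([v_lo, values[..., inner], v_hi], axis=-1)
    return np.trapezoid(vals, grid, axis=-1)


def sliding_psd(
    recording: MultiChannelRecording,
    window_s: float = 20.0,
    shift_s: float = 1.0,
    segment_s: float = 1.0,
    taper: str = "hann",
):
    """Welch PSD on sliding windows of a recording.

    Each window of ``window_s`` seconds, advanced by ``shift_s``, is split
    into non-overlapping ``segment_s`` segments whose tapered periodograms are
    averaged (Welch). The frequency resolution is 1/segment_s.

    Returns
    -------
    freqs : ndarray, shape (n_freqs,)
    psd : ndarray, shape (n_windows, n_freqs, n_channels)
        One-sided spectral density (unit²/Hz).
    t0_s : float
        Timestamp of the first window's start.

    Notes
    -----
    Window count = floor((duration − window_s)/shift_s) + 1. When the shift
    equals the segment length (the default 1 s / 1 s), segment periodograms
    are computed once on the common grid and rolling-averaged, which is
    algebraically identical to Welch run per window.
    """
    fs = recording.fs
    x = recording.samples
    nper = int(round(fs * segment_s))
    if abs(nper - fs * segment_s) > 1e-9:
        raise ValueError("fs * segment_s must be an integer sample count")
    n_window = int(round(window_s * fs))
    n_shift = int(round(shift_s * fs))
    if x.shape[0] < n_window:
        raise ValueError(
            f"recording of {recording.duration_s:.1f} s shorter than the "
            f"{window_s} s analysis window"
        )
    n_windows = (x.shape[0] - n_window) // n_shift + 1
    nseg = n_window // nper
    if nseg * nper != n_window:
        raise ValueError("window_s must be an integer multiple of segment_s")

    win = sps.get_window(taper, nper)
    scale = 1.0 / (fs * np.sum(win**2))
    freqs = rfftfreq(nper, d=1.0 / fs)

    def _segment_psd(segs):
        # segs: (n_segments, nper, n_channels); per-segment mean removed,
        # one-sided density scaling as in Welch
        segs = segs - segs.mean(axis=1, keepdims=True)
        spec = rfft(segs * win[None, :, None], axis=1)
        p = (spec.real**2 + spec.imag**2) * scale
        p[:, 1:, :] *= 2.0
        if nper % 2 == 0:
            p[:, -1, :] /= 2.0
        return p

    if n_shift == nper:
        n_segs_total = n_windows - 1 + nseg
        segs = x[: n_segs_total * nper].reshape(n_segs_total, nper, x.shape[1])
        pseg = _segment_psd(segs)
        csum = np.concatenate([np.zeros((1,) + pseg.shape[1:]), np.cumsum(pseg, axis=0)])
        psd = (csum[nseg:] - csum[:-nseg]) / nseg
        psd = psd[:n_windows]
    else:
        psd = np.empty((n_windows, freqs.size, x.shape[1]))
        for k in range(n_windows):
            seg_block = x[k * n_shift : k * n_shift + n_window]
            segs = seg_block.reshape(nseg, nper, x.shape[1])
            psd[k] = _segment_psd(segs).mean(axis=0)
    return freqs, psd, recording.start_time


def band_fraction(freqs, spectrum, band: BandDef, total: BandDef = TOTAL):
    """Band power as a fraction of total-band power for one spectrum.

    Returns NaN where the total-band power is zero (nothing to normalize by);
    NaN propagates rather than masquerading as zero power.
    """
    num = integrate_band(freqs, spectrum, band.low_hz, band.high_hz)
    den = integrate_band(freqs, spectrum, total.low_hz, total.high_hz)
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def first_order_series(
    recording: MultiChannelRecording,
    band: BandDef,
    total: BandDef = TOTAL,
    window_s: float = 20.0,
    shift_s: float = 1.0,
    segment_s: float = 1.0,
    taper: str = "hann",
) -> PowerTimeSeries:
    """Normalized band-power fraction per sliding window and channel."""
    freqs, psd, t0 = sliding_psd(recording, window_s, shift_s, segment_s, taper)
    num = integrate_band(freqs, psd, band.low_hz, band.high_hz, axis=1)
    den = integrate_band(freqs, psd, total.low_hz, total.high_hz, axis=1)
    frac = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return PowerTimeSeries(frac, band, shift_s, t0, recording.channel_labels)


def power_series_frame(series: PowerTimeSeries):
    """Long-format table of a power series: time_s, channel, band, fraction."""
    import pandas as pd

    times = np.repeat(series.times, series.n_channels)
    channels = np.tile(series.channel_labels, series.n_windows)
    return pd.DataFrame({
        "time_s": times,
        "channel": channels,
        "band": series.band.name,
        "fraction": series.values.ravel(),
    })
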