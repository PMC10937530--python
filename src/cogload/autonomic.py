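"""Autonomic indices: heart-rate variability from PPG and SCR counts from EDA.

Pulse peaks are detected on a band-limited (0.5–8 Hz) photoplethysmogram and
validated against an autocorrelation estimate of the beat period: a candidate
peak is rejected when its interval from the last accepted beat falls outside
0.5–1.5 times the running period estimate. HRV is summarized as RMSSD (root
mean square of successive differences of the N-N intervals, ms), the standard
short-term parasympathetic index.

Skin-conductance responses are counted with a trough-to-peak detector: a
deflection whose rise completes within 1–5 s and whose amplitude exceeds the
detection threshold (default 0.05 μS) counts as one SCR; the summary index is
events per minute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from cogload.io import MultiChannelRecording

__all__ = ["BeatSeries", "SCREvents", "detect_pulses", "rmssd", "detect_scr", "screen_nn"]


@dataclass
class BeatSeries:
    """Detected pulse-peak times and the screened N-N intervals."""

    beat_times_s: np.ndarray
    nn_intervals_ms: np.ndarray

    def __post_init__(self):
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.nn_intervals_ms = np.asarray(self.nn_intervals_ms, dtype=float)
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")


@dataclass
class SCREvents:
    """Detected skin-conductance responses over an analyzed duration."""

    onset_times_s: np.ndarray
    amplitudes_uS: np.ndarray
    duration_s: float

    def __post_init__(self):
        self.onset_times_s = np.asarray(self.onset_times_s, dtype=float)
        self.amplitudes_uS = np.asarray(self.amplitudes_uS, dtype=float)

    @property
    def n_events(self) -> int:
        return len(self.onset_times_s)

    @property
    def rate_per_min(self) -> float:
        return self.n_events / (self.duration_s / 60.0)


def screen_nn(intervals_ms, lo_ms=300.0, hi_ms=2000.0, max_rel_dev=0.25, med_win=11):
    """Artifact screening of inter-beat intervals.

    Keeps intervals inside [lo_ms, hi_ms] that deviate less than
    ``max_rel_dev`` from a running median (window ``med_win`` beats).
    """
    x = np.asarray(intervals_ms, dtype=float)
    if x.size == 0:
        return x
    med = sps.medfilt(x, kernel_size=min(med_win, x.size | 1))
    keep = (x >= lo_ms) & (x <= hi_ms) & (np.abs(x - med) <= max_rel_dev * med)
    return x[keep]


def detect_pulses(
    ppg: MultiChannelRecording,
    band_hz=(0.5, 8.0),
    acf_window_s: float = 10.0,
    gate=(0.5, 1.5),
    min_periodicity: float = 0.2,
    screen: bool = True,
) -> BeatSeries:
    """Detect pulse peaks in a single-channel PPG recording.

    Raises ValueError when no cardiac periodicity is detectable (flat or
    noise-only input). Beat *count* is invariant to amplitude scaling: the
    detection geometry only uses relative peak structure.
    """
    if ppg.n_channels != 1:
        raise ValueError("PPG must be single-channel")
    x = ppg.samples[:, 0]
    fs = ppg.fs
    if ppg.duration_s < 30.0:
        raise ValueError("need at least 30 s of PPG")
    if np.std(x) == 0:
        raise ValueError("no periodicity detectable in a constant signal")

    sos = sps.butter(3, band_hz, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)

    # beat-period prior from the autocorrelation of the band-limited pulse
    nacf = int(round(acf_window_s * fs))
    seg = y[: min(len(y), 6 * nacf)]
    seg = seg - seg.mean()
    acf = sps.fftconvolve(seg, seg[::-1], mode="full")[len(seg) - 1 :]
    acf /= acf[0]
    lo, hi = int(0.3 * fs), int(2.0 * fs)  # plausible IBI range 300–2000 ms
    lag = lo + int(np.argmax(acf[lo:hi]))
    if acf[lag] < min_periodicity:
        raise ValueError("no periodicity detectable in the PPG signal")
    period = lag / fs

    peaks, _ = sps.find_peaks(
        y, distance=max(1, int(gate[0] * period * fs)), height=0.3 * np.std(y)
    )
    if len(peaks) < 2:
        raise ValueError("too few pulse peaks detected")

    # gate candidate peaks against the running period estimate
    accepted = [peaks[0]]
    run_period = period
    for p in peaks[1:]:
        interval = (p - accepted[-1]) / fs
        if interval < gate[0] * run_period:
            continue
        if interval > gate[1] * run_period:
            # lost beats: re-anchor without folding the gap into the estimate
            accepted.append(p)
            continue
        accepted.append(p)
        run_period = 0.8 * run_period + 0.2 * interval
    beat_times = np.asarray(accepted) / fs + ppg.start_time
    nn = np.diff(beat_times) * 1000.0
    if screen:
        nn = screen_nn(nn)
    return BeatSeries(beat_times, nn)


def rmssd(nn_intervals_ms) -> float:
    """Root mean square of successive differences of N-N intervals (ms)."""
    nn = np.asarray(nn_intervals_ms, dtype=float)
    if nn.size < 2:
        raise ValueError("RMSSD needs at least 2 intervals")
    d = np.diff(nn)
    return float(np.sqrt(np.mean(d**2)))


def detect_scr(
    eda: MultiChannelRecording,
    min_amplitude_uS: float = 0.05,
    rise_window_s=(1.0, 5.0),
    analysis_fs: float = 32.0,
) -> SCREvents:
    """Count skin-conductance responses with a trough-to-peak rule.

    The conductance trace is low-passed and decimated to ``analysis_fs``;
    each local maximum is paired with the preceding local minimum, and the
    deflection counts as an SCR when the rise time lies within
    ``rise_window_s`` and the amplitude is at least ``min_amplitude_uS``.
    """
    if eda.n_channels != 1:
        raise ValueError("EDA must be single-channel")
    if eda.duration_s < 60.0:
        raise ValueError("need at least 60 s of EDA for a stable SCR rate")
    x = eda.samples[:, 0]
    fs = eda.fs
    dec = max(1, int(round(fs / analysis_fs)))
    if dec > 1:
        sos = sps.butter(4, min(analysis_fs / 2 * 0.8, fs / 2 * 0.9), fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)[::dec]
        fs = fs / dec
    # smooth residual noise over ~250 ms
    k = max(1, int(round(0.25 * fs)))
    x = np.convolve(x, np.ones(k) / k, mode="same")

    maxima, _ = sps.find_peaks(x)
    minima, _ = sps.find_peaks(-x)
    onsets, amps = [], []
    last_peak = -np.inf
    for p in maxima:
        prior = minima[minima < p]
        trough = prior[-1] if prior.size else 0
        if trough <= last_peak:
            # rising through multiple ripples toward one response apex:
            # keep only the first qualifying deflection
            continue
        rise = (p - trough) / fs
        amp = x[p] - x[trough]
        if rise_window_s[0] <= rise <= rise_window_s[1] and amp >= min_amplitude_uS:
            onsets.append(trough / fs + eda.start_time)
            amps.append(amp)
            last_peak = p
    return SCREvents(np.asarray(onsets), np.asarray(amps), eda.duration_s)


def beats_to_csv(beats: BeatSeries, path) -> None:
    """Beat-time table (beat_time_s) as CSV."""
    import pandas as pd

    pd.DataFrame({"beat_time_s": beats.beat_times_s}).to_csv(path, index=False)


def scr_to_csv(events: SCREvents, path) -> None:
    """SCR event table (onset_s, amplitude_uS) as CSV."""
    import pandas as pd

    pd.DataFrame({"onset_s": events.onset_times_s,
                  "amplitude_uS": events.amplitudes_uS}).to_csv(path, index=False)
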