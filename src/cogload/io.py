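"""Reading/writing of signal recordings and trial logs, and temporal windowing.

Signals travel as :class:`MultiChannelRecording` blocks — a uniformly sampled
``[time x channel]`` array plus sampling rate and labels. EEG is expected at
256 Hz on the six frontal channels AF3/AF4/F3/F4/F7/F8; PPG and EDA at 512 Hz.
The first 60 s of each task are conventionally discarded (measurement
instability right after task onset); :func:`trim_initial` implements that rule
with the amount exposed as a parameter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

EEG_CHANNELS = ("AF3", "AF4", "F3", "F4", "F7", "F8")
EEG_FS = 256.0
PERIPHERAL_FS = 512.0

#: channel-count expectation per modality (None = any)
_EXPECTED_CHANNELS = {"EEG": 6, "PPG": 1, "EDA": 1}
_EXPECTED_FS = {"EEG": EEG_FS, "PPG": PERIPHERAL_FS, "EDA": PERIPHERAL_FS}


@dataclass
class MultiChannelRecording:
    """Uniformly sampled multi-channel signal block.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        Signal values; μV for EEG, device units for PPG/EDA.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        One label per column.
    modality : {"EEG", "PPG", "EDA"}
    start_time : float
        Seconds relative to task onset (0 = task onset).
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple
    modality: str = "EEG"
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise ValueError("samples must be a [time x channel] array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[1]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[1]} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds relative to task onset."""
        return self.start_time + np.arange(self.n_samples) / self.fs


@dataclass
class Trial:
    """One n-back trial: stimulus digit, onset, response and outcome."""

    trial_index: int
    digit: int
    onset_s: float
    response: str  # "match"/"nonmatch", "even"/"odd", or "none"
    rt_ms: float  # NaN when no response
    correct: bool | None = None


@dataclass
class TaskRun:
    """One condition's behavioral log (canonically 200 trials at 3-s ISI)."""

    condition: str  # "zero_back" | "three_back"
    trials: list = field(default_factory=list)
    isi_s: float = 3.0

    def __post_init__(self):
        if self.condition not in ("zero_back", "three_back"):
            raise ValueError(f"unknown condition {self.condition!r}")
        onsets = np.array([t.onset_s for t in self.trials])
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("trial onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def digits(self) -> np.ndarray:
        return np.array([t.digit for t in self.trials], dtype=int)

    @property
    def rts_ms(self) -> np.ndarray:
        return np.array([t.rt_ms for t in self.trials], dtype=float)

    @property
    def responses(self) -> list:
        return [t.response for t in self.trials]


def read_recording(path, modality: str, fs_expected: float | None = None) -> MultiChannelRecording:
    """Read a recording from EDF or headered CSV.

    CSV: one column per channel with a single header row of labels; time is
    implicit from the sampling rate. EDF: channels and rate from the header
    (physical-unit scaling honored by the reader).

    Raises on a sampling-rate mismatch rather than silently resampling, and on
    a channel count that contradicts the declared modality.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    modality = modality.upper()
    if modality not in _EXPECTED_CHANNELS:
        raise ValueError(f"unknown modality {modality!r}")
    if fs_expected is None:
        fs_expected = _EXPECTED_FS[modality]

    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        fs = float(raw.info["sfreq"])
        labels = tuple(raw.ch_names)
        data = raw.get_data().T  # volts for eeg channel types
        if modality == "EEG":
            data = data * 1e6  # internal EEG unit is μV
    else:
        frame = pd.read_csv(path)
        if frame.shape[1] < 1 or any(str(c).strip() == "" for c in frame.columns):
            raise ValueError(f"unparseable CSV header in {path}")
        try:
            data = frame.to_numpy(dtype=float)
        except (TypeError, ValueError) as err:
            raise ValueError(f"non-numeric samples in {path}") from err
        fs = float(fs_expected)
        labels = tuple(str(c) for c in frame.columns)

    if abs(fs - fs_expected) > 1e-9:
        raise ValueError(
            f"{path}: sampling rate {fs} Hz does not match expected {fs_expected} Hz"
        )
    n_expected = _EXPECTED_CHANNELS[modality]
    if n_expected is not None and data.shape[1] != n_expected:
        raise ValueError(
            f"{path}: {data.shape[1]} channels, expected {n_expected} for {modality}"
        )
    return MultiChannelRecording(data, fs, labels, modality=modality)


def write_recording(recording: MultiChannelRecording, path) -> None:
    """Write a recording as headered CSV (full float precision; round-trips
    through :func:`read_recording` within 1e-9 relative tolerance)."""
    path = Path(path)
    frame = pd.DataFrame(recording.samples, columns=list(recording.channel_labels))
    frame.to_csv(path, index=False, float_format="%.12g")


def trim_initial(recording: MultiChannelRecording, drop_s: float) -> MultiChannelRecording:
    """Drop the first ``drop_s`` seconds (task-onset instability window).

    The returned recording's ``start_time`` advances by ``drop_s``; nothing
    else is altered, so ``trim_initial(x, a)`` then ``(·, b)`` equals
    ``trim_initial(x, a + b)``.
    """
    if drop_s < 0:
        raise ValueError("drop_s must be non-negative")
    n_drop = int(round(drop_s * recording.fs))
    if n_drop >= recording.n_samples:
        raise ValueError(
            f"cannot drop {drop_s} s from a {recording.duration_s:.1f} s recording"
        )
    return replace(
        recording,
        samples=recording.samples[n_drop:].copy(),
        start_time=recording.start_time + drop_s,
    )


_TRIAL_COLUMNS = ["trial_index", "digit", "onset_s", "response", "rt_ms", "correct"]


def read_trials(path, condition: str, isi_s: float = 3.0) -> TaskRun:
    """Read a trial-log CSV (columns trial_index, digit, onset_s, response,
    rt_ms, correct) into a :class:`TaskRun`."""
    frame = pd.read_csv(path)
    missing = [c for c in _TRIAL_COLUMNS[:5] if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing trial-log columns {missing}")
    trials = []
    for _, row in frame.iterrows():
        correct = None
        if "correct" in frame.columns and not pd.isna(row["correct"]):
            correct = bool(row["correct"])
        rt = float(row["rt_ms"]) if not pd.isna(row["rt_ms"]) else float("nan")
        trials.append(
            Trial(int(row["trial_index"]), int(row["digit"]), float(row["onset_s"]),
                  str(row["response"]), rt, correct)
        )
    return TaskRun(condition=condition, trials=trials, isi_s=isi_s)


def write_trials(run: TaskRun, path) -> None:
    """Write a trial log as CSV in the layout :func:`read_trials` expects."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRIAL_COLUMNS)
        for t in run.trials:
            rt = "" if np.isnan(t.rt_ms) else f"{t.rt_ms:.3f}"
            correct = "" if t.correct is None else t.correct
            writer.writerow([t.trial_index, t.digit, f"{t.onset_s:.3f}", t.response, rt, correct])
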