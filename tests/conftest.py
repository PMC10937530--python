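import numpy as np
import pytest

from cogload.bandpower import ALPHA, first_order_series
from cogload.io import EEG_CHANNELS, MultiChannelRecording
from cogload.preprocess import bandpass, remove_offset
from cogload.synthdata import synth_eeg


def make_eeg(samples_fn, duration_s=300.0, fs=256.0, n_channels=6):
    """Build a 6-channel EEG recording from a function of the time vector."""
    t = np.arange(int(duration_s * fs)) / fs
    x = np.tile(np.asarray(samples_fn(t))[:, None], (1, n_channels))
    return MultiChannelRecording(x, fs, EEG_CHANNELS[:n_channels], modality="EEG")


@pytest.fixture(scope="session")
def tone_eeg():
    """300-s pure 10 Hz unit sinusoid on all six channels."""
    return make_eeg(lambda t: np.sin(2 * np.pi * 10 * t))


@pytest.fixture(scope="session")
def modulated_eeg():
    """Synthetic EEG with period-100 s alpha modulation, depth 0.5."""
    return synth_eeg(duration_s=300.0, modulation_depth=0.5,
                     modulation_period_s=100.0, seed=7)


@pytest.fixture(scope="session")
def alpha_series(modulated_eeg):
    """First-order alpha series of the modulated fixture (preprocessed)."""
    rec = bandpass(remove_offset(modulated_eeg))
    return first_order_series(rec, ALPHA)


def write_minimal_edf(path, data, fs, labels):
    """Write a minimal valid EDF file (synthetic fixture; 16-bit physical
    scaling, 1-s records) for exercising the EDF read path."""
    data = np.asarray(data, dtype=float)
    n_samples, ns = data.shape
    n_records = int(n_samples // fs)
    if n_records * fs != n_samples:
        raise ValueError("duration must be an integer number of seconds")
    spr = int(fs)
    pmin = float(f"{data.min() - 1:.3f}"[:8])
    pmax = float(f"{data.max() + 1:.3f}"[:8])
    dmin, dmax = -32768, 32767

    def pad(s, n):
        b = str(s).encode("ascii")
        return b + b" " * (n - len(b))

    header = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80), pad("01.01.20", 8),
        pad("00.00.00", 8), pad(256 * (1 + ns), 8), pad("", 44),
        pad(n_records, 8), pad(1, 8), pad(ns, 4),
    ])
    signal_header = b"".join([
        b"".join(pad(l, 16) for l in labels),
        b"".join(pad("", 80) for _ in labels),
        b"".join(pad("uV", 8) for _ in labels),
        b"".join(pad(f"{pmin:.3f}"[:8], 8) for _ in labels),
        b"".join(pad(f"{pmax:.3f}"[:8], 8) for _ in labels),
        b"".join(pad(dmin, 8) for _ in labels),
        b"".join(pad(dmax, 8) for _ in labels),
        b"".join(pad("", 80) for _ in labels),
        b"".join(pad(spr, 8) for _ in labels),
        b"".join(pad("", 32) for _ in labels),
    ])
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin) * scale + dmin).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        for r in range(n_records):
            fh.write(digital[r * spr : (r + 1) * spr].T.tobytes())
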