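"""EEG conditioning: per-channel offset removal and 4–30 Hz FIR band-limiting.

The band-pass is a linear-phase windowed-sinc (Hamming) FIR of order 424
designed at 256 Hz. Filtering is single-pass with the constant order/2 = 212
sample group delay compensated by shifting, so filtered samples stay aligned
with the input time axis; the 212 samples at each edge are transient-
contaminated, which downstream windowing tolerates because the first minute of
each task is discarded anyway. A zero-phase (forward-backward) variant is
available via ``zero_phase=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from cogload.io import MultiChannelRecording


@dataclass(frozen=True)
class FilterSpec:
    """Linear-phase FIR band-pass specification.

    order must be even so the group delay order/2 is an integer number of
    samples.
    """

    low_hz: float = 4.0
    high_hz: float = 30.0
    order: int = 424
    fs: float = 256.0
    window: str = "hamming"

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz < self.fs / 2:
            raise ValueError("require 0 < low < high < fs/2")
        if self.order % 2:
            raise ValueError("FIR order must be even")

    def taps(self) -> np.ndarray:
        """The order+1 filter coefficients."""
        return signal.firwin(
            self.order + 1,
            [self.low_hz, self.high_hz],
            fs=self.fs,
            pass_zero=False,
            window=self.window,
        )

    def frequency_response(self, freqs_hz) -> np.ndarray:
        """Complex response of the designed filter at the given frequencies."""
        _, h = signal.freqz(self.taps(), worN=np.atleast_1d(freqs_hz), fs=self.fs)
        return h


def remove_offset(recording: MultiChannelRecording) -> MultiChannelRecording:
    """Subtract each channel's sample mean (DC offset removal)."""
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    centered = recording.samples - recording.samples.mean(axis=0, keepdims=True)
    return replace(recording, samples=centered)


def bandpass(
    recording: MultiChannelRecording,
    spec: FilterSpec = FilterSpec(),
    zero_phase: bool = False,
) -> MultiChannelRecording:
    """Apply the band-pass FIR to every channel, delay-compensated.

    Output has the same length as the input. With ``zero_phase`` the filter is
    applied forward and backward (squaring the magnitude response) instead of
    single-pass with a shift.
    """
    if abs(recording.fs - spec.fs) > 1e-9:
        raise ValueError(
            f"recording at {recording.fs} Hz but filter designed for {spec.fs} Hz"
        )
    if spec.order >= recording.n_samples:
        raise ValueError("filter order must be below the signal length")
    taps = spec.taps()
    if zero_phase:
        out = signal.filtfilt(taps, [1.0], recording.samples, axis=0, padlen=spec.order)
    else:
        # full convolution sliced at the group delay == mode="same" for the
        # odd-length symmetric kernel: compensates the order/2 sample delay
        out = signal.fftconvolve(recording.samples, taps[:, None], mode="full", axes=0)
        half = spec.order // 2
        out = out[half:half + recording.n_samples]
    return replace(recording, samples=np.ascontiguousarray(out))
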