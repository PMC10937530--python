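"""Infra-slow fluctuations of band power: the index and second-order series.

The first-order band-power series (1 sample/s) is itself an oscillating
signal. Its rhythmic infra-slow content is quantified two ways:

* **Infra-slow fluctuation index** — per channel, the fluctuation PSD of the
  alpha-power series integrated over periods 64–128 s, normalized by the
  integral over periods 5–128 s, then averaged across the six channels. A
  fraction in [0, 1]: how much of the (non-DC) fluctuation energy below 0.2 Hz
  sits in the slowest octave.
* **Second-order time series** — per second, the fluctuation power at periods
  40–90 s computed from a 130-s sliding window of the first-order series;
  the per-channel slow-modulation envelope feeding the arousal model.

The mean level of band power is deliberately excluded (linear detrending, and
integration bands that start above 0 Hz): the index measures *fluctuation*,
not level, so adding a constant to the power series leaves it unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import rfft, rfftfreq

from cogload.bandpower import BandDef, PowerTimeSeries, integrate_band

__all__ = [
    "PeriodBand", "InfraslowIndex", "fluctuation_spectrum",
    "infraslow_index", "second_order_series",
    "INDEX_NUMERATOR", "INDEX_DENOMINATOR", "SECOND_ORDER_BAND",
]


@dataclass(frozen=True)
class PeriodBand:
    """A band of oscillation periods [short_s, long_s] seconds, i.e. the
    frequency band [1/long_s, 1/short_s] Hz."""

    long_s: float
    short_s: float

    def __post_init__(self):
        if not 0 < self.short_s < self.long_s:
            raise ValueError("require 0 < short_s < long_s")

    @property
    def f_low(self) -> float:
        return 1.0 / self.long_s

    @property
    def f_high(self) -> float:
        return 1.0 / self.short_s


INDEX_NUMERATOR = PeriodBand(long_s=128.0, short_s=64.0)
INDEX_DENOMINATOR = PeriodBand(long_s=128.0, short_s=5.0)
SECOND_ORDER_BAND = PeriodBand(long_s=90.0, short_s=40.0)


@dataclass
class InfraslowIndex:
    """Channel-averaged infra-slow fluctuation index for one task run."""

    value: float
    per_channel: np.ndarray
    channel_labels: tuple
    condition: str | None = None

    def __post_init__(self):
        self.per_channel = np.asarray(self.per_channel, dtype=float)


def fluctuation_spectrum(
    values,
    dt_s: float = 1.0,
    nperseg: int = 256,
    nfft: int = 512,
    detrend: str | bool = "linear",
    taper: str = "hann",
    min_samples: int = 256,
):
    """Welch PSD of a power time series (the "fluctuation spectrum").

    ``values`` is 1-D or (time x channel); the spectrum spans 0 … 1/(2 dt) Hz.
    A ~300-sample series admits only one 256-sample segment, so by default
    this is a single Hann-tapered, linearly detrended segment zero-padded to
    ``nfft`` (resolution ≈ 0.002 Hz); longer series average multiple
    half-overlapping segments.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < min_samples:
        raise ValueError(
            f"series of {n} samples too short for fluctuation analysis "
            f"(need ≥ {min_samples})"
        )
    nper = min(nperseg, n)
    freqs, psd = sps.welch(
        values,
        fs=1.0 / dt_s,
        window=taper,
        nperseg=nper,
        noverlap=nper // 2,
        nfft=max(nfft, nper),
        detrend=detrend,
        axis=0,
    )
    return freqs, psd


def infraslow_index(
    alpha_series: PowerTimeSeries,
    num_band: PeriodBand = INDEX_NUMERATOR,
    den_band: PeriodBand = INDEX_DENOMINATOR,
    condition: str | None = None,
    **spectrum_kw,
) -> InfraslowIndex:
    """Infra-slow fluctuation index of a band-power series.

    Per channel: integral of the fluctuation PSD over [1/128, 1/64] Hz divided
    by the integral over [1/128, 1/5] Hz; the reported value is the arithmetic
    mean of the per-channel ratios. Because the numerator band is nested in
    the denominator band the ratio lies in [0, 1].
    """
    n = alpha_series.n_windows
    if n * alpha_series.dt_s < 2 * num_band.long_s:
        warnings.warn(
            f"series of {n * alpha_series.dt_s:.0f} s holds fewer than two full "
            f"cycles of the longest analyzed period ({num_band.long_s:.0f} s); "
            "the index estimate will be coarse",
            stacklevel=2,
        )
    freqs, psd = fluctuation_spectrum(alpha_series.values, alpha_series.dt_s, **spectrum_kw)
    num = integrate_band(freqs, psd, num_band.f_low, num_band.f_high, axis=0)
    den = integrate_band(freqs, psd, den_band.f_low, den_band.f_high, axis=0)
    if np.any(den <= 0):
        raise ValueError("zero fluctuation power in the normalization band")
    per_channel = num / den
    return InfraslowIndex(
        value=float(np.mean(per_channel)),
        per_channel=per_channel,
        channel_labels=alpha_series.channel_labels,
        condition=condition,
    )


def _detrended_windows(x: np.ndarray, length: int, shift: int) -> np.ndarray:
    """Strided [n_windows x length] view of a 1-D/2-D series with a per-window
    linear trend removed (vectorized least squares against t = 0..length-1)."""
    n_out = (x.shape[0] - length) // shift + 1
    idx = np.arange(length)[None, :] + shift * np.arange(n_out)[:, None]
    w = x[idx]  # (n_out, length) or (n_out, length, n_ch)
    t = np.arange(length, dtype=float)
    t = t - t.mean()
    denom = np.sum(t**2)
    if w.ndim == 3:
        t_ = t[None, :, None]
    else:
        t_ = t[None, :]
    slope = np.sum(w * t_, axis=1, keepdims=True) / denom
    mean = w.mean(axis=1, keepdims=True)
    return w - mean - slope * t_


def second_order_series(
    band_series: PowerTimeSeries,
    window_s: float = 130.0,
    shift_s: float = 1.0,
    band: PeriodBand = SECOND_ORDER_BAND,
    nfft: int = 256,
    taper: str = "hann",
) -> PowerTimeSeries:
    """Sliding-window infra-slow fluctuation power of a first-order series.

    Each 130-s window of the (1 Hz) band-power series yields one value: the
    integrated fluctuation PSD over periods 40–90 s. Output length is
    ``len − 130 + 1``; values are stamped at window starts, so the
    second-order series covers only the leading part of the first-order
    series' time axis.
    """
    length = int(round(window_s / band_series.dt_s))
    shift = int(round(shift_s / band_series.dt_s))
    x = band_series.values
    if x.shape[0] < length:
        raise ValueError(
            f"series of {x.shape[0]} samples shorter than the "
            f"{length}-sample second-order window"
        )
    fs = 1.0 / band_series.dt_s
    win = sps.get_window(taper, length)
    scale = 1.0 / (fs * np.sum(win**2))
    nfft = max(nfft, length)
    freqs = rfftfreq(nfft, d=band_series.dt_s)

    w = _detrended_windows(x, length, shift)  # (n_out, length, n_ch)
    spec = rfft(w * win[None, :, None], n=nfft, axis=1)
    psd = (spec.real**2 + spec.imag**2) * scale
    psd[:, 1:, :] *= 2.0
    if nfft % 2 == 0:
        psd[:, -1, :] /= 2.0
    values = integrate_band(freqs, psd, band.f_low, band.f_high, axis=1)
    out_band = BandDef(f"{band_series.band.name}_fluct", band.f_low, band.f_high)
    return PowerTimeSeries(
        values, out_band, shift_s, band_series.t0_s, band_series.channel_labels
    )
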