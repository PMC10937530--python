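"""n-back behavioral scoring and reaction-time indices.

Zero-back (low load): respond with the parity of the displayed digit.
Three-back (high load): respond whether the digit matches the one shown three
trials earlier; the first three trials have no defined truth and are flagged
non-scorable. Summary indices per run: accuracy, mean RT over all responded
trials (correct and incorrect alike), the RT interquartile range, and the RT
fluctuation index — the mean Welch PSD of the trial-by-trial RT series in the
very-low-frequency band (< 0.05 Hz), which rises when responding waxes and
wanes slowly over the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from cogload.io import TaskRun

__all__ = [
    "BehaviorSummary", "score_zero_back", "score_three_back", "score_trials",
    "rt_indices", "rt_fluctuation_spectrum", "summarize",
]

#: RT fluctuation band (Hz): open at 0 (the mean never counts as fluctuation)
VLF_BAND = (0.0, 0.05)


@dataclass
class BehaviorSummary:
    """Scalar behavioral indices for one task run."""

    condition: str
    accuracy: float
    mean_rt_ms: float
    rt_iqr_ms: float
    rt_fluct_index: float
    n_scorable: int
    n_omitted: int


def score_zero_back(run: TaskRun):
    """Per-trial correctness of parity judgments.

    Returns (correct, scorable) boolean arrays; every trial is scorable.
    """
    if run.n_trials < 1:
        raise ValueError("no trials to score")
    digits = run.digits
    truth = np.where(digits % 2 == 0, "even", "odd")
    responses = np.asarray(run.responses)
    valid = np.isin(responses, ("even", "odd", "none"))
    if not valid.all():
        bad = sorted(set(responses[~valid]))
        raise ValueError(f"malformed zero-back responses: {bad}")
    correct = responses == truth
    return correct, np.ones(run.n_trials, dtype=bool)


def score_three_back(run: TaskRun):
    """Per-trial correctness of 3-back match judgments.

    Trial i (0-based, i >= 3) is a match iff digit[i] == digit[i-3]; trials
    0–2 are non-scorable. Returns (correct, scorable) boolean arrays.
    """
    if run.n_trials < 4:
        raise ValueError("three-back needs at least 4 trials to score")
    digits = run.digits
    responses = np.asarray(run.responses)
    valid = np.isin(responses, ("match", "nonmatch", "none"))
    if not valid.all():
        bad = sorted(set(responses[~valid]))
        raise ValueError(f"malformed three-back responses: {bad}")
    scorable = np.zeros(run.n_trials, dtype=bool)
    scorable[3:] = True
    truth = np.full(run.n_trials, "", dtype=object)
    truth[3:] = np.where(digits[3:] == digits[:-3], "match", "nonmatch")
    correct = scorable & (responses == truth)
    return correct, scorable


def score_trials(run: TaskRun):
    """Dispatch to the condition's scorer."""
    if run.condition == "zero_back":
        return score_zero_back(run)
    return score_three_back(run)


def accuracy(run: TaskRun, denominator: str = "scorable") -> float:
    """Fraction of correct responses; ``denominator`` counts either only
    scorable trials (default) or all trials."""
    correct, scorable = score_trials(run)
    n = int(scorable.sum()) if denominator == "scorable" else run.n_trials
    return float(correct.sum() / n)


def rt_indices(run: TaskRun, min_responses: int = 8):
    """Mean and interquartile range of RT over all responded trials.

    Correct and incorrect responses both enter; omissions are excluded and
    counted. Quartiles use linear interpolation (numpy default), declared
    because IQR values depend on the quantile rule.
    """
    rts = run.rts_ms
    responded = ~np.isnan(rts)
    if responded.sum() < min_responses:
        raise ValueError(
            f"only {int(responded.sum())} responded trials; need ≥ {min_responses}"
        )
    r = rts[responded]
    q1, q3 = np.percentile(r, [25, 75])
    return float(np.mean(r)), float(q3 - q1), int((~responded).sum())


def rt_fluctuation_spectrum(
    run: TaskRun,
    band_hz=VLF_BAND,
    max_missing: float = 0.2,
    nperseg: int = 128,
):
    """Welch PSD of the trial-indexed RT series and its VLF fluctuation index.

    The RT series is sampled once per inter-stimulus interval (1/isi Hz);
    missing responses are linearly interpolated before the spectrum (raises
    when more than ``max_missing`` of trials lack a response). The index is
    the mean PSD over 0 < f < 0.05 Hz — invariant to adding a constant to all
    RTs since the 0-Hz bin is excluded.
    """
    rts = run.rts_ms
    missing = np.isnan(rts)
    if missing.mean() > max_missing:
        raise ValueError(
            f"{missing.mean():.0%} of trials lack a response (limit {max_missing:.0%})"
        )
    idx = np.arange(len(rts))
    series = rts.copy()
    if missing.any():
        series[missing] = np.interp(idx[missing], idx[~missing], rts[~missing])
    fs = 1.0 / run.isi_s
    nper = min(nperseg, len(series))
    freqs, psd = sps.welch(
        series, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2,
        detrend="constant",
    )
    in_band = (freqs > band_hz[0]) & (freqs < band_hz[1])
    index = float(np.mean(psd[in_band])) if in_band.any() else float("nan")
    return freqs, psd, index


def summarize(run: TaskRun, denominator: str = "scorable") -> BehaviorSummary:
    """All behavioral indices for one run."""
    correct, scorable = score_trials(run)
    acc = correct.sum() / (scorable.sum() if denominator == "scorable" else run.n_trials)
    mean_rt, iqr, n_omitted = rt_indices(run)
    _, _, fluct = rt_fluctuation_spectrum(run)
    return BehaviorSummary(
        condition=run.condition,
        accuracy=float(acc),
        mean_rt_ms=mean_rt,
        rt_iqr_ms=iqr,
        rt_fluct_index=fluct,
        n_scorable=int(scorable.sum()),
        n_omitted=n_omitted,
    )
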