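"""Seeded synthetic multi-modal sessions with known ground truth.

Emulates the study conditions end to end: 6-min, 6-channel frontal EEG at
256 Hz built from 1/f background noise plus narrowband theta and alpha, where
the alpha component's envelope carries a multiplicative infra-slow modulation
1 + depth*sin(2*pi*t/period); ring-finger PPG at 512 Hz as a pulse-template
train with sinusoidally modulated inter-beat intervals (respiratory sinus
arrhythmia); EDA as a slowly drifting tonic level with injected SCR
transients; and 200-trial n-back logs at 3-s ISI with Bernoulli correctness
and a low-frequency RT drift.

Cohorts couple a latent per-participant trait to both the high-load increase
in alpha modulation depth and task accuracy through a bivariate Gaussian
copula, so the induced correlation between the two ground-truth quantities
equals ``trait_rho`` in expectation — the structure the end-to-end
correlational analysis is asked to recover.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq

from cogload.io import EEG_CHANNELS, MultiChannelRecording, TaskRun, Trial

__all__ = [
    "CohortSpec", "ParticipantData", "CohortData",
    "synth_eeg", "synth_ppg", "synth_eda", "synth_behavior", "synth_cohort",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _shaped_noise(n: int, fs: float, rng, exponent: float = 0.0,
                  band: tuple | None = None) -> np.ndarray:
    """Unit-variance Gaussian noise spectrally shaped as 1/f^exponent and/or
    band-limited (frequency-domain construction)."""
    white = rng.standard_normal(n)
    spec = rfft(white)
    f = rfftfreq(n, d=1.0 / fs)
    gain = np.ones_like(f)
    if exponent:
        gain[1:] = f[1:] ** (-exponent / 2.0)
        gain[0] = 0.0
    if band is not None:
        gain *= (f >= band[0]) & (f <= band[1])
    x = irfft(spec * gain, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synth_eeg(
    duration_s: float = 360.0,
    fs: float = 256.0,
    alpha_amp: float = 6.0,
    theta_amp: float = 5.0,
    noise_amp: float = 10.0,
    modulation_depth: float = 0.5,
    modulation_period_s: float = 100.0,
    noise_1f_exponent: float = 1.0,
    envelope_noise_sd: float = 0.25,
    seed=0,
) -> MultiChannelRecording:
    """Six-channel frontal EEG with infra-slow amplitude-modulated alpha.

    Each channel is 1/f background + narrowband theta (4–7 Hz) + narrowband
    alpha (8–13 Hz) whose envelope is ``1 + depth*sin(2*pi*t/period)``; the
    modulation phase is shared across channels (a global arousal-like
    drive) and randomized per recording. On top of the imposed rhythmic
    modulation, the alpha envelope carries spontaneous broadband infra-slow
    waxing and waning (log-normal, per channel, sd ``envelope_noise_sd`` in
    log units) — without it the band-power series would fluctuate only
    through estimation noise, which real EEG does not resemble. Amplitudes
    are μV-scale standard deviations of each component.
    """
    if not 0 <= modulation_depth <= 1:
        raise ValueError("modulation depth must lie in [0, 1] (envelope >= 0)")
    rng = _rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + modulation_depth * np.sin(2 * np.pi * t / modulation_period_s + phase)
    channels = []
    for _ in EEG_CHANNELS:
        bg = noise_amp * _shaped_noise(n, fs, rng, exponent=noise_1f_exponent)
        th = theta_amp * _shaped_noise(n, fs, rng, band=(4.0, 7.0))
        if envelope_noise_sd > 0:
            slow = _shaped_noise(n, fs, rng, exponent=0.5, band=(0.0, 0.25))
            spont = np.exp(envelope_noise_sd * slow - envelope_noise_sd**2 / 2)
        else:
            spont = 1.0
        al = alpha_amp * _shaped_noise(n, fs, rng, band=(8.0, 13.0)) * envelope * spont
        channels.append(bg + th + al)
    return MultiChannelRecording(
        np.column_stack(channels), fs, EEG_CHANNELS, modality="EEG"
    )


def _ppg_template(fs: float) -> np.ndarray:
    """One pulse waveform (~0.7 s): systolic peak plus small dicrotic bump;
    the template maximum sits at its center so beats land at peak times."""
    tt = np.arange(int(0.7 * fs)) / fs - 0.35
    wave = np.exp(-(tt / 0.055) ** 2) + 0.25 * np.exp(-(((tt - 0.22) / 0.08) ** 2))
    return wave


def synth_ppg(
    duration_s: float = 360.0,
    fs: float = 512.0,
    mean_ibi_ms: float = 800.0,
    rsa_amp_ms: float = 40.0,
    rsa_freq_hz: float = 0.25,
    jitter_ms: float = 3.0,
    snr_db: float | None = 20.0,
    seed=0,
):
    """Pulse-template train with modulated beat-to-beat intervals.

    Returns (recording, true_beat_times_s). The instantaneous inter-beat
    interval is ``mean + rsa_amp*sin(2*pi*f_rsa*t) + jitter``; additive
    Gaussian noise is scaled to the requested SNR (None = noise-free).
    """
    if not 500.0 <= mean_ibi_ms <= 1500.0:
        raise ValueError("mean IBI outside the plausible 500–1500 ms range")
    if rsa_amp_ms >= mean_ibi_ms / 2:
        raise ValueError("RSA amplitude must stay below half the mean IBI")
    rng = _rng(seed)
    beats = []
    t = 0.3
    while t < duration_s - 0.5:
        beats.append(t)
        ibi = (
            mean_ibi_ms
            + rsa_amp_ms * np.sin(2 * np.pi * rsa_freq_hz * t)
            + jitter_ms * rng.standard_normal()
        )
        t += ibi / 1000.0
    beats = np.asarray(beats)

    n = int(round(duration_s * fs))
    x = np.zeros(n)
    tpl = _ppg_template(fs)
    half = len(tpl) // 2
    for b in beats:
        i = int(round(b * fs))
        lo, hi = i - half, i - half + len(tpl)
        s0, s1 = max(lo, 0), min(hi, n)
        x[s0:s1] += tpl[s0 - lo : s1 - lo]
    if snr_db is not None:
        noise_sd = x.std() / (10 ** (snr_db / 20.0))
        x = x + noise_sd * rng.standard_normal(n)
    rec = MultiChannelRecording(x[:, None], fs, ("PPG",), modality="PPG")
    return rec, beats


def _scr_template(fs: float, tau_rise: float = 0.7, tau_decay: float = 3.0,
                  length_s: float = 15.0) -> np.ndarray:
    """Biexponential SCR shape, unit peak amplitude (rise to peak ~1.3 s)."""
    tt = np.arange(int(length_s * fs)) / fs
    wave = np.exp(-tt / tau_decay) - np.exp(-tt / tau_rise)
    return wave / wave.max()


def synth_eda(
    duration_s: float = 360.0,
    fs: float = 512.0,
    tonic_uS: float = 2.0,
    drift_amp_uS: float = 0.05,
    scr_times_s=None,
    scr_rate_per_min: float = 4.0,
    scr_amp_uS: float = 0.2,
    noise_uS: float = 0.003,
    seed=0,
):
    """Tonic skin conductance with injected SCR transients.

    Returns (recording, true_onset_times_s). Events are placed at
    ``scr_times_s`` when given, else drawn uniformly at the requested rate
    with a 10-s refractory spacing.
    """
    rng = _rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = tonic_uS + drift_amp_uS * np.sin(2 * np.pi * t / duration_s + rng.uniform(0, 6.28))
    if scr_times_s is None:
        n_events = rng.poisson(scr_rate_per_min * duration_s / 60.0)
        onsets = np.sort(rng.uniform(5.0, duration_s - 20.0, size=n_events))
        onsets = onsets[np.concatenate([[True], np.diff(onsets) > 10.0])]
    else:
        onsets = np.asarray(scr_times_s, dtype=float)
    tpl = _scr_template(fs)
    for o in onsets:
        i = int(round(o * fs))
        hi = min(i + len(tpl), n)
        x[i:hi] += scr_amp_uS * tpl[: hi - i]
    x = x + noise_uS * rng.standard_normal(n)
    rec = MultiChannelRecording(x[:, None], fs, ("EDA",), modality="EDA")
    return rec, onsets


def synth_behavior(
    condition: str = "three_back",
    n_trials: int = 200,
    isi_s: float = 3.0,
    accuracy_true: float = 0.9,
    rt_base_ms: float = 600.0,
    rt_noise_ms: float = 80.0,
    rt_drift_amp_ms: float = 0.0,
    rt_drift_period_s: float = 50.0,
    omission_rate: float = 0.0,
    seed=0,
) -> TaskRun:
    """An n-back trial log with Bernoulli correctness and drifting RTs.

    Responses are correct with probability ``accuracy_true`` independently
    per trial; RTs are base + low-frequency sinusoidal drift + Gaussian
    noise, floored at 150 ms.
    """
    if not 0 <= accuracy_true <= 1:
        raise ValueError("accuracy_true must lie in [0, 1]")
    rng = _rng(seed)
    digits = rng.integers(0, 10, size=n_trials)
    trials = []
    for i in range(n_trials):
        onset = i * isi_s
        if condition == "zero_back":
            truth = "even" if digits[i] % 2 == 0 else "odd"
            wrong = "odd" if truth == "even" else "even"
        else:
            if i >= 3:
                truth = "match" if digits[i] == digits[i - 3] else "nonmatch"
            else:  # no defined truth; respond anyway, content arbitrary
                truth = "nonmatch"
            wrong = "match" if truth == "nonmatch" else "nonmatch"
        if omission_rate and rng.random() < omission_rate:
            trials.append(Trial(i, int(digits[i]), onset, "none", float("nan")))
            continue
        response = truth if rng.random() < accuracy_true else wrong
        rt = (
            rt_base_ms
            + rt_drift_amp_ms * np.sin(2 * np.pi * onset / rt_drift_period_s)
            + rt_noise_ms * rng.standard_normal()
        )
        trials.append(Trial(i, int(digits[i]), onset, response, max(rt, 150.0)))
    return TaskRun(condition=condition, trials=trials, isi_s=isi_s)


@dataclass
class CohortSpec:
    """Generation parameters for a synthetic study cohort.

    ``trait_rho`` is the target correlation between the latent infra-slow
    enhancement (three-back minus zero-back modulation depth) and three-back
    accuracy, induced through a bivariate Gaussian copula on the two
    quantities.
    """

    n_participants: int = 12
    trait_rho: float = 0.7
    modulation_period_s: float = 100.0
    depth_mid: float = 0.30
    depth_diff_mean: float = 0.15
    depth_diff_sd: float = 0.24
    envelope_noise_sd: float = 0.25
    accuracy_three_mean: float = 0.78
    accuracy_three_sd: float = 0.12
    accuracy_zero_mean: float = 0.96
    noise_1f_exponent: float = 1.0
    eeg_duration_s: float = 360.0
    mean_ibi_ms: float = 800.0
    rsa_amp_ms: float = 40.0
    scr_rate_per_min: float = 4.0
    rt_base_ms: float = 600.0
    rt_noise_ms: float = 80.0
    rt_drift_amp_three_ms: float = 120.0
    rt_drift_amp_zero_ms: float = 30.0
    rt_drift_period_s: float = 50.0
    n_trials: int = 200
    isi_s: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 4:
            raise ValueError("cohort needs at least 4 participants")
        if abs(self.trait_rho) > 1:
            raise ValueError("|trait_rho| must be <= 1")
        # binomial response noise bounds the correlation the measured
        # accuracy can carry; report infeasible targets instead of clipping
        p = self.accuracy_three_mean
        binom_sd = np.sqrt(p * (1 - p) / self.n_trials)
        attainable = self.accuracy_three_sd / np.hypot(self.accuracy_three_sd, binom_sd)
        if abs(self.trait_rho) > attainable:
            raise ValueError(
                f"trait_rho {self.trait_rho} exceeds the attainable |rho| "
                f"{attainable:.3f} under the accuracy noise settings"
            )


@dataclass
class ParticipantData:
    """One participant's recordings and logs for both conditions."""

    participant_id: str
    eeg: dict = field(default_factory=dict)        # condition -> recording
    ppg: dict = field(default_factory=dict)
    eda: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)   # condition -> TaskRun
    truth: dict = field(default_factory=dict)


@dataclass
class CohortData:
    participants: list
    ground_truth: "object"  # pandas DataFrame
    spec: CohortSpec


CONDITIONS = ("zero_back", "three_back")


def synth_cohort(spec: CohortSpec, modalities=("eeg", "ppg", "eda", "behavior")) -> CohortData:
    """Generate a full cohort (participants x 2 conditions) with ground truth.

    The latent copula draws (u, v) with correlation ``trait_rho``; u drives
    the high-minus-low-load modulation-depth difference (split symmetrically
    around ``depth_mid`` so both conditions stay in the index's responsive
    range), v the three-back accuracy, so the ground-truth depth difference
    and accuracy correlate at ``trait_rho`` in expectation.
    """
    import pandas as pd

    rng = _rng(spec.seed)
    cov = np.array([[1.0, spec.trait_rho], [spec.trait_rho, 1.0]])
    uv = rng.multivariate_normal([0.0, 0.0], cov, size=spec.n_participants)
    participants, rows = [], []
    for i in range(spec.n_participants):
        pid = f"P{i + 1:02d}"
        u, v = uv[i]
        diff = spec.depth_diff_mean + spec.depth_diff_sd * u
        depth_zero = float(np.clip(spec.depth_mid - diff / 2, 0.02, 0.95))
        depth_three = float(np.clip(spec.depth_mid + diff / 2, 0.02, 0.95))
        acc_three = float(np.clip(spec.accuracy_three_mean + spec.accuracy_three_sd * v, 0.50, 0.995))
        acc_zero = float(np.clip(spec.accuracy_zero_mean + 0.01 * rng.standard_normal(), 0.85, 1.0))
        depths = {"zero_back": depth_zero, "three_back": depth_three}
        accs = {"zero_back": acc_zero, "three_back": acc_three}
        rt_drifts = {"zero_back": spec.rt_drift_amp_zero_ms,
                     "three_back": spec.rt_drift_amp_three_ms}
        pdata = ParticipantData(pid)
        pdata.truth = {
            "depth_zero": depth_zero,
            "depth_three": depth_three,
            "depth_diff": depth_three - depth_zero,
            "accuracy_true_zero": acc_zero,
            "accuracy_true_three": acc_three,
        }
        # one noise realization per participant and modality, shared across
        # conditions: the participant's intrinsic signal processes are the
        # same in both tasks and only the imposed parameters differ (paired
        # design / common random numbers)
        sub = rng.integers(2**31, size=4)
        for cond in CONDITIONS:
            if "eeg" in modalities:
                pdata.eeg[cond] = synth_eeg(
                    duration_s=spec.eeg_duration_s,
                    modulation_depth=depths[cond],
                    modulation_period_s=spec.modulation_period_s,
                    noise_1f_exponent=spec.noise_1f_exponent,
                    envelope_noise_sd=spec.envelope_noise_sd,
                    seed=int(sub[0]),
                )
            if "ppg" in modalities:
                pdata.ppg[cond], _ = synth_ppg(
                    duration_s=spec.eeg_duration_s,
                    mean_ibi_ms=spec.mean_ibi_ms,
                    rsa_amp_ms=spec.rsa_amp_ms,
                    seed=int(sub[1]),
                )
            if "eda" in modalities:
                pdata.eda[cond], _ = synth_eda(
                    duration_s=spec.eeg_duration_s,
                    scr_rate_per_min=spec.scr_rate_per_min,
                    seed=int(sub[2]),
                )
            if "behavior" in modalities:
                pdata.behavior[cond] = synth_behavior(
                    condition=cond,
                    n_trials=spec.n_trials,
                    isi_s=spec.isi_s,
                    accuracy_true=accs[cond],
                    rt_base_ms=spec.rt_base_ms,
                    rt_noise_ms=spec.rt_noise_ms,
                    rt_drift_amp_ms=rt_drifts[cond],
                    rt_drift_period_s=spec.rt_drift_period_s,
                    seed=int(sub[3]),
                )
        participants.append(pdata)
        rows.append({"participant_id": pid, **pdata.truth})
    return CohortData(participants, pd.DataFrame(rows), spec)


def write_cohort(cohort: CohortData, out_dir) -> None:
    """Write a cohort in the CSV layout the io/pipeline modules read:
    ``<pid>/<condition>_{eeg,ppg,eda}.csv`` and ``_trials.csv`` plus
    ``ground_truth.csv`` at the top level."""
    from pathlib import Path

    from cogload.io import write_recording, write_trials

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in cohort.participants:
        pdir = out / p.participant_id
        pdir.mkdir(exist_ok=True)
        for cond in CONDITIONS:
            if cond in p.eeg:
                write_recording(p.eeg[cond], pdir / f"{cond}_eeg.csv")
            if cond in p.ppg:
                write_recording(p.ppg[cond], pdir / f"{cond}_ppg.csv")
            if cond in p.eda:
                write_recording(p.eda[cond], pdir / f"{cond}_eda.csv")
            if cond in p.behavior:
                write_trials(p.behavior[cond], pdir / f"{cond}_trials.csv")
    cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
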