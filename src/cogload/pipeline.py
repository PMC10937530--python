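"""End-to-end orchestration: recordings -> per-participant indices -> statistics.

For every participant and condition the pipeline trims the first minute,
band-limits the EEG, computes the first-order alpha/theta series, the
infra-slow fluctuation index, RMSSD, the SCR rate, the behavioral indices
and (when a trained model is supplied) the high-arousal portion; it then
forms three-back-minus-zero-back difference scores and runs the paired-test
and difference-score-correlation battery with Benjamini–Hochberg correction.

Defaults equal the study parameters: 60-s trim; 4–30 Hz order-424 FIR;
20 s/1 s/1 s power windows; index bands 64–128 s over 5–128 s; 130-s
second-order windows over 40–90 s; 3-s ISI. Every effective parameter is
echoed into the report so a run can be reproduced from its own output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cogload import autonomic, behavior
from cogload.arousal import build_features, estimate_trace
from cogload.bandpower import ALPHA, THETA, first_order_series
from cogload.infraslow import infraslow_index, second_order_series
from cogload.io import MultiChannelRecording, TaskRun, read_recording, read_trials, trim_initial
from cogload.preprocess import FilterSpec, bandpass, remove_offset
from cogload.stats import bh_adjust, diff_correlation, difference_scores, paired_test

log = logging.getLogger("cogload.pipeline")

CONDITIONS = ("zero_back", "three_back")


@dataclass
class PipelineConfig:
    """Every knob of the study pipeline, defaulting to the study values."""

    data_dir: str | None = None
    out_dir: str | None = None
    trim_s: float = 60.0
    filter_low_hz: float = 4.0
    filter_high_hz: float = 30.0
    filter_order: int = 424
    zero_phase: bool = False
    window_s: float = 20.0
    shift_s: float = 1.0
    segment_s: float = 1.0
    index_num_period_s: tuple = (64.0, 128.0)
    index_den_period_s: tuple = (5.0, 128.0)
    second_order_window_s: float = 130.0
    second_order_period_s: tuple = (40.0, 90.0)
    scr_threshold_uS: float = 0.05
    isi_s: float = 3.0
    bh_q: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("index_num_period_s", "index_den_period_s", "second_order_period_s"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SessionResult:
    """Scalar indices for one participant x condition."""

    participant_id: str
    condition: str
    infraslow_index: float = np.nan
    alpha_median: float = np.nan
    rmssd_ms: float = np.nan
    scr_rate_per_min: float = np.nan
    accuracy: float = np.nan
    mean_rt_ms: float = np.nan
    rt_iqr_ms: float = np.nan
    rt_fluct_index: float = np.nan
    high_portion: float = np.nan
    missing: list = field(default_factory=list)


def eeg_indices(eeg: MultiChannelRecording, config: PipelineConfig,
                arousal_model=None) -> dict:
    """Infra-slow index (and optionally the arousal trace) of one EEG run."""
    from cogload.infraslow import PeriodBand

    rec = trim_initial(eeg, config.trim_s)
    rec = remove_offset(rec)
    spec = FilterSpec(config.filter_low_hz, config.filter_high_hz,
                      config.filter_order, eeg.fs)
    rec = bandpass(rec, spec, zero_phase=config.zero_phase)
    alpha1 = first_order_series(rec, ALPHA, window_s=config.window_s,
                                shift_s=config.shift_s, segment_s=config.segment_s)
    num = PeriodBand(config.index_num_period_s[1], config.index_num_period_s[0])
    den = PeriodBand(config.index_den_period_s[1], config.index_den_period_s[0])
    idx = infraslow_index(alpha1, num, den)
    out = {
        "infraslow_index": idx.value,
        "alpha_median": float(np.median(alpha1.values)),
    }
    if arousal_model is not None:
        theta1 = first_order_series(rec, THETA, window_s=config.window_s,
                                    shift_s=config.shift_s, segment_s=config.segment_s)
        so_band = PeriodBand(config.second_order_period_s[1], config.second_order_period_s[0])
        alpha2 = second_order_series(alpha1, config.second_order_window_s,
                                     config.shift_s, so_band)
        theta2 = second_order_series(theta1, config.second_order_window_s,
                                     config.shift_s, so_band)
        feats = build_features(alpha1, theta1, alpha2, theta2)
        out["high_portion"] = estimate_trace(arousal_model, feats).high_portion
    return out


def process_session(
    participant_id: str,
    condition: str,
    config: PipelineConfig,
    eeg: MultiChannelRecording | None = None,
    ppg: MultiChannelRecording | None = None,
    eda: MultiChannelRecording | None = None,
    trials: TaskRun | None = None,
    arousal_model=None,
) -> SessionResult:
    """Compute all indices for one condition; absent modalities yield NaN
    fields and are listed in ``missing`` (mirrors the study's handling of
    participants with unusable EDA)."""
    res = SessionResult(participant_id, condition)
    if eeg is not None:
        res.__dict__.update(eeg_indices(eeg, config, arousal_model))
    else:
        res.missing.append("eeg")
    if ppg is not None:
        beats = autonomic.detect_pulses(trim_initial(ppg, config.trim_s))
        res.rmssd_ms = autonomic.rmssd(beats.nn_intervals_ms)
    else:
        res.missing.append("ppg")
    if eda is not None:
        scr = autonomic.detect_scr(trim_initial(eda, config.trim_s),
                                   min_amplitude_uS=config.scr_threshold_uS)
        res.scr_rate_per_min = scr.rate_per_min
    else:
        res.missing.append("eda")
    if trials is not None:
        summ = behavior.summarize(trials)
        res.accuracy = summ.accuracy
        res.mean_rt_ms = summ.mean_rt_ms
        res.rt_iqr_ms = summ.rt_iqr_ms
        res.rt_fluct_index = summ.rt_fluct_index
    else:
        res.missing.append("behavior")
    return res


def run_participant(config: PipelineConfig, participant_id: str,
                    arousal_model=None) -> list:
    """Process both conditions of one participant from ``config.data_dir``
    (layout written by :func:`cogload.synthdata.write_cohort`)."""
    pdir = Path(config.data_dir) / participant_id
    results = []
    for cond in CONDITIONS:
        kw = {}
        for modality, reader in (
            ("eeg", lambda p: read_recording(p, "EEG")),
            ("ppg", lambda p: read_recording(p, "PPG")),
            ("eda", lambda p: read_recording(p, "EDA")),
        ):
            path = pdir / f"{cond}_{modality}.csv"
            if path.exists():
                try:
                    kw[modality] = reader(path)
                except Exception as err:
                    raise RuntimeError(f"stage io/{modality} failed for "
                                       f"{participant_id}/{cond}: {err}") from err
            else:
                log.warning("%s/%s: missing %s", participant_id, cond, modality)
        tpath = pdir / f"{cond}_trials.csv"
        if tpath.exists():
            kw["trials"] = read_trials(tpath, cond, config.isi_s)
        results.append(process_session(participant_id, cond, config,
                                       arousal_model=arousal_model, **kw))
    return results


_PAIRED_VARS = ("infraslow_index", "accuracy", "mean_rt_ms", "rt_iqr_ms",
                "rt_fluct_index", "rmssd_ms", "scr_rate_per_min")

#: the study's correlation battery: (column_a, column_b) on the merged table
_CORRELATIONS = (
    ("infraslow_index_diff", "accuracy_three"),
    ("rmssd_ms_three", "accuracy_three"),
    ("rt_iqr_ms_diff", "accuracy_three"),
    ("scr_rate_per_min_three", "accuracy_three"),
    ("infraslow_index_diff", "rt_iqr_ms_diff"),
    ("infraslow_index_diff", "rt_fluct_index_diff"),
)


def analyze_cohort(summary: pd.DataFrame, config: PipelineConfig) -> dict:
    """Statistics battery on a per-participant x condition summary table."""
    diffs = difference_scores(summary)
    three = summary[summary.condition == "three_back"].set_index("participant_id")
    table = diffs.set_index("participant_id")
    for col in ("accuracy", "rmssd_ms", "scr_rate_per_min"):
        if col in three.columns:
            table[f"{col}_three"] = three[col]
    table = table.reset_index()

    paired, correlations = {}, {}
    for var in _PAIRED_VARS:
        if var not in summary.columns:
            continue
        wide = summary.pivot(index="participant_id", columns="condition", values=var).dropna()
        try:
            res = paired_test(wide["three_back"], wide["zero_back"])
            paired[var] = dataclasses.asdict(res)
        except ValueError as err:
            paired[var] = {"error": str(err)}
    for a, b in _CORRELATIONS:
        if a not in table.columns or b not in table.columns:
            continue
        try:
            res = diff_correlation(table, a, b)
            correlations[f"{a}~{b}"] = dataclasses.asdict(res)
        except ValueError as err:
            correlations[f"{a}~{b}"] = {"error": str(err)}
    valid = {k: v for k, v in correlations.items() if "p_value" in v}
    if valid:
        adj, rej = bh_adjust([v["p_value"] for v in valid.values()], q=config.bh_q)
        for (k, v), a, rj in zip(valid.items(), adj, rej):
            v["p_adjusted"] = float(a)
            v["discovery"] = bool(rj)
    return {
        "config": config.to_dict(),
        "n_participants": int(summary.participant_id.nunique()),
        "paired_tests": paired,
        "correlations": correlations,
        "difference_table": table.to_dict(orient="list"),
    }


def run_cohort(config: PipelineConfig, participant_ids=None, arousal_model=None) -> dict:
    """Full pipeline over a cohort directory: summaries + statistics report.

    Writes ``summary.csv`` and ``report.json`` to ``config.out_dir`` when it
    is set, and returns the report dict with the summary table attached.
    """
    data_dir = Path(config.data_dir)
    if participant_ids is None:
        participant_ids = sorted(
            p.name for p in data_dir.iterdir()
            if p.is_dir() and any(p.glob("*_*.csv"))
        )
    if len(participant_ids) < 4:
        raise ValueError("cohort analysis needs at least 4 participants")
    rows = []
    for pid in participant_ids:
        for res in run_participant(config, pid, arousal_model):
            rows.append({k: v for k, v in dataclasses.asdict(res).items() if k != "missing"})
    summary = pd.DataFrame(rows)
    report = analyze_cohort(summary, config)
    report["summary"] = summary.to_dict(orient="list")
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
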