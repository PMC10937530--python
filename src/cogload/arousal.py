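"""SVM-based arousal-state estimation from EEG power-fluctuation features.

Per second of task time, a 24-dimensional feature vector is assembled from
the {first-order, second-order} x {alpha, theta} power series of the six
frontal channels. Vectors are z-normalized per participant and task,
classified high/low arousal by a Gaussian-kernel support vector machine, and
validated with leave-one-person-out cross-validation (every fold holds out
all vectors of one participant, so no participant leaks between train and
test). The run-level summary is the high-arousal portion: the fraction of
seconds classified as high arousal.

The published model's weights and training data are not distributed; this
module ships the architecture and training harness, trained on labeled
(typically synthetic) sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.svm import SVC

from cogload.bandpower import PowerTimeSeries

__all__ = [
    "FeatureSet", "ArousalTrace", "LopoReport",
    "build_features", "z_normalize", "train_lopo", "estimate_trace",
    "FEATURE_ORDER",
]

#: fixed feature layout: blocks of 6 channels
FEATURE_ORDER = ("alpha_first", "theta_first", "alpha_second", "theta_second")
N_CHANNELS = 6
N_FEATURES = len(FEATURE_ORDER) * N_CHANNELS  # 24


@dataclass
class FeatureSet:
    """Time-indexed feature matrix for one participant/task (or a stack)."""

    times_s: np.ndarray
    values: np.ndarray  # (n_times, 24)
    participant_id: str | None = None
    labels: np.ndarray | None = None  # 1 = high arousal, 0 = low (training)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(f"features must be (n, {N_FEATURES})")


@dataclass
class ArousalTrace:
    """Per-second high/low decisions and their high-arousal portion."""

    times_s: np.ndarray
    decisions: np.ndarray  # 1 = high
    decision_values: np.ndarray | None = None

    @property
    def high_portion(self) -> float:
        return float(np.mean(self.decisions == 1))


@dataclass
class LopoReport:
    """Leave-one-person-out cross-validation outcome."""

    fold_participants: list
    fold_accuracies: np.ndarray
    model: SVC = field(repr=False, default=None)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def build_features(
    alpha_first: PowerTimeSeries,
    theta_first: PowerTimeSeries,
    alpha_second: PowerTimeSeries,
    theta_second: PowerTimeSeries,
    participant_id: str | None = None,
) -> FeatureSet:
    """Assemble 24-dim vectors on the common time support of the four series.

    The second-order series is shorter (130-s window formation), so vectors
    exist only where all four series have samples; times are matched on the
    1-s grid.
    """
    series = (alpha_first, theta_first, alpha_second, theta_second)
    for s in series:
        if s.n_channels != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} channels, got {s.n_channels}")
    grids = [np.round(s.times).astype(int) for s in series]
    common = grids[0]
    for g in grids[1:]:
        common = np.intersect1d(common, g)
    if common.size == 0:
        raise ValueError("series have no overlapping time support")
    blocks = []
    for s, g in zip(series, grids):
        sel = np.searchsorted(g, common)
        blocks.append(s.values[sel])  # (n_common, 6)
    values = np.concatenate(blocks, axis=1)
    return FeatureSet(common.astype(float), values, participant_id=participant_id)


def z_normalize(values: np.ndarray) -> np.ndarray:
    """Z-transform each feature dimension within its scope (mean 0, sd 1).

    The scope is whatever block is passed in — canonically one participant's
    task run. Zero-variance dimensions are flagged and passed through as
    zeros rather than dividing by zero.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("z-normalization needs at least 2 vectors")
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance feature dimension(s) set to 0",
            stacklevel=2,
        )
    sd = np.where(flat, 1.0, sd)
    out = (values - mean) / sd
    out[:, flat] = 0.0
    return out


def train_lopo(
    feature_sets,
    C: float = 1.0,
    gamma="scale",
    normalize: bool = True,
) -> LopoReport:
    """Train the Gaussian-kernel SVM with leave-one-person-out validation.

    ``feature_sets`` is an iterable of labeled :class:`FeatureSet`, one or
    more per participant. Each fold holds out every vector of one
    participant; the returned model is refit on all participants.
    """
    feature_sets = list(feature_sets)
    parts = sorted({fs.participant_id for fs in feature_sets})
    if len(parts) < 3:
        raise ValueError("leave-one-person-out needs at least 3 participants")
    X, y, groups = [], [], []
    for fs in feature_sets:
        if fs.labels is None:
            raise ValueError(f"feature set for {fs.participant_id} lacks labels")
        v = z_normalize(fs.values) if normalize else fs.values
        X.append(v)
        y.append(np.asarray(fs.labels, dtype=int))
        groups.append(np.full(len(v), parts.index(fs.participant_id)))
    X = np.concatenate(X)
    y = np.concatenate(y)
    groups = np.concatenate(groups)

    accs, held = [], []
    for train_idx, test_idx in LeaveOneGroupOut().split(X, y, groups):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a training fold contains a single class")
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
        clf.fit(X[train_idx], y[train_idx])
        accs.append(clf.score(X[test_idx], y[test_idx]))
        held.append(parts[int(groups[test_idx][0])])
    final = SVC(kernel="rbf", C=C, gamma=gamma).fit(X, y)
    return LopoReport(held, np.asarray(accs), final)


def estimate_trace(model: SVC, features: FeatureSet, normalize: bool = True) -> ArousalTrace:
    """Classify each second of a task run and report the high-arousal portion.

    Features must be normalized in the same scope convention used in
    training (per participant-task; the default applies it here).
    """
    v = z_normalize(features.values) if normalize else features.values
    if v.shape[1] != model.n_features_in_:
        raise ValueError(
            f"{v.shape[1]}-dim features for a {model.n_features_in_}-dim model"
        )
    decisions = model.predict(v)
    dvals = model.decision_function(v)
    return ArousalTrace(features.times_s, decisions, dvals)


def save_model(model: SVC, path, scope: str = "per-participant-task") -> None:
    """Serialize a trained arousal model as a versioned bundle."""
    import joblib

    joblib.dump({"format_version": 1, "n_features": int(model.n_features_in_),
                 "normalization_scope": scope, "model": model}, path)


def load_model(path) -> SVC:
    """Load a bundle written by :func:`save_model`."""
    import joblib

    bundle = joblib.load(path)
    if bundle.get("format_version") != 1:
        raise ValueError(f"unsupported model bundle version: {bundle.get('format_version')}")
    if bundle["n_features"] != N_FEATURES:
        raise ValueError("model bundle feature dimension mismatch")
    return bundle["model"]
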