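import numpy as np
import pytest

from cogload.arousal import (
    FeatureSet,
    build_features,
    estimate_trace,
    train_lopo,
    z_normalize,
)
from cogload.bandpower import ALPHA, THETA, PowerTimeSeries

CH6 = ("AF3", "AF4", "F3", "F4", "F7", "F8")

#: fixed separation direction in feature space
_DIRECTION = np.ones(24) / np.sqrt(24)


def cluster_sets(n_participants=8, separation_sd=4.0, n_per_class=30, seed=0):
    """Labeled feature sets: two Gaussian clusters per participant whose
    means sit ``separation_sd`` standard deviations apart."""
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_participants):
        offset = 0.3 * rng.standard_normal(24)
        lo = rng.standard_normal((n_per_class, 24)) + offset
        hi = rng.standard_normal((n_per_class, 24)) + offset + separation_sd * _DIRECTION
        values = np.vstack([lo, hi])
        labels = np.concatenate([np.zeros(n_per_class), np.ones(n_per_class)])
        times = np.arange(len(values), dtype=float)
        sets.append(FeatureSet(times, values, participant_id=f"P{i:02d}", labels=labels))
    return sets


def series(values, band=ALPHA, t0=0.0):
    return PowerTimeSeries(values, band, 1.0, t0, CH6)


class TestBuildFeatures:
    def test_common_support_and_dimension(self):
        rng = np.random.default_rng(1)
        a1 = series(rng.random((341, 6)))
        t1 = series(rng.random((341, 6)), THETA)
        a2 = series(rng.random((212, 6)))
        t2 = series(rng.random((212, 6)), THETA)
        feats = build_features(a1, t1, a2, t2)
        assert feats.values.shape == (212, 24)
        np.testing.assert_array_equal(feats.times_s, np.arange(212.0))

    def test_blocks_ordered_first_then_second(self):
        a1 = series(np.full((10, 6), 0.1))
        t1 = series(np.full((10, 6), 0.2), THETA)
        a2 = series(np.full((10, 6), 0.3))
        t2 = series(np.full((10, 6), 0.4), THETA)
        feats = build_features(a1, t1, a2, t2)
        np.testing.assert_allclose(feats.values[0], [0.1] * 6 + [0.2] * 6 + [0.3] * 6 + [0.4] * 6)

    def test_wrong_channel_count_rejected(self):
        bad = PowerTimeSeries(np.zeros((10, 5)), ALPHA, 1.0, 0.0, CH6[:5])
        good = series(np.zeros((10, 6)))
        with pytest.raises(ValueError, match="channels"):
            build_features(bad, good, good, good)

    def test_empty_overlap_rejected(self):
        a = series(np.zeros((10, 6)), t0=0.0)
        b = series(np.zeros((10, 6)), t0=100.0)
        with pytest.raises(ValueError, match="overlap"):
            build_features(a, a, b, b)


class TestZNormalize:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(2)
        out = z_normalize(rng.random((100, 24)) * 7 + 3)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        x = rng.random((50, 24))
        once = z_normalize(x)
        np.testing.assert_allclose(z_normalize(once), once, atol=1e-9)

    def test_constant_dimension_flagged_as_zeros(self):
        rng = np.random.default_rng(4)
        x = rng.random((50, 24))
        x[:, 7] = 2.5
        with pytest.warns(UserWarning, match="zero-variance"):
            out = z_normalize(x)
        np.testing.assert_array_equal(out[:, 7], 0.0)


class TestTrainLopo:
    def test_separated_clusters_high_accuracy(self):
        report = train_lopo(cluster_sets(separation_sd=4.0, seed=5))
        assert report.mean_accuracy >= 0.9
        assert len(report.fold_accuracies) == 8

    def test_folds_never_mix_participants(self):
        sets = cluster_sets(n_participants=5, seed=6)
        report = train_lopo(sets)
        assert sorted(report.fold_participants) == sorted(s.participant_id for s in sets)

    def test_accuracy_monotone_in_separation(self):
        accs = [train_lopo(cluster_sets(separation_sd=s, seed=7)).mean_accuracy
                for s in (1.0, 2.0, 4.0)]
        assert accs[0] <= accs[1] <= accs[2]

    def test_two_participants_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            train_lopo(cluster_sets(n_participants=2, seed=8))

    def test_single_class_fold_rejected(self):
        sets = cluster_sets(n_participants=3, seed=9)
        for s in sets:
            s.labels = np.ones_like(s.labels)
        with pytest.raises(ValueError, match="single class"):
            train_lopo(sets)


class TestEstimateTrace:
    def test_portion_recovery(self):
        model = train_lopo(cluster_sets(seed=10)).model
        errors = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n_hi = 70
            lo = rng.standard_normal((30, 24))
            hi = rng.standard_normal((n_hi, 24)) + 4.0 * _DIRECTION
            feats = FeatureSet(np.arange(100.0), np.vstack([lo, hi]))
            trace = estimate_trace(model, feats)
            errors.append(abs(trace.high_portion - 0.7))
        assert np.mean(errors) < 0.1

    def test_saturated_portions(self):
        # raw feature space on both sides: vectors deep inside one cluster
        model = train_lopo(cluster_sets(seed=11), normalize=False).model
        rng = np.random.default_rng(12)
        deep_hi = 0.2 * rng.standard_normal((50, 24)) + 5.0 * _DIRECTION
        deep_lo = 0.2 * rng.standard_normal((50, 24)) - 1.0 * _DIRECTION
        hi = FeatureSet(np.arange(50.0), deep_hi)
        lo = FeatureSet(np.arange(50.0), deep_lo)
        assert estimate_trace(model, hi, normalize=False).high_portion == 1.0
        assert estimate_trace(model, lo, normalize=False).high_portion == 0.0

    def test_order_invariance(self):
        model = train_lopo(cluster_sets(seed=13)).model
        rng = np.random.default_rng(14)
        x = rng.standard_normal((60, 24)) + 2.0 * _DIRECTION
        feats = FeatureSet(np.arange(60.0), x)
        perm = rng.permutation(60)
        shuffled = FeatureSet(np.arange(60.0), x[perm])
        d1 = estimate_trace(model, feats).decisions
        d2 = estimate_trace(model, shuffled).decisions
        np.testing.assert_array_equal(d1[perm], d2)

    def test_dimension_mismatch_rejected(self):
        model = train_lopo(cluster_sets(seed=15)).model
        bad = FeatureSet(np.arange(10.0), np.zeros((10, 24)))
        bad.values = np.zeros((10, 12))
        with pytest.raises(ValueError, match="dim"):
            estimate_trace(model, bad, normalize=False)


def test_model_bundle_round_trip(tmp_path):
    from cogload.arousal import load_model, save_model

    report = train_lopo(cluster_sets(seed=16))
    path = tmp_path / "arousal_model.joblib"
    save_model(report.model, path)
    loaded = load_model(path)
    rng = np.random.default_rng(17)
    x = z_normalize(rng.standard_normal((20, 24)))
    np.testing.assert_array_equal(loaded.predict(x), report.model.predict(x))
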