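"""Discriminability maps, interval selection, features, and LDA variants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from charstream.features import (
    DiscriminabilityMap,
    IntervalSet,
    balanced_accuracy,
    crossval_binary_accuracy,
    extract_features,
    fit_pipeline,
    score,
    select_intervals,
    signed_r2,
    train_shrinkage_lda,
    train_sparse_lda,
)
from charstream.preprocess import EpochSet


def _epochs_from_array(data, fs=100.0, labels=None, trials=None):
    n = data.shape[0]
    md = pd.DataFrame(
        {
            "trial": trials if trials is not None else np.zeros(n, int),
            "sample": np.arange(n) * 10,
            "symbol": ["A"] * n,
            "group": ["L"] * n,
            "iteration": np.zeros(n, int),
            "is_target": labels if labels is not None else np.zeros(n, int),
            "is_pretarget": np.zeros(n, bool),
            "is_posttarget": np.zeros(n, bool),
            "trial_target": ["A"] * n,
            "trial_target_group": ["L"] * n,
        }
    )
    window = (0.0, data.shape[2] * 1000.0 / fs)
    channels = tuple(f"ch{i}" for i in range(data.shape[1]))
    return EpochSet(data=data, window=window, fs=fs, channels=channels, metadata=md)


class TestSignedR2:
    def test_hand_computed_point_biserial(self):
        """Six observations checked against the direct correlation formula."""
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        data = vals[:, None, None]
        eset = _epochs_from_array(data, labels=y)
        dmap = signed_r2(eset)
        r = np.corrcoef(vals, y)[0, 1]
        assert dmap.values[0, 0] == pytest.approx(np.sign(r) * r**2, abs=1e-12)

    def test_identical_classes_give_zero(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(1, 2, 10))
        data = np.concatenate([base, base], axis=0)
        eset = _epochs_from_array(data, labels=np.array([0, 1]))
        dmap = signed_r2(eset)
        assert np.allclose(dmap.values, 0.0, atol=1e-12)

    def test_perfect_separation_is_unity(self):
        data = np.concatenate(
            [np.zeros((5, 1, 4)), np.ones((5, 1, 4))], axis=0
        )
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        dmap = signed_r2(_epochs_from_array(data, labels=y))
        assert np.allclose(np.abs(dmap.values), 1.0)

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(40, 3, 20))
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        eset = _epochs_from_array(data, labels=y)
        d1 = signed_r2(eset, y)
        d2 = signed_r2(eset, 1 - y)
        assert np.allclose(d1.values, -d2.values, atol=1e-12)

    def test_zero_variance_warns_and_zeroes(self):
        data = np.ones((6, 1, 3))
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning):
            dmap = signed_r2(_epochs_from_array(data, labels=y))
        assert np.allclose(dmap.values, 0.0)

    def test_single_class_rejected(self):
        data = np.zeros((4, 1, 3))
        with pytest.raises(ValueError):
            signed_r2(_epochs_from_array(data, labels=np.zeros(4, int)))


def _map_from_score(score_curve, fs=100.0):
    times = np.arange(len(score_curve)) * 1000.0 / fs - 1000.0
    return DiscriminabilityMap(
        values=np.asarray(score_curve)[None, :], channels=("ch0",), times=times
    )


class TestSelectIntervals:
    def test_single_bump_is_captured(self):
        times = np.arange(-1000, 1000, 10.0)
        curve = np.exp(-0.5 * ((times - 300) / 40) ** 2)
        dmap = DiscriminabilityMap(curve[None, :], ("ch0",), times)
        with pytest.warns(UserWarning):  # fewer than 3 plateaus exist
            intervals = select_intervals(dmap, n=3)
        assert any(t0 <= 300 < t1 for t0, t1 in intervals)

    def test_intervals_are_disjoint_and_bounded(self):
        rng = np.random.default_rng(5)
        times = np.arange(-1000, 1000, 10.0)
        curve = np.abs(rng.normal(size=times.size)) + 0.1
        dmap = DiscriminabilityMap(curve[None, :], ("ch0",), times)
        intervals = select_intervals(dmap, n=5)
        ivs = sorted(intervals)
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            assert a1 <= b0
        for t0, t1 in ivs:
            assert 30.0 - 1e-9 <= t1 - t0 <= 160.0

    def test_tie_breaks_to_earlier_interval(self):
        times = np.arange(-1000, 1000, 10.0)
        curve = np.zeros(times.size)
        for center in (-300, 400):  # two identical bumps
            curve += np.exp(-0.5 * ((times - center) / 40) ** 2)
        dmap = DiscriminabilityMap(curve[None, :], ("ch0",), times)
        with pytest.warns(UserWarning):
            intervals = select_intervals(dmap, n=3)
        first = sorted(intervals)[0]
        assert first[0] <= -300 < first[1]

    def test_invalid_count_rejected(self):
        dmap = _map_from_score(np.ones(100))
        with pytest.raises(ValueError):
            select_intervals(dmap, n=6)

    def test_overlapping_intervals_rejected_by_type(self):
        with pytest.raises(ValueError):
            IntervalSet(intervals=((0.0, 100.0), (50.0, 150.0)))


class TestExtractFeatures:
    def test_constant_epoch_gives_constant_features(self):
        data = np.ones((3, 4, 50))
        eset = _epochs_from_array(data, labels=np.array([0, 0, 1]))
        feats = extract_features(eset, IntervalSet(((0.0, 100.0), (200.0, 300.0))))
        assert np.allclose(feats, 1.0)

    def test_feature_dimension(self):
        data = np.zeros((2, 16, 200))
        eset = _epochs_from_array(data, labels=np.array([0, 1]))
        intervals = IntervalSet(tuple((i * 200.0, i * 200.0 + 100.0) for i in range(5)))
        assert extract_features(eset, intervals).shape == (2, 80)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(5, 3, 100))
        eset = _epochs_from_array(data, labels=np.array([0, 0, 0, 1, 1]))
        iv = (100.0, 250.0)
        feats = extract_features(eset, IntervalSet((iv,)))
        times = eset.times
        mask = (times >= iv[0]) & (times < iv[1])
        brute = data[:, :, mask].mean(axis=2)
        assert np.allclose(feats, brute)

    def test_empty_interval_rejected(self):
        data = np.zeros((2, 1, 10))
        eset = _epochs_from_array(data, labels=np.array([0, 1]))
        with pytest.raises(ValueError):
            extract_features(eset, IntervalSet(((5000.0, 5100.0),)))


class TestLda:
    def test_full_shrinkage_is_mean_difference(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 5))
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        model = train_shrinkage_lda(X, y, gamma=1.0)
        diff = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
        cos = diff @ model.w / np.linalg.norm(diff) / np.linalg.norm(model.w)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_recovers_closed_form_direction_at_large_n(self):
        """At n = 1e5 the shrinkage-LDA weights align with the population
        optimum within 2% angular error."""
        rng = np.random.default_rng(42)
        n = 100_000
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        delta = np.array([1.0, 0.5])
        L = np.linalg.cholesky(cov)
        X0 = rng.normal(size=(n // 2, 2)) @ L.T
        X1 = rng.normal(size=(n // 2, 2)) @ L.T + delta
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        model = train_shrinkage_lda(X, y)
        w_opt = np.linalg.solve(cov, delta)
        cos = model.w @ w_opt / np.linalg.norm(model.w) / np.linalg.norm(w_opt)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 0.02 * 90.0

    def test_sparse_limit_recovers_dense_direction(self):
        rng = np.random.default_rng(1)
        n = 4000
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(size=n) > 0).astype(int)
        dense = train_shrinkage_lda(X, y)
        sparse = train_sparse_lda(X, y, lam=1e-8)
        cos = dense.w @ sparse.w / np.linalg.norm(dense.w) / np.linalg.norm(sparse.w)
        assert cos > 0.99

    def test_huge_penalty_warns_all_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3))
        y = np.r_[np.zeros(25, int), np.ones(25, int)]
        with pytest.warns(UserWarning):
            model = train_sparse_lda(X, y, lam=1e6)
        assert not model.w.any()

    def test_positive_scores_mean_target(self):
        rng = np.random.default_rng(3)
        X0 = rng.normal(size=(200, 3))
        X1 = rng.normal(size=(200, 3)) + 2.0
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(200, int), np.ones(200, int)]
        model = train_shrinkage_lda(X, y)
        assert score(model, X[y == 1]).mean() > 0 > score(model, X[y == 0]).mean()

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 1000), st.floats(0.5, 5.0), st.floats(-3.0, 3.0))
    def test_score_order_invariant_to_feature_rescaling(self, seed, scale, shift):
        """LDA rankings survive channel-wise affine feature rescaling."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(80, 3))
        y = (X[:, 0] > 0).astype(int)
        m1 = train_shrinkage_lda(X, y, gamma=0.1)
        X2 = X * scale + shift
        m2 = train_shrinkage_lda(X2, y, gamma=0.1)
        r1 = np.argsort(score(m1, X))
        r2 = np.argsort(score(m2, X2))
        assert np.array_equal(r1, r2)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            train_shrinkage_lda(np.zeros((3, 2)), np.array([0, 1, 1]))


class TestCrossval:
    def test_chance_level_on_noise(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(600, 4, 40))
        y = rng.integers(0, 2, 600)
        trials = np.repeat(np.arange(10), 60)
        eset = _epochs_from_array(data, labels=y, trials=trials)
        acc = crossval_binary_accuracy(eset, k=5)
        assert abs(acc - 0.5) < 0.08

    def test_separable_data_is_perfect(self):
        rng = np.random.default_rng(4)
        y = np.tile([0, 1], 50)
        data = rng.normal(scale=0.05, size=(100, 2, 40))
        data[y == 1] += 5.0
        trials = np.repeat(np.arange(10), 10)
        eset = _epochs_from_array(data, labels=y, trials=trials)
        assert crossval_binary_accuracy(eset, k=5) == 1.0

    def test_interval_selection_inside_folds_prevents_leakage(self):
        """On pure-noise data, selecting intervals on the full set before
        CV inflates accuracy relative to the leakage-free path."""
        rng = np.random.default_rng(7)
        data = rng.normal(size=(400, 2, 60))
        y = rng.integers(0, 2, 400)
        trials = np.repeat(np.arange(8), 50)
        eset = _epochs_from_array(data, labels=y, trials=trials)
        honest = crossval_binary_accuracy(eset, k=4)

        from charstream.features import _blocked_folds, signed_r2, select_intervals

        dmap = signed_r2(eset, y)
        intervals = select_intervals(dmap, n=5)  # leaky: uses all data
        leaky_accs = []
        for tr, te in _blocked_folds(trials, y, 4):
            X_tr = extract_features(eset.subset(tr), intervals)
            X_te = extract_features(eset.subset(te), intervals)
            model = train_shrinkage_lda(X_tr, y[tr])
            pred = (score(model, X_te) > 0).astype(int)
            leaky_accs.append(balanced_accuracy(y[te], pred))
        # both hover near chance on noise; the leaky estimate must not be
        # systematically below the honest one (it peeks at the test data)
        assert np.mean(leaky_accs) >= honest - 0.05
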