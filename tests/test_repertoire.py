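"""Call-type classification and clustering: metrics, splits, selection,
classifiers, embedding, elbow."""

import numpy as np
import pandas as pd
import pytest

from zebrarep.cnn import CNNConfig, SmallCNN
from zebrarep.repertoire import (ClassificationReport, SplitSpec,
                                 choose_k_elbow, cluster_and_diagnose,
                                 downsample_matrix, embed_2d, evaluate,
                                 select_features_by_importance, split_indices,
                                 train_feature_classifier,
                                 train_spectrogram_classifier)
from zebrarep.specprep import MelParams, MelSpectrogram


def brute_force_report(true, pred, classes):
    """Independent oracle: metrics from explicitly counted confusion cells."""
    cm = {(t, p): 0 for t in classes for p in classes}
    for t, p in zip(true, pred):
        cm[(t, p)] += 1
    acc = sum(cm[(c, c)] for c in classes) / len(true)
    out = dict(accuracy=acc, precision={}, recall={}, f1={})
    for c in classes:
        tp = cm[(c, c)]
        fp = sum(cm[(o, c)] for o in classes if o != c)
        fn = sum(cm[(c, o)] for o in classes if o != c)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        out["precision"][c] = p
        out["recall"][c] = r
        out["f1"][c] = 2 * p * r / (p + r) if p + r else 0.0
    return out


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array(["a", "b", "a", "b"])
        rep = evaluate(y, y)
        assert rep.accuracy == 1.0
        assert all(v == 1.0 for v in rep.f1.values())

    def test_f1_harmonic_mean_formula(self):
        # class "a": precision 0.5 (1 TP, 1 FP), recall 1.0 -> f1 = 2/3
        true = np.array(["a", "b", "b"])
        pred = np.array(["a", "a", "b"])
        rep = evaluate(pred, true)
        assert rep.precision["a"] == 0.5
        assert rep.recall["a"] == 1.0
        assert rep.f1["a"] == pytest.approx(2 / 3)

    def test_matches_brute_force_oracle_on_random_labels(self, rng):
        classes = ["qq", "sn", "ss", "sq"]
        for _ in range(25):
            n = int(rng.integers(20, 80))
            true = rng.choice(classes, n)
            pred = rng.choice(classes, n)
            rep = evaluate(pred, true, classes=classes)
            oracle = brute_force_report(true, pred, classes)
            assert rep.accuracy == pytest.approx(oracle["accuracy"])
            for c in classes:
                assert rep.precision[c] == pytest.approx(oracle["precision"][c])
                assert rep.recall[c] == pytest.approx(oracle["recall"][c])
                assert rep.f1[c] == pytest.approx(oracle["f1"][c])

    def test_confusion_rows_sum_to_class_counts(self, rng):
        classes = ["a", "b", "c"]
        true = rng.choice(classes, 60)
        pred = rng.choice(classes, 60)
        rep = evaluate(pred, true, classes=classes)
        for i, c in enumerate(classes):
            assert rep.confusion_matrix[i].sum() == np.sum(true == c)
        assert rep.accuracy == np.trace(rep.confusion_matrix) / 60

    def test_empty_or_mismatched_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            evaluate(np.array(["a"]), np.array(["a", "b"]))


class TestSplits:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SplitSpec(0.7, 0.0, 0.2)

    def test_disjoint_covering_stratified(self, rng):
        labels = np.repeat(np.array(["a", "b", "c", "d"]), 50)
        tr, va, te = split_indices(labels, SplitSpec(0.49, 0.21, 0.30, seed=3))
        all_idx = np.concatenate([tr, va, te])
        assert len(set(all_idx)) == len(labels)
        for part, frac in ((tr, 0.49), (va, 0.21), (te, 0.30)):
            for c in "abcd":
                assert np.sum(labels[part] == c) == pytest.approx(
                    frac * 50, abs=1.01)


class TestFeatureSelection:
    def _single_signal_table(self, rng, n=200):
        y = rng.choice(["a", "b", "c", "d"], n)
        X = pd.DataFrame(rng.normal(size=(n, 4)),
                         columns=["noise1", "q50", "noise2", "noise3"])
        shift = {"a": 0.0, "b": 3.0, "c": 6.0, "d": 9.0}
        X["q50"] += np.array([shift[c] for c in y])
        return X, y

    def test_informative_feature_ranked_first(self, rng):
        X, y = self._single_signal_table(rng)
        _, scores = select_features_by_importance(X, y, threshold=0.0)
        assert scores.index[0] == "q50"

    def test_zero_threshold_keeps_all(self, rng):
        X, y = self._single_signal_table(rng)
        selected, _ = select_features_by_importance(X, y, threshold=0.0)
        assert set(selected) == set(X.columns)

    def test_unreachable_threshold_errors_with_advice(self, rng):
        X, y = self._single_signal_table(rng)
        with pytest.raises(ValueError, match="threshold"):
            select_features_by_importance(X, y, threshold=1e6)

    def test_missing_values_rejected(self, rng):
        X, y = self._single_signal_table(rng)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            select_features_by_importance(X, y)


def _blob_features(rng, n_per=60, spread=0.5):
    centers = np.array([[0, 0, 0], [8, 0, 0], [0, 8, 0], [0, 0, 8]])
    X = np.concatenate([c + spread * rng.standard_normal((n_per, 3))
                        for c in centers])
    y = np.repeat(["a", "b", "c", "d"], n_per)
    return pd.DataFrame(X, columns=["f1", "f2", "f3"]), y


class TestFeatureClassifier:
    def test_separable_classes_high_accuracy(self, rng):
        X, y = _blob_features(rng)
        m = train_feature_classifier(X, y, n_trials=3, seed=0)
        assert m.report.accuracy >= 0.9

    def test_shuffled_labels_drop_to_chance(self, rng):
        X, y = _blob_features(rng)
        y_shuf = rng.permutation(y)
        m = train_feature_classifier(X, y_shuf, n_trials=2, seed=0)
        n_test = m.report.confusion_matrix.sum()
        se = np.sqrt(0.25 * 0.75 / n_test)
        assert abs(m.report.accuracy - 0.25) <= 3 * se + 1e-9

    def test_single_class_rejected(self, rng):
        X, _ = _blob_features(rng, n_per=20)
        with pytest.raises(ValueError):
            train_feature_classifier(X, np.repeat("a", len(X)), n_trials=1)


def _blob_spectrograms(rng, n_per=30):
    specs, labels = [], []
    for c in range(4):
        for _ in range(n_per):
            m = np.full((32, 40), -80.0)
            m[c * 8:(c + 1) * 8, 5:30] = rng.uniform(-20, 0, (8, 25))
            specs.append(MelSpectrogram(m, MelParams(), 40))
            labels.append(f"t{c}")
    return specs, np.array(labels)


class TestSpectrogramClassifier:
    def test_separable_spectrograms_learned(self, rng):
        specs, labels = _blob_spectrograms(rng)
        cfg = CNNConfig(max_epochs=15, patience=5, seed=0)
        m = train_spectrogram_classifier(specs, labels, config=cfg, seed=0)
        assert m.report.accuracy >= 0.8

    def test_fixed_seed_is_deterministic(self, rng):
        specs, labels = _blob_spectrograms(rng, n_per=15)
        cfg = CNNConfig(max_epochs=4, patience=2, seed=1)
        r1 = train_spectrogram_classifier(specs, labels, config=cfg, seed=1)
        cfg2 = CNNConfig(max_epochs=4, patience=2, seed=1)
        r2 = train_spectrogram_classifier(specs, labels, config=cfg2, seed=1)
        assert r1.report.accuracy == r2.report.accuracy
        assert np.array_equal(r1.report.confusion_matrix, r2.report.confusion_matrix)

    def test_constant_inputs_stay_at_chance(self, rng):
        specs = [MelSpectrogram(np.full((32, 40), -30.0), MelParams(), 40)
                 for _ in range(80)]
        labels = np.array(["t0", "t1", "t2", "t3"] * 20)
        cfg = CNNConfig(max_epochs=3, patience=2, seed=0)
        m = train_spectrogram_classifier(specs, labels, config=cfg, seed=0)
        assert m.report.accuracy <= 0.5

    def test_shape_mismatch_rejected(self, rng):
        specs = [MelSpectrogram(np.zeros((32, 40)), MelParams(), 40),
                 MelSpectrogram(np.zeros((32, 41)), MelParams(), 41)]
        with pytest.raises(ValueError):
            train_spectrogram_classifier(specs, np.array(["a", "b"]))


def test_downsample_matrix_block_means():
    m = np.arange(16, dtype=float).reshape(4, 4)
    out = downsample_matrix(m, (2, 2))
    assert np.allclose(out, [[2.5, 4.5], [10.5, 12.5]])


class TestEmbedding:
    def test_two_blobs_remain_separable(self, rng):
        X = np.concatenate([rng.normal(0, 0.5, (40, 5)),
                            rng.normal(8, 0.5, (40, 5))])
        # neighborhood sized for the fixture, not the full-dataset defaults
        emb = embed_2d(X, n_neighbors=15, local_connectivity=1.0, seed=0)
        from sklearn.metrics import silhouette_score
        labels = np.repeat([0, 1], 40)
        assert silhouette_score(emb, labels) > 0.5

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            embed_2d(rng.normal(size=(5, 3)))

    def test_neighbor_clamping_warns(self, rng):
        X = rng.normal(size=(50, 3))
        with pytest.warns(UserWarning, match="clamped"):
            embed_2d(X, n_neighbors=200, seed=0)

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(size=(60, 4))
        e1 = embed_2d(X, seed=3)
        e2 = embed_2d(X, seed=3)
        assert np.allclose(e1, e2)


class TestClustering:
    def test_elbow_on_canonical_curves(self):
        # four well-separated blobs: huge drops to k=4, then flat
        assert choose_k_elbow([10000, 5000, 2500, 35, 30, 27, 25, 22]) == 4
        # single Gaussian blob: ~1/k decay never crosses the payoff bar
        assert choose_k_elbow([100, 66, 43, 34, 28, 23, 20, 17]) == 1
        assert choose_k_elbow([100.0]) == 1

    def test_four_blobs_select_k4(self, rng):
        X, _ = _blob_features(rng, n_per=40)
        res = cluster_and_diagnose(X.values, np.repeat(["a", "b", "c", "d"], 40),
                                   k_max=8, seed=0)
        assert res.k == 4
        assert np.all(np.diff(res.inertia_by_k) <= 1e-6)

    def test_identical_points_force_k1(self):
        pts = np.ones((30, 2))
        res = cluster_and_diagnose(pts, np.repeat(["a", "b", "c"], 10),
                                   k_max=5, seed=0)
        assert res.k == 1

    def test_type_cluster_rows_sum_to_one(self, rng):
        X, y = _blob_features(rng, n_per=30)
        res = cluster_and_diagnose(X.values, y, k_max=6, seed=0)
        assert np.allclose(res.type_cluster_matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_two_distant_blobs_within_between_disjoint(self, rng):
        pts = np.concatenate([rng.normal(0, 0.3, (40, 2)),
                              rng.normal(50, 0.3, (40, 2))])
        types = np.repeat(["x", "y"], 40)
        res = cluster_and_diagnose(pts, types, k_max=5, seed=0)
        assert res.overlap_coefficient < 0.05
        assert res.within_distances.max() < res.between_distances.min()

    def test_elbow_invariant_to_permutation(self, rng):
        X, y = _blob_features(rng, n_per=30)
        perm = rng.permutation(len(y))
        r1 = cluster_and_diagnose(X.values, y, k_max=6, seed=0)
        r2 = cluster_and_diagnose(X.values[perm], y[perm], k_max=6, seed=0)
        assert r1.k == r2.k
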