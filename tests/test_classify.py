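import numpy as np
import pytest

from effconn import classify
from effconn.classify import (
    EdgeScoreRecord,
    edge_labels,
    edge_scores,
    pooled_roc,
    tpr_at_fpr,
    train,
)


def make_gaussian_dataset(catalog, n_per_class, sep, n_features=20, seed=0):
    """Well-separated synthetic classes in feature space."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, sep, size=(len(catalog), n_features))
    X = np.vstack(
        [centers[k] + rng.standard_normal((n_per_class, n_features)) for k in range(len(catalog))]
    )
    y = np.repeat(np.arange(len(catalog)), n_per_class)
    return X, y


class TestTrain:
    def test_separable_classes_high_accuracy(self, catalog):
        X, y = make_gaussian_dataset(catalog, 24, sep=6.0)
        rng = np.random.default_rng(1)
        idx = rng.permutation(len(y))
        split = int(0.8 * len(y))
        tr, te = idx[:split], idx[split:]
        clf = train(X[tr], y[tr], catalog, c_grid=(1.0,), seed=0)
        pred = clf.predict_posterior(X[te]).argmax(axis=1)
        assert (pred == y[te]).mean() > 0.95

    def test_posterior_normalized(self, catalog):
        X, y = make_gaussian_dataset(catalog, 4, sep=2.0)
        clf = train(X, y, catalog, c_grid=(1.0,))
        post = clf.predict_posterior(X)
        assert np.allclose(post.sum(axis=1), 1.0)
        assert post.shape == (len(y), 25)

    def test_single_example_per_class_memorized(self, catalog):
        X, y = make_gaussian_dataset(catalog, 1, sep=8.0)
        clf = train(X, y, catalog, c_grid=(10.0,))
        pred = clf.predict_posterior(X).argmax(axis=1)
        assert (pred == y).all()

    def test_permuted_labels_chance_level(self, catalog):
        X, y = make_gaussian_dataset(catalog, 24, sep=6.0, seed=3)
        rng = np.random.default_rng(4)
        y_perm = rng.permutation(y)
        split = 500
        clf = train(X[:split], y_perm[:split], catalog, c_grid=(1.0,))
        acc = (clf.predict_posterior(X[split:]).argmax(axis=1) == y_perm[split:]).mean()
        assert acc < 0.12  # chance is 0.04

    def test_single_class_raises(self, catalog):
        X = np.zeros((10, 4))
        with pytest.raises(ValueError):
            train(X, np.zeros(10, dtype=int), catalog)

    def test_deterministic(self, catalog):
        X, y = make_gaussian_dataset(catalog, 6, sep=1.0, seed=9)
        a = train(X, y, catalog, seed=5)
        b = train(X, y, catalog, seed=5)
        assert np.allclose(a.model.coef_, b.model.coef_)


class TestEdgeScores:
    def test_empty_config_mass(self, catalog):
        post = np.zeros(25)
        post[0] = 1.0  # class 0 is the empty configuration
        assert np.allclose(edge_scores(post, catalog), 0.0)

    def test_chain_mass(self, catalog, chain_config):
        post = np.zeros(25)
        post[chain_config.class_index] = 1.0
        expected = np.array([1, 0, 0, 1, 0, 0], dtype=float)
        assert np.allclose(edge_scores(post, catalog), expected)

    def test_uniform_posterior_edge_fraction(self, catalog):
        # oracle: count catalog members containing each edge slot
        slots = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
        counts = np.array(
            [sum(cfg.A[i, j] for cfg in catalog) for i, j in slots], dtype=float
        )
        scores = edge_scores(np.full(25, 1 / 25), catalog)
        assert np.allclose(scores, counts / 25)

    def test_unnormalized_posterior_raises(self, catalog):
        with pytest.raises(ValueError):
            edge_scores(np.full(25, 0.1), catalog)

    def test_bounds_and_monotonicity(self, catalog, rng):
        for _ in range(20):
            w = rng.random(25)
            post = w / w.sum()
            s = edge_scores(post, catalog)
            assert np.all((s >= 0) & (s <= 1 + 1e-12))

    def test_edge_labels_order(self, chain_config):
        assert edge_labels(chain_config).tolist() == [1, 0, 0, 1, 0, 0]


def manual_auc(scores, labels):
    """Independent oracle: Mann-Whitney probability of correct ranking."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (len(pos) * len(neg))


class TestPooledRoc:
    def _records(self, scores, labels):
        return [
            EdgeScoreRecord(example_id=k, scores=s, labels=l)
            for k, (s, l) in enumerate(zip(scores.reshape(-1, 6), labels.reshape(-1, 6)))
        ]

    def test_perfect_scores(self, rng):
        labels = (rng.random(120) > 0.6).astype(int)
        labels[:6] = [1, 0, 1, 0, 1, 0]  # both classes guaranteed
        records = self._records(labels.astype(float), labels)
        curve = pooled_roc(records, n_bootstrap=0)
        assert curve.auc == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        labels = (rng.random(6000) > 0.65).astype(int)
        scores = rng.random(6000)
        curve = pooled_roc(self._records(scores, labels), n_bootstrap=0)
        assert curve.auc == pytest.approx(0.5, abs=0.03)

    def test_matches_mann_whitney_oracle(self, rng):
        labels = (rng.random(600) > 0.7).astype(int)
        labels[:6] = [1, 0, 1, 0, 1, 0]
        scores = rng.random(600) + 0.3 * labels
        curve = pooled_roc(self._records(scores, labels), n_bootstrap=0)
        assert curve.auc == pytest.approx(manual_auc(scores, labels), abs=1e-9)

    def test_auc_invariant_under_monotone_transform(self, rng):
        labels = (rng.random(300) > 0.5).astype(int)
        labels[:6] = [1, 0, 1, 0, 1, 0]
        scores = rng.random(300)
        a = pooled_roc(self._records(scores, labels), n_bootstrap=0).auc
        b = pooled_roc(self._records(np.tanh(3 * scores) + 2, labels), n_bootstrap=0).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_bootstrap_ci_positive(self, rng):
        labels = (rng.random(300) > 0.5).astype(int)
        labels[:6] = [1, 0, 1, 0, 1, 0]
        scores = rng.random(300) + labels
        curve = pooled_roc(self._records(scores, labels), n_bootstrap=100, seed=1)
        assert 0 < curve.auc_ci < 0.2

    def test_single_class_raises(self):
        records = self._records(np.random.rand(60), np.ones(60, dtype=int))
        with pytest.raises(ValueError):
            pooled_roc(records, n_bootstrap=0)

    def test_monotone_curve(self, rng):
        labels = (rng.random(600) > 0.5).astype(int)
        labels[:6] = [1, 0, 1, 0, 1, 0]
        scores = rng.random(600)
        curve = pooled_roc(self._records(scores, labels), n_bootstrap=0)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)


class TestTprAtFpr:
    def test_perfect(self, rng):
        labels = (rng.random(60) > 0.5).astype(int)
        labels[:6] = [1, 0, 1, 0, 1, 0]
        records = [
            EdgeScoreRecord(k, labels[6 * k : 6 * k + 6].astype(float), labels[6 * k : 6 * k + 6])
            for k in range(10)
        ]
        curve = pooled_roc(records, n_bootstrap=0)
        assert tpr_at_fpr(curve, 0.1) == pytest.approx(1.0)

    def test_chance(self):
        rng = np.random.default_rng(2)
        labels = (rng.random(12000) > 0.5).astype(int)
        scores = rng.random(12000)
        records = [
            EdgeScoreRecord(k, scores[6 * k : 6 * k + 6], labels[6 * k : 6 * k + 6])
            for k in range(2000)
        ]
        curve = pooled_roc(records, n_bootstrap=0)
        assert tpr_at_fpr(curve, 0.1) == pytest.approx(0.1, abs=0.03)


class TestModelSerialization:
    def test_json_round_trip_preserves_posteriors(self, catalog):
        X, y = make_gaussian_dataset(catalog, 4, sep=2.0)
        clf = train(X, y, catalog, c_grid=(1.0,))
        back = classify.TrainedClassifier.from_json(clf.to_json())
        assert np.allclose(back.predict_posterior(X[:5]), clf.predict_posterior(X[:5]))

    def test_newer_schema_rejected(self, catalog):
        import json

        X, y = make_gaussian_dataset(catalog, 2, sep=2.0)
        clf = train(X, y, catalog, c_grid=(1.0,))
        obj = json.loads(clf.to_json())
        obj["schema_version"] = 99
        with pytest.raises(ValueError, match="newer"):
            classify.TrainedClassifier.from_json(json.dumps(obj))


class TestCrossval:
    def _feature_dataset(self, catalog, n_per_class=10, seed=0):
        """Synthetic featurized dataset whose features encode the class."""
        from effconn.dataset import Dataset, Example, Timeseries

        rng = np.random.default_rng(seed)
        centers = rng.normal(0, 4.0, size=(25, 30))
        examples = []
        feats = []
        for config in catalog:
            for _ in range(n_per_class):
                ts = Timeseries(rng.standard_normal((3, 20)), 1.0, ("X", "Y", "Z"))
                examples.append(Example(ts, config))
                feats.append(centers[config.class_index] + rng.standard_normal(30))
        ds = Dataset(examples, "synthetic", catalog)
        return ds.with_features(np.vstack(feats), lag=1)

    def test_fold_arithmetic_and_auc(self, catalog):
        ds = self._feature_dataset(catalog)
        curve, folds = classify.crossval_evaluate(ds, folds=5, c_grid=(1.0,), seed=0, n_bootstrap=0)
        assert len(folds) == 5
        assert curve.n_pooled == 25 * 10 * 6
        assert curve.auc > 0.95  # separable by construction

    def test_deterministic_given_seed(self, catalog):
        ds = self._feature_dataset(catalog, n_per_class=6, seed=1)
        a, _ = classify.crossval_evaluate(ds, folds=3, c_grid=(1.0,), seed=7, n_bootstrap=0)
        b, _ = classify.crossval_evaluate(ds, folds=3, c_grid=(1.0,), seed=7, n_bootstrap=0)
        assert a.auc == b.auc

    def test_transfer_requires_matching_catalog(self, catalog):
        ds = self._feature_dataset(catalog, n_per_class=4)
        import effconn.graphs as graphs

        other = graphs.enumerate_dags(2)
        ds2 = self._feature_dataset(catalog, n_per_class=4)
        ds2.catalog = other
        with pytest.raises(ValueError):
            classify.transfer_evaluate(ds, ds2)
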