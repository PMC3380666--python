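import numpy as np
import pytest
from scipy.stats import binomtest

from gaborseg.classifiers import (classify, knn_neighbor_indices, mlp_forward,
                                  mlp_gradients, predict_knn, predict_proba,
                                  qg_discriminants, select_architecture, train_knn,
                                  train_mlp, train_qg, MLPModel)
from tests.conftest import make_free_dataset


class TestQuadraticGaussian:
    def test_symmetric_1d_boundary_at_zero(self):
        X = np.array([[-1.5], [-1.0], [-0.5], [0.5], [1.0], [1.5]])
        y = np.array([0, 0, 0, 1, 1, 1])
        m = train_qg(make_free_dataset(X, y))
        assert predict_proba(m, [[0.0]])[0] == pytest.approx(0.5, abs=1e-9)
        assert predict_proba(m, [[-0.2]])[0] < 0.5 < predict_proba(m, [[0.2]])[0]

    def test_discriminant_matches_closed_form(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-1, 1, (80, 5)), rng.normal(1, 2, (80, 5))])
        y = np.repeat([0, 1], 80)
        m = train_qg(make_free_dataset(X, y))
        probes = rng.normal(size=(20, 5))
        got = qg_discriminants(m, probes)
        # independent oracle: explicit inverse and determinant
        for i, x in enumerate(probes):
            for c in (0, 1):
                diff = x - m.means[c]
                sign, logdet = np.linalg.slogdet(m.covariances[c])
                expected = (np.log(m.priors[c]) - 0.5 * logdet
                            - 0.5 * diff @ np.linalg.inv(m.covariances[c]) @ diff)
                assert got[i, c] == pytest.approx(expected, abs=1e-10)

    def test_separated_gaussians_perfect_training_accuracy(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-10, 1, (50, 3)), rng.normal(10, 1, (50, 3))])
        y = np.repeat([0, 1], 50)
        m = train_qg(make_free_dataset(X, y))
        assert (classify(predict_proba(m, X)) == y).all()

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="D\\+1"):
            train_qg(make_free_dataset(np.zeros((4, 3)), [0, 0, 1, 1]))


class TestKNN:
    def test_query_on_training_point_k1(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(30, 4)), rng.integers(0, 2, 30)
        m = train_knn(make_free_dataset(X, y), k=1)
        np.testing.assert_array_equal(predict_knn(m, X), y)

    def test_neighbor_sets_match_exhaustive_oracle(self):
        from sklearn.neighbors import NearestNeighbors
        rng = np.random.default_rng(3)
        Xtr, ytr = rng.normal(size=(200, 15)), rng.integers(0, 2, 200)
        Xq = rng.normal(size=(50, 15))
        m = train_knn(make_free_dataset(Xtr, ytr), k=5)
        mine = knn_neighbor_indices(m, Xq)
        oracle = NearestNeighbors(n_neighbors=5, algorithm="brute").fit(Xtr)
        theirs = oracle.kneighbors(Xq, return_distance=False)
        for a, b in zip(mine, theirs):
            assert set(a) == set(b)

    def test_degenerate_k_equals_n(self):
        rng = np.random.default_rng(4)
        X, y = rng.normal(size=(20, 3)), rng.integers(0, 2, 20)
        m = train_knn(make_free_dataset(X, y), k=20)
        np.testing.assert_allclose(predict_knn(m, rng.normal(size=(7, 3))),
                                   y.mean())

    def test_distance_ties_break_to_lower_index(self):
        X = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], dtype=float)
        m = train_knn(make_free_dataset(X, [1, 0, 0, 1]), k=2)
        nbrs = knn_neighbor_indices(m, [[0.0, 0.0]])  # all equidistant
        np.testing.assert_array_equal(nbrs[0], [0, 1])

    def test_empty_or_bad_k(self):
        with pytest.raises(ValueError):
            train_knn(make_free_dataset(np.zeros((5, 2)), np.zeros(5)), k=9)


class TestMLP:
    def _toy(self, n=60, seed=5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 15))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        return make_free_dataset(X, y)

    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 15))
        y = rng.integers(0, 2, 10).astype(float)
        model = MLPModel(W1=rng.normal(scale=0.5, size=(15, 3)), b1=rng.normal(size=3),
                         W2=rng.normal(scale=0.5, size=(3, 1)), b2=rng.normal(size=1))

        def loss(m):
            p = np.clip(mlp_forward(m, X)[1], 1e-12, 1 - 1e-12)
            return float(-(y * np.log(p) + (1 - y) * np.log1p(-p)).mean())

        grads = mlp_gradients(model, X, y)
        eps = 1e-5  # central differences: truncation ~eps², round-off ~1e-16/eps
        for name in ("W1", "b1", "W2", "b2"):
            arr = getattr(model, name)
            fd = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = arr[i]
                arr[i] = orig + eps
                hi = loss(model)
                arr[i] = orig - eps
                lo = loss(model)
                arr[i] = orig
                fd[i] = (hi - lo) / (2 * eps)
            rel = np.abs(grads[name] - fd) / np.maximum(
                1e-8, np.abs(grads[name]) + np.abs(fd))
            assert rel.max() <= 1e-6

    def test_learns_linearly_separable_embedding(self):
        # 2 informative columns, 13 zero columns
        rng = np.random.default_rng(7)
        X = np.zeros((200, 15))
        X[:, :2] = rng.normal(size=(200, 2))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        ds = make_free_dataset(X, y)
        m = train_mlp(ds, ds, hidden=4, max_epochs=500, patience=500, seed=0)
        acc = (classify(predict_proba(m, X)) == y).mean()
        assert acc >= 0.99

    @pytest.mark.parametrize("h", [1, 0, 21])
    def test_hidden_range_enforced(self, h):
        ds = self._toy()
        with pytest.raises(ValueError, match=r"\[2, 20\]"):
            train_mlp(ds, ds, hidden=h, max_epochs=1)

    def test_bit_reproducible_given_seed(self):
        ds, val = self._toy(), self._toy(seed=8)
        a = train_mlp(ds, val, hidden=3, max_epochs=30, seed=11)
        b = train_mlp(ds, val, hidden=3, max_epochs=30, seed=11)
        for name in ("W1", "b1", "W2", "b2"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_best_validation_weights_kept(self):
        ds, val = self._toy(), self._toy(seed=9)
        m = train_mlp(ds, val, hidden=3, max_epochs=40, patience=5, seed=1)
        from gaborseg.classifiers import _bce
        assert _bce(mlp_forward(m, val.features.features)[1],
                    val.labels.astype(float)) == pytest.approx(m.record.best_val_error)
        assert m.record.best_epoch <= m.record.epochs_run

    def test_select_architecture(self):
        ds, val = self._toy(120), self._toy(60, seed=10)
        single = select_architecture(ds, val, h_grid=[4], max_epochs=10, seed=0)
        assert single.hidden == 4
        best = select_architecture(ds, val, h_grid=[3, 6], max_epochs=10, seed=0)
        cand = [train_mlp(ds, val, hidden=h, max_epochs=10, seed=0) for h in (3, 6)]
        assert best.record.best_val_error == min(c.record.best_val_error for c in cand)
        with pytest.raises(ValueError, match="empty"):
            select_architecture(ds, val, h_grid=[])


class TestCommonInterface:
    def test_dimension_mismatch_names_both(self):
        rng = np.random.default_rng(12)
        m = train_knn(make_free_dataset(rng.normal(size=(10, 4)),
                                        rng.integers(0, 2, 10)), k=1)
        with pytest.raises(ValueError, match="3.*4|4.*3"):
            predict_proba(m, np.zeros((2, 3)))

    def test_threshold_extremes(self):
        scores = np.array([0.0, 0.3, 1.0])
        assert classify(scores, 0.0).all()
        np.testing.assert_array_equal(classify(scores, 1.0), [False, False, True])

    def test_threshold_sweep_reproduces_roc_points(self):
        from gaborseg.evaluation import confusion, metrics, roc
        rng = np.random.default_rng(13)
        scores = rng.uniform(size=100)
        truth = rng.integers(0, 2, 100).astype(bool)
        curve = roc(scores, truth)
        for thr, fpr, tpr in list(zip(curve.thresholds, curve.fpr, curve.tpr))[1:]:
            sens, spec, _ = metrics(confusion(classify(scores, thr), truth))
            assert tpr == pytest.approx(sens, abs=1e-12)
            assert fpr == pytest.approx(1 - spec, abs=1e-12)

    def test_all_classifiers_beat_chance_on_phantoms(self, small_splits):
        train, val, test = small_splits
        n = min(2000, test.n)
        models = [train_qg(train), train_knn(train, k=5),
                  train_mlp(train, val, hidden=6, max_epochs=60, patience=10, seed=0)]
        for m in models:
            pred = classify(predict_proba(m, test.features.features[:n]))
            hits = int((pred == test.labels[:n].astype(bool)).sum())
            assert binomtest(hits, n, 0.5, alternative="greater").pvalue < 0.01
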