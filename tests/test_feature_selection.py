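"""Transfer rule, binarization, k-NN CV scoring and the BGLSMA wrapper."""

import numpy as np
import pytest

from slimeopt.datasets import ExpressionDataset, generate_expression_dataset
from slimeopt.feature_selection import (
    BGLSMASelector,
    FitnessWeights,
    _knn_error_on_folds,
    _make_folds,
    binarize,
    euclidean_distance,
    knn_cv_error,
    run_bglsma,
    subset_fitness,
    transfer,
)
from slimeopt.glsma import GLSMAConfig
from tests.conftest import ScriptedRNG


class TestTransfer:
    def test_values(self):
        assert transfer(0.0) == pytest.approx(0.5, abs=1e-12)
        assert transfer(1.0) == pytest.approx(1.0 / (1.0 + np.exp(-2.0)), abs=1e-12)

    def test_symmetry_and_monotonicity(self, rng):
        x = rng.normal(size=200)
        assert np.allclose(transfer(-x), 1.0 - transfer(x), atol=1e-12)
        xs = np.sort(x)
        assert np.all(np.diff(transfer(xs)) > 0)
        assert np.all((transfer(xs) > 0) & (transfer(xs) < 1))


class TestBinarize:
    def test_threshold_one_selects_everything(self):
        rng = ScriptedRNG([np.ones((2, 1))])
        bits = binarize(np.zeros((2, 3)), rng)
        assert bits.all()

    def test_threshold_zero_triggers_single_bit_repair(self):
        rng = ScriptedRNG([np.zeros((2, 1)), 1, 2])  # thresholds, repair indices
        bits = binarize(np.zeros((2, 3)), rng)
        assert np.array_equal(bits.sum(axis=1), [1, 1])
        assert bits[0, 1] and bits[1, 2]

    def test_zero_coordinate_selected_half_the_time(self):
        # column at x=0 -> selection probability T(0)=0.5; the companion
        # column at -4 keeps rows non-empty so the repair rule stays out.
        rng = np.random.default_rng(77)
        P = np.tile([0.0, -4.0], (100_000, 1))
        rate = binarize(P, rng)[:, 0].mean()
        assert abs(rate - 0.5) <= 3 * np.sqrt(0.25 / 100_000)

    def test_output_strictly_binary(self, rng):
        bits = binarize(rng.normal(size=(50, 20)), rng)
        assert bits.dtype == bool and set(np.unique(bits)) <= {False, True}


class TestDistance:
    def test_three_four_five(self):
        assert euclidean_distance([0, 0], [3, 4]) == 5.0
        assert euclidean_distance([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=10), rng.normal(size=10)
            brute = np.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))
            assert euclidean_distance(x, y) == pytest.approx(brute, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])


class TestKnnCvError:
    def _tiny(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1], [0.05], [5.05]])
        y = np.array([0, 0, 1, 1, 0, 1])
        return ExpressionDataset(matrix=X, labels=y, feature_names=["g0"])

    def test_hand_computed_nearest_neighbour(self):
        # Explicit fold: test {0, 2} against train {1, 3, 4, 5}; both test
        # points sit nearest a same-class neighbour -> error 0.
        data = self._tiny()
        folds = [(np.array([1, 3, 4, 5]), np.array([0, 2]))]
        err = _knn_error_on_folds(data.matrix, data.labels,
                                  np.array([True]), folds, k=1)
        assert err == 0.0

    def test_separable_fixture_zero_error(self):
        data = self._tiny()
        assert knn_cv_error(data, np.array([True]), folds=3, seed=0) == 0.0

    def test_matches_sklearn_on_fixed_folds(self, rng):
        # independent route: sklearn's estimator on the same partition
        from sklearn.neighbors import KNeighborsClassifier

        X = rng.normal(size=(40, 8))
        y = np.arange(40) % 2
        mask = np.array([True] * 5 + [False] * 3)
        folds = _make_folds(y, 5, seed=3)
        ours = _knn_error_on_folds(X, y, mask, folds, k=1)
        errs = []
        for tr, te in folds:
            clf = KNeighborsClassifier(n_neighbors=1).fit(X[np.ix_(tr, np.flatnonzero(mask))], y[tr])
            errs.append(np.sum(clf.predict(X[np.ix_(te, np.flatnonzero(mask))]) != y[te]))
        assert ours == pytest.approx(sum(errs) / 40, abs=1e-12)

    def test_feature_order_invariance(self, rng):
        X = rng.normal(size=(30, 10))
        y = np.arange(30) % 3
        data = ExpressionDataset(matrix=X, labels=y,
                                 feature_names=[f"g{i}" for i in range(10)])
        mask = np.zeros(10, dtype=bool)
        mask[[1, 4, 7]] = True
        perm = rng.permutation(10)
        data_p = ExpressionDataset(matrix=X[:, perm], labels=y,
                                   feature_names=[f"g{i}" for i in perm])
        assert knn_cv_error(data, mask, folds=5, seed=1) == knn_cv_error(
            data_p, mask[perm], folds=5, seed=1
        )

    def test_fold_reduction_warns_and_empty_mask_rejected(self):
        data = self._tiny()
        with pytest.warns(UserWarning, match="reducing folds"):
            knn_cv_error(data, np.array([True]), folds=10, seed=0)
        with pytest.raises(ValueError, match="no features"):
            knn_cv_error(data, np.array([False]), folds=3, seed=0)


class TestSubsetFitness:
    def test_printed_arithmetic(self):
        assert subset_fitness(0.0, 1, 2000) == pytest.approx(2.5e-5, rel=1e-12)
        assert subset_fitness(1.0, 2000, 2000) == pytest.approx(1.0, rel=1e-12)
        assert subset_fitness(0.1, 50, 2000) == pytest.approx(0.09625, rel=1e-12)

    def test_monotone_tradeoff(self):
        assert subset_fitness(0.1, 10, 100) < subset_fitness(0.1, 11, 100)
        assert subset_fitness(0.1, 10, 100) < subset_fitness(0.2, 10, 100)

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            FitnessWeights(0.9, 0.2)
        with pytest.raises(ValueError):
            subset_fitness(1.5, 1, 10)


class TestRunBglsma:
    def test_result_self_consistent_and_reproducible(self):
        data = generate_expression_dataset(
            n_samples=40, n_features=60, n_classes=2, n_informative=4,
            effect_size=4.0, seed=5,
        )
        cfg = GLSMAConfig(pop_size=10, max_evals=1500, seed=9)
        res = run_bglsma(data, cfg)
        assert res.n_selected == int(res.mask.sum()) >= 1
        refit = subset_fitness(
            knn_cv_error(data, res.mask, k=1, folds=res.folds, seed=res.seed),
            res.n_selected, data.n_features,
        )
        assert res.fitness == pytest.approx(refit, abs=1e-12)
        res2 = run_bglsma(data, cfg)
        assert np.array_equal(res.mask, res2.mask) and res.fitness == res2.fitness
        assert np.all(np.diff(res.trace) <= 0)

    def test_degenerate_data_rejected(self):
        X = np.ones((8, 3))
        one_class = ExpressionDataset(matrix=X, labels=np.zeros(8),
                                      feature_names=["a", "b", "c"])
        with pytest.raises(ValueError, match="2 classes"):
            run_bglsma(one_class, GLSMAConfig(pop_size=5, max_evals=200))


class TestSelectorEstimator:
    def test_sklearn_contract(self):
        data = generate_expression_dataset(
            n_samples=40, n_features=50, n_classes=2, n_informative=4,
            effect_size=4.0, seed=3,
        )
        sel = BGLSMASelector(pop_size=10, max_evals=1200, seed=0)
        Xt = sel.fit(data.matrix, data.labels).transform(data.matrix)
        assert Xt.shape == (40, sel.n_selected_)
        assert sel.get_support().sum() == sel.n_selected_
        assert sel.get_params()["max_evals"] == 1200
        # pipeline composition
        from sklearn.pipeline import Pipeline
        from sklearn.neighbors import KNeighborsClassifier

        pipe = Pipeline([
            ("select", BGLSMASelector(pop_size=8, max_evals=800, seed=1)),
            ("knn", KNeighborsClassifier(n_neighbors=1)),
        ]).fit(data.matrix, data.labels)
        assert pipe.score(data.matrix, data.labels) > 0.8
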