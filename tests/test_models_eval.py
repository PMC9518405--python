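"""Classifiers, PSO, metric arithmetic and the evaluation protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgwell import (
    ConfusionMatrix,
    PSOConfig,
    RFConfig,
    cross_validate,
    evaluate,
    pso_minimize,
    split_holdout,
    train_pso_svm,
    train_rf,
)
from ecgwell.models_eval import default_mtry, metrics_from_confusion
from ecgwell.errors import ConfigurationError, InvalidArgumentError


def _blobs(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal([-2, -2], 0.5, size=(n // 2, 2))
    X1 = rng.normal([2, 2], 0.5, size=(n // 2, 2))
    X = np.vstack([X0, X1])
    y = np.repeat([0, 1], n // 2)
    return X, y


class TestRandomForest:
    def test_separable_data_perfect_training_accuracy(self):
        X, y = _blobs()
        model = train_rf(X, y, RFConfig(n_trees=50, seed=0))
        assert np.mean(model.predict(X) == y) == 1.0

    def test_mtry_exceeding_feature_count_rejected(self):
        X, y = _blobs()
        with pytest.raises(ConfigurationError):
            train_rf(X, y, RFConfig(mtry=5))

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            train_rf(np.zeros((10, 3)), np.zeros(10))

    def test_seeded_determinism(self):
        X, y = _blobs()
        Xt = np.random.default_rng(5).normal(size=(20, 2))
        p1 = train_rf(X, y, RFConfig(n_trees=50, seed=3)).predict(Xt)
        p2 = train_rf(X, y, RFConfig(n_trees=50, seed=3)).predict(Xt)
        np.testing.assert_array_equal(p1, p2)

    def test_default_mtry_follows_protocol(self):
        assert default_mtry(184) == 12
        assert default_mtry(500) == 20
        assert default_mtry(100) == 10


class TestPSO:
    def test_sphere_function_reaches_corner_minimum(self):
        """Box [0.1,100]^2: minimum of sum(x^2) is 0.02 at the corner."""
        for seed in range(10):
            _, best, _ = pso_minimize(lambda p: float(np.sum(p**2)), PSOConfig(seed=seed))
            assert best <= 0.05

    def test_gbest_trace_monotone_nonincreasing(self):
        _, _, trace = pso_minimize(
            lambda p: float((p[0] - 50) ** 2 + (p[1] - 3) ** 2), PSOConfig(seed=1)
        )
        assert np.all(np.diff(trace) <= 0)

    def test_positions_respect_bounds(self):
        seen = []

        def objective(p):
            seen.append(p.copy())
            return float(np.sum(p**2))

        pso_minimize(objective, PSOConfig(seed=2, max_iters=30))
        arr = np.array(seen)
        assert np.all(arr >= 0.1 - 1e-12) and np.all(arr <= 100 + 1e-12)

    def test_single_particle_at_minimizer_stays(self):
        """pbest == gbest == start, so the velocity update stays zero."""
        cfg = PSOConfig(n_particles=1, max_iters=25, seed=0, bounds=((0.0, 4.0),))
        best, val, _ = pso_minimize(
            lambda p: float((p[0] - 2.0) ** 2), cfg, x0=np.array([[2.0]])
        )
        assert best[0] == pytest.approx(2.0, abs=1e-12)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            PSOConfig(bounds=((100.0, 0.1),))

    def test_nan_objective_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pso_minimize(lambda p: float("nan"), PSOConfig(seed=0, max_iters=2))


class TestPSOSVM:
    def test_rings_data_learned_by_rbf(self):
        rng = np.random.default_rng(0)
        n = 60
        r = np.concatenate([rng.uniform(0, 1, n), rng.uniform(2, 3, n)])
        theta = rng.uniform(0, 2 * np.pi, 2 * n)
        X = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        y = np.repeat([0, 1], n)
        cfg = PSOConfig(n_particles=6, max_iters=8, seed=0)
        model, (c, gamma) = train_pso_svm(X, y, cfg, cv_folds=3)
        assert 0.1 <= c <= 100 and 0.1 <= gamma <= 100
        assert np.mean(model.predict(X) == y) > 0.9

    def test_seeded_determinism(self):
        X, y = _blobs(40, seed=2)
        cfg = PSOConfig(n_particles=4, max_iters=4, seed=7)
        _, pair1 = train_pso_svm(X, y, cfg, cv_folds=3)
        _, pair2 = train_pso_svm(X, y, cfg, cv_folds=3)
        assert pair1 == pair2


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([0, 1] * 5)
        cm, rep = evaluate(y, y)
        assert (rep.rec, rep.pre, rep.f_score, rep.acc_percent) == (1, 1, 1, 100)
        assert cm.total == 10

    def test_all_positive_predictor_rec_one_pre_prevalence(self):
        actual = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        cm, rep = evaluate(np.ones(10, dtype=int), actual)
        assert rep.rec == 1.0
        assert rep.pre == pytest.approx(0.3)
        assert cm.fn == 0

    def test_worked_confusion_example(self):
        rep = metrics_from_confusion(ConfusionMatrix(tp=3, fp=1, fn=2, tn=4))
        assert rep.rec == pytest.approx(0.6)
        assert rep.pre == pytest.approx(0.75)
        assert rep.f_score == pytest.approx(2 * 0.6 * 0.75 / 1.35)
        assert rep.acc_percent == pytest.approx(70.0)

    def test_positive_class_configurable(self):
        pred = np.array([0, 0, 1, 1])
        act = np.array([0, 1, 1, 1])
        _, rep1 = evaluate(pred, act, positive=1)
        _, rep0 = evaluate(pred, act, positive=0)
        assert rep1.rec == pytest.approx(2 / 3)
        assert rep0.rec == pytest.approx(1.0)
        assert rep1.acc_percent == rep0.acc_percent  # ACC side-independent

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            evaluate([0, 1], [0, 1, 1])

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_metric_identities(self, tp, fp, fn, tn):
        rep = metrics_from_confusion(ConfusionMatrix(tp, fp, fn, tn))
        rec = tp / (tp + fn) if tp + fn else 0.0
        pre = tp / (tp + fp) if tp + fp else 0.0
        assert rep.rec == pytest.approx(rec)
        assert rep.pre == pytest.approx(pre)
        if rec + pre > 0:
            assert rep.f_score == pytest.approx(2 * rec * pre / (rec + pre))
        total = tp + fp + fn + tn
        if total:
            assert rep.acc_percent == pytest.approx(100 * (tp + tn) / total)


class TestSplitsAndCV:
    def test_stratified_holdout_counts(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 3590 + [1] * 2740)
        X = rng.normal(size=(len(y), 2))
        X_tr, X_te, y_tr, y_te = split_holdout(X, y, train_frac=0.70, seed=1)
        assert abs(np.sum(y_tr == 0) - 0.7 * 3590) <= 1
        assert abs(np.sum(y_tr == 1) - 0.7 * 2740) <= 1
        assert len(y_tr) + len(y_te) == len(y)

    def test_split_is_partition_and_deterministic(self):
        X = np.arange(40, dtype=float).reshape(-1, 1)
        y = np.repeat([0, 1], 20)
        a = split_holdout(X, y, seed=3)
        b = split_holdout(X, y, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        combined = np.sort(np.concatenate([a[0].ravel(), a[1].ravel()]))
        np.testing.assert_array_equal(combined, X.ravel())

    def test_tiny_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            split_holdout(np.zeros((5, 1)), np.array([0, 0, 0, 0, 1]))

    def test_cv_identity_model_perfect_score(self):
        class Memorizer:
            def fit(self, X, y):
                self.lookup = {tuple(row): lab for row, lab in zip(X, y)}
                return self

            def predict(self, X):
                return np.array([self.lookup.get(tuple(r), 0) for r in X])

        X = np.arange(60, dtype=float).reshape(-1, 1)
        y = np.repeat([0, 1], 30)

        class Oracle:  # predicts from the known rule, ignoring training data
            def fit(self, X, y):
                return self

            def predict(self, X):
                return (X.ravel() >= 30).astype(int)

        mean, reports = cross_validate(X, y, lambda s: Oracle(), seed=0)
        assert mean.acc_percent == 100.0
        assert len(reports) == 3

    def test_average_equals_mean_of_rounds_and_determinism(self):
        from sklearn.ensemble import RandomForestClassifier

        X, y = _blobs(60, seed=1)

        def factory(s):
            return RandomForestClassifier(n_estimators=20, random_state=s)

        mean1, reports1 = cross_validate(X, y, factory, seed=4)
        mean2, _ = cross_validate(X, y, factory, seed=4)
        assert mean1.acc_percent == pytest.approx(
            np.mean([r.acc_percent for r in reports1])
        )
        assert mean1 == mean2
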