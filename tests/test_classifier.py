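"""Softmax network: gradients, training behaviour, PSO search, CV ROC."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from cytodeep import (
    ClassifierConfig,
    LabelVector,
    MarkerTable,
    SoftmaxNetClassifier,
    crossvalidated_roc,
    predict_posteriors,
    train,
    tune_hyperparameters,
)
from cytodeep.classify import SearchSpace
from cytodeep import nnet


def _as_table(X):
    return MarkerTable(X, [f"m{j}" for j in range(X.shape[1])],
                       [f"c{i}" for i in range(X.shape[0])], transformed=True)


class TestGradients:
    @pytest.mark.parametrize("activation", ["softplus", "relu"])
    def test_analytic_gradient_matches_numerical(self, activation):
        """Backprop of the penalised cross-entropy agrees with finite differences."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 4))
        Y = np.eye(2)[[0, 1, 0]]
        params = nnet.init_params([4, 5, 3, 2], rng)
        if activation == "relu":
            # keep pre-activations away from the kink for finite differences
            params = [(W, b + 0.5) for W, b in params]
        lam = 0.01
        dropout = 0.3 if activation == "softplus" else 0.0

        def evaluate(need_grads=False):
            # fresh identically-seeded rng -> identical dropout masks, so the
            # objective is a deterministic function of the parameters
            return nnet.loss_and_grads(params, X, Y, lambda_l2=lam,
                                       activation=activation,
                                       dropout_rate=dropout,
                                       rng=np.random.default_rng(5))

        _, grads = evaluate()
        eps = 1e-6
        for li, (W, b) in enumerate(params):
            for arr, garr in ((W, grads[li][0]), (b, grads[li][1])):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    lp, _ = evaluate()
                    arr[idx] = orig - eps
                    lm, _ = evaluate()
                    arr[idx] = orig
                    numeric = (lp - lm) / (2 * eps)
                    assert numeric == pytest.approx(garr[idx], rel=1e-4, abs=1e-7)


class TestSoftmaxOutputs:
    def test_softmax_symmetry_and_log_ratio(self):
        probs = nnet.softmax(np.array([[0.0, 0.0], [np.log(2.0), 0.0]]))
        np.testing.assert_allclose(probs[0], [0.5, 0.5])
        np.testing.assert_allclose(probs[1], [2 / 3, 1 / 3])

    def test_posterior_rows_sum_to_one(self, separable_2pop):
        X, y = separable_2pop
        model = SoftmaxNetClassifier(hidden_sizes=(8,), epochs=10).fit(X, y)
        table = _as_table(np.linspace(-5, 15, 40)[:, None])
        post = predict_posteriors(model, table)
        np.testing.assert_allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)
        assert (post.argmax_labels == np.array(post.population_names, dtype=object)[
            np.argmax(post.probs, axis=1)]).all()


class TestTraining:
    def test_separable_data_reaches_perfect_training_accuracy(self, separable_2pop):
        """Matches a logistic-regression oracle on linearly separable data."""
        X, y = separable_2pop
        model = SoftmaxNetClassifier(hidden_sizes=(16,), epochs=30, batch_size=16,
                                     early_stopping=False, random_state=0).fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0
        oracle = LogisticRegression().fit(X, y)
        assert (oracle.predict(X) == y).mean() == 1.0

    def test_huge_l2_penalty_flattens_posteriors(self, separable_2pop):
        X, y = separable_2pop
        model = SoftmaxNetClassifier(hidden_sizes=(4,), epochs=200, batch_size=16,
                                     lambda_l2=1e6, early_stopping=False,
                                     random_state=0).fit(X, y)
        probs = model.predict_proba(X)
        np.testing.assert_allclose(probs, 0.5, atol=0.01)
        assert max(float(np.abs(W).max()) for W, _b in model.params_) < 1e-4

    def test_determinism_under_fixed_seed(self, separable_2pop):
        X, y = separable_2pop
        runs = [SoftmaxNetClassifier(hidden_sizes=(8,), epochs=15,
                                     random_state=3).fit(X, y) for _ in range(2)]
        assert runs[0].loss_curve_[-1] == runs[1].loss_curve_[-1]
        np.testing.assert_array_equal(runs[0].params_[0][0], runs[1].params_[0][0])

    def test_training_loss_decreases_on_average(self, separable_2pop):
        X, y = separable_2pop
        model = SoftmaxNetClassifier(hidden_sizes=(16,), epochs=40,
                                     early_stopping=False, random_state=0).fit(X, y)
        curve = np.array(model.loss_curve_)
        tail = max(2, len(curve) // 10)
        assert curve[-tail:].mean() <= curve[:tail].mean()

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        y = np.array(["a"] * 10)
        with pytest.raises(ValueError, match="2 populations"):
            SoftmaxNetClassifier().fit(X, y)

    def test_tiny_class_rejected(self):
        X = np.zeros((8, 2))
        y = np.array(["a"] * 6 + ["b"] * 2, dtype=object)
        with pytest.raises(ValueError, match="need >= 5"):
            SoftmaxNetClassifier().fit(X, y)

    def test_marker_count_mismatch_rejected(self, separable_2pop):
        X, y = separable_2pop
        model = SoftmaxNetClassifier(hidden_sizes=(4,), epochs=5).fit(X, y)
        with pytest.raises(ValueError, match="markers"):
            model.predict_proba(np.zeros((3, 7)))

    def test_train_requires_transformed_table(self, separable_2pop):
        X, y = separable_2pop
        table = MarkerTable(np.abs(X), ["m0"], [f"c{i}" for i in range(len(X))],
                            transformed=False)
        labels = LabelVector(y, population_names=["a", "b"])
        with pytest.raises(ValueError, match="transformed"):
            train(table, labels)

    def test_heldout_accuracy_on_six_sigma_benchmark(self, small_cohort):
        _specs, table, observed, truth = small_cohort
        config = ClassifierConfig(hidden_sizes=(32, 16), epochs=60,
                                  batch_size=64, seed=0)
        model = train(table, observed, config)
        held_out = ~observed.labeled_mask & np.isin(
            truth.labels.astype(str), [str(c) for c in model.classes_])
        pred = model.predict(table.values[held_out])
        assert (pred == truth.labels[held_out].astype(str)).mean() >= 0.99


@pytest.fixture(scope="module")
def tiny_problem():
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(0, 1, (60, 2)), rng.normal(6, 1, (60, 2))])
    y = np.array(["a"] * 60 + ["b"] * 60, dtype=object)
    return _as_table(X), LabelVector(y, population_names=["a", "b"])


class TestHyperparameterSearch:
    def _space(self, **kw):
        fixed = {"epochs": 8, "batch_size": 32}
        return SearchSpace(base_hidden_sizes=(8, 4), fixed=fixed, **kw)

    def test_single_point_space_returns_that_point(self, tiny_problem):
        table, labels = tiny_problem
        space = self._space(n_layers=(1, 1), log10_lambda=(-3.0, -3.0),
                            dropout_rate=(0.1, 0.1))
        config = tune_hyperparameters(table, labels, space, swarm_size=3,
                                      iterations=2, seed=0)
        assert config.hidden_sizes == (8,)
        assert config.lambda_l2 == pytest.approx(1e-3)
        assert config.dropout_rate == pytest.approx(0.1)

    def test_winner_at_least_as_good_as_worst_evaluated(self, tiny_problem):
        table, labels = tiny_problem
        space = self._space(n_layers=(1, 2), log10_lambda=(-4.0, 0.0),
                            dropout_rate=(0.0, 0.4))
        best, history = tune_hyperparameters(table, labels, space, swarm_size=4,
                                             iterations=2, seed=1,
                                             return_history=True)
        scores = [s for _c, s in history]
        best_score = max(s for c, s in history if c == best)
        assert best_score >= min(scores)
        assert best_score == max(scores)

    def test_empty_space_rejected(self, tiny_problem):
        table, labels = tiny_problem
        space = self._space(n_layers=(2, 1))
        with pytest.raises(ValueError, match="empty"):
            tune_hyperparameters(table, labels, space, seed=0)


class TestCrossvalidatedRoc:
    def test_separable_data_gives_unit_areas(self, small_cohort):
        _specs, table, observed, _truth = small_cohort
        config = ClassifierConfig(hidden_sizes=(16,), epochs=60,
                                  batch_size=32, seed=0)
        result = crossvalidated_roc(table, observed, config, folds=4)
        assert all(a > 0.999 for a in result["per_class"].values())
        assert result["mean"] > 0.999

    def test_shuffled_labels_give_chance_area(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(600, 3))
        y = np.array(["a", "b"] * 300, dtype=object)
        table = _as_table(X)
        labels = LabelVector(y, population_names=["a", "b"])
        config = ClassifierConfig(hidden_sizes=(8,), epochs=10, seed=0)
        result = crossvalidated_roc(table, labels, config, folds=4)
        assert result["mean"] == pytest.approx(0.5, abs=0.07)

    def test_single_fold_rejected(self, small_cohort):
        _specs, table, observed, _ = small_cohort
        with pytest.raises(ValueError, match="folds"):
            crossvalidated_roc(table, observed, folds=1)
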