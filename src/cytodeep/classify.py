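"""Supervised identification of canonical populations by a softmax network.

A feed-forward net with softmax output assigns each cell a posterior over
the K gated populations.  The estimator follows scikit-learn conventions
(``fit`` / ``predict_proba`` / ``get_params``), so it composes with sklearn
pipelines and model selection; module-level helpers adapt it to the
package's MarkerTable/LabelVector containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import nnet
from .io import UNASSIGNED, LabelVector, MarkerTable
from .metrics import roc_curve_area

DEFAULT_HIDDEN_SIZES = (128, 64, 32)


class SoftmaxNetClassifier(BaseEstimator, ClassifierMixin):
    """Feed-forward softmax classifier trained by mini-batch Adam.

    Parameters
    ----------
    hidden_sizes : tuple of int, default (128, 64, 32)
        Hidden-layer widths.
    activation : {"relu", "softplus"}
        Hidden-layer nonlinearity.
    lambda_l2 : float
        L2 penalty strength on weight matrices (biases excluded).
    learning_rate, batch_size, epochs, dropout_rate
        Optimisation settings; dropout uses inverted scaling at train time.
        ``epochs=None`` (default) budgets enough epochs for at least 2,000
        optimizer steps (clamped to [100, 1000] epochs), so small gated
        cohorts are not silently undertrained at the large default batch
        size; early stopping usually ends training well before the budget.
    early_stopping : bool
        Hold out ``validation_fraction`` of the training cells (stratified)
        and stop after ``patience`` epochs without validation-loss
        improvement, restoring the best parameters.
    random_state : int
        Seeds initialisation, shuffling, dropout and the validation split.

    Attributes
    ----------
    classes_ : ndarray of population names, in lexicographic order
    params_ : list of (W, b) per layer
    loss_curve_ : per-epoch training loss (penalised cross-entropy)
    """

    def __init__(self, hidden_sizes=DEFAULT_HIDDEN_SIZES, activation="relu",
                 lambda_l2=1e-4, learning_rate=1e-3, batch_size=256, epochs=None,
                 dropout_rate=0.0, early_stopping=True, validation_fraction=0.1,
                 patience=10, random_state=0):
        self.hidden_sizes = hidden_sizes
        self.activation = activation
        self.lambda_l2 = lambda_l2
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout_rate = dropout_rate
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if len(self.hidden_sizes) < 1:
            raise ValueError("at least one hidden layer is required")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("training requires at least 2 populations")
        counts = np.bincount(y_idx)
        if counts.min() < 5:
            small = self.classes_[int(np.argmin(counts))]
            raise ValueError(
                f"population {small!r} has only {counts.min()} labeled cells (need >= 5)"
            )
        self.n_features_in_ = X.shape[1]

        rng = np.random.default_rng(self.random_state)
        sizes = [X.shape[1], *self.hidden_sizes, n_classes]
        params = nnet.init_params(sizes, rng)

        X_val = y_val = None
        if self.early_stopping and self.validation_fraction > 0:
            # stratified holdout; falls back to no holdout for tiny classes
            try:
                X, X_val, y_idx, y_val = train_test_split(
                    X, y_idx, test_size=self.validation_fraction,
                    stratify=y_idx,
                    random_state=int(rng.integers(2**31 - 1)),
                )
            except ValueError:
                X_val = None

        onehot = np.eye(n_classes)
        optimizer = nnet.Adam(params, learning_rate=self.learning_rate)
        n = X.shape[0]
        n_batches = max(1, int(np.ceil(n / self.batch_size)))
        if self.epochs is None:
            # budget at least ~2000 optimizer steps regardless of cohort size
            epoch_budget = int(np.clip(np.ceil(2000 / n_batches), 100, 1000))
        else:
            epoch_budget = self.epochs
        # patience counts epochs, but an epoch can be very few optimizer
        # steps on a small cohort; wait for >= ~500 stalled steps so slowly
        # learned rare populations are not abandoned
        patience = max(self.patience, int(np.ceil(500 / n_batches)))
        best_val, best_params, stall = np.inf, params, 0
        self.loss_curve_ = []
        for epoch in range(epoch_budget):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                batch = order[start:start + self.batch_size]
                loss, grads = nnet.loss_and_grads(
                    params, X[batch], onehot[y_idx[batch]],
                    lambda_l2=self.lambda_l2, activation=self.activation,
                    dropout_rate=self.dropout_rate, rng=rng,
                )
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite training loss at epoch {epoch}")
                params = optimizer.step(params, grads)
                epoch_loss += loss * len(batch)
            self.loss_curve_.append(epoch_loss / n)

            if X_val is not None:
                probs, _ = nnet.forward(params, X_val, self.activation)
                val_loss = -np.mean(
                    np.log(probs[np.arange(len(y_val)), y_val] + 1e-12)
                )
                if val_loss < best_val - 1e-6:
                    best_val, best_params, stall = val_loss, params, 0
                else:
                    stall += 1
                    if stall >= patience:
                        params = best_params
                        break
            else:
                best_params = params
        else:
            if X_val is not None:
                params = best_params
        self.params_ = params
        self.n_epochs_ = len(self.loss_curve_)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} markers, model expects {self.n_features_in_}"
            )
        probs, _ = nnet.forward(self.params_, X, self.activation)
        return probs

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


@dataclass(frozen=True)
class ClassifierConfig:
    """Bag of training hyperparameters mirroring SoftmaxNetClassifier."""

    hidden_sizes: tuple = DEFAULT_HIDDEN_SIZES
    activation: str = "relu"
    lambda_l2: float = 1e-4
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int | None = None  # None -> step-budgeted epoch count
    dropout_rate: float = 0.0
    seed: int = 0

    def make_estimator(self) -> SoftmaxNetClassifier:
        return SoftmaxNetClassifier(
            hidden_sizes=tuple(self.hidden_sizes), activation=self.activation,
            lambda_l2=self.lambda_l2, learning_rate=self.learning_rate,
            batch_size=self.batch_size, epochs=self.epochs,
            dropout_rate=self.dropout_rate, random_state=self.seed,
        )


@dataclass(frozen=True)
class PosteriorMatrix:
    """Per-cell class probabilities; rows sum to one."""

    probs: np.ndarray
    population_names: list[str]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[1] != len(self.population_names):
            raise ValueError("probs shape incompatible with population names")
        if probs.size and (
            (probs < -1e-9).any() or (probs > 1 + 1e-9).any()
            or not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        ):
            raise ValueError("rows must be probability vectors summing to 1")

    @property
    def max_posterior(self) -> np.ndarray:
        return self.probs.max(axis=1)

    @property
    def argmax_labels(self) -> np.ndarray:
        names = np.array(self.population_names, dtype=object)
        return names[np.argmax(self.probs, axis=1)]


def train(table: MarkerTable, labels: LabelVector,
          config: ClassifierConfig | None = None) -> SoftmaxNetClassifier:
    """Train the softmax net on the labeled (non-UNASSIGNED) cells."""
    if not table.transformed:
        raise ValueError("train expects an arcsinh-transformed table")
    config = config or ClassifierConfig()
    mask = labels.labeled_mask
    model = config.make_estimator()
    model.fit(table.values[mask], labels.labels[mask].astype(str))
    return model


def predict_posteriors(model: SoftmaxNetClassifier, table: MarkerTable) -> PosteriorMatrix:
    """Apply the trained net to every cell of the table."""
    probs = model.predict_proba(table.values)
    return PosteriorMatrix(probs=probs, population_names=[str(c) for c in model.classes_])


# ---------------------------------------------------------------------------
# Hyperparameter search: global-best particle swarm over (depth, lambda, dropout)
# ---------------------------------------------------------------------------

#: Standard constriction coefficients (inertia, cognitive, social).
PSO_INERTIA, PSO_COGNITIVE, PSO_SOCIAL = 0.72, 1.49, 1.49


@dataclass
class SearchSpace:
    """Box bounds for the swarm; depth counts hidden layers kept from the base."""

    n_layers: tuple[int, int] = (1, 3)
    log10_lambda: tuple[float, float] = (-5.0, -1.0)
    dropout_rate: tuple[float, float] = (0.0, 0.5)
    base_hidden_sizes: tuple = DEFAULT_HIDDEN_SIZES
    fixed: dict = field(default_factory=dict)  # passthrough ClassifierConfig fields

    def bounds(self) -> np.ndarray:
        return np.array([self.n_layers, self.log10_lambda, self.dropout_rate],
                        dtype=float)

    def to_config(self, position: np.ndarray, seed: int) -> ClassifierConfig:
        depth = int(round(position[0]))
        return ClassifierConfig(
            hidden_sizes=tuple(self.base_hidden_sizes[:depth]),
            lambda_l2=float(10.0 ** position[1]),
            dropout_rate=float(position[2]),
            seed=seed,
            **self.fixed,
        )


def _validation_roc(table: MarkerTable, labels: LabelVector,
                    config: ClassifierConfig, seed: int) -> float:
    """Half/half stratified split; macro-average one-vs-rest ROC area."""
    mask = labels.labeled_mask
    X, y = table.values[mask], labels.labels[mask].astype(str)
    X_tr, X_va, y_tr, y_va = train_test_split(
        X, y, test_size=0.5, stratify=y, random_state=seed)
    model = config.make_estimator().fit(X_tr, y_tr)
    probs = model.predict_proba(X_va)
    areas = []
    for j, cls in enumerate(model.classes_):
        truth = (y_va == cls).astype(int)
        if truth.min() == truth.max():
            continue
        areas.append(roc_curve_area(probs[:, j], truth))
    return float(np.mean(areas)) if areas else 0.5


def tune_hyperparameters(
    table: MarkerTable,
    labels: LabelVector,
    search_space: SearchSpace | None = None,
    swarm_size: int = 8,
    iterations: int = 5,
    seed: int = 0,
    return_history: bool = False,
):
    """Global-best PSO maximising validation macro one-vs-rest ROC area.

    Velocity update is the canonical inertia + cognitive + social rule;
    positions are clipped to the box and the depth dimension is rounded.
    Ties break toward the first-evaluated configuration.  With
    ``return_history`` the (config, score) pairs of every evaluation are
    returned alongside the winner.
    """
    space = search_space or SearchSpace()
    bounds = space.bounds()
    lo, hi = bounds[:, 0], bounds[:, 1]
    if (hi < lo).any():
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    dim = len(lo)
    pos = rng.uniform(lo, hi, size=(swarm_size, dim))
    vel = rng.uniform(-(hi - lo), hi - lo, size=(swarm_size, dim)) * 0.1

    history: list[tuple[ClassifierConfig, float]] = []

    def evaluate(p: np.ndarray) -> float:
        config = space.to_config(p, seed=seed)
        score = _validation_roc(table, labels, config, seed=seed)
        history.append((config, score))
        return score

    pbest = pos.copy()
    pbest_score = np.array([evaluate(p) for p in pos])
    g = int(np.argmax(pbest_score))  # argmax takes the first on ties
    gbest, gbest_score = pbest[g].copy(), pbest_score[g]

    single_point = np.allclose(lo, hi)
    if not single_point:
        for _ in range(iterations):
            r1 = rng.random((swarm_size, dim))
            r2 = rng.random((swarm_size, dim))
            vel = (PSO_INERTIA * vel
                   + PSO_COGNITIVE * r1 * (pbest - pos)
                   + PSO_SOCIAL * r2 * (gbest - pos))
            pos = np.clip(pos + vel, lo, hi)
            for i in range(swarm_size):
                score = evaluate(pos[i])
                if score > pbest_score[i]:
                    pbest[i], pbest_score[i] = pos[i].copy(), score
                    if score > gbest_score:
                        gbest, gbest_score = pos[i].copy(), score
    best = space.to_config(gbest, seed=seed)
    return (best, history) if return_history else best


def crossvalidated_roc(
    table: MarkerTable,
    labels: LabelVector,
    config: ClassifierConfig | None = None,
    folds: int = 4,
) -> dict:
    """Stratified k-fold one-vs-rest ROC areas per population, plus the mean.

    A class absent from a fold's test split gets NaN for that fold and is
    excluded from its per-class average with a warning.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    config = config or ClassifierConfig()
    mask = labels.labeled_mask
    X, y = table.values[mask], labels.labels[mask].astype(str)
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    per_class: dict[str, list[float]] = {c: [] for c in classes}
    for train_idx, test_idx in skf.split(X, y):
        model = config.make_estimator().fit(X[train_idx], y[train_idx])
        probs = model.predict_proba(X[test_idx])
        col = {c: j for j, c in enumerate(model.classes_)}
        for c in classes:
            truth = (y[test_idx] == c).astype(int)
            if truth.min() == truth.max() or c not in col:
                warnings.warn(f"population {c!r} missing from a fold; ROC undefined")
                continue
            per_class[c].append(roc_curve_area(probs[:, col[c]], truth))
    areas = {c: (float(np.mean(v)) if v else float("nan"))
             for c, v in per_class.items()}
    valid = [a for a in areas.values() if np.isfinite(a)]
    return {"per_class": areas, "mean": float(np.mean(valid)) if valid else float("nan")}
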