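"""Origin classifiers: kernel SVM on precomputed Gram matrices, MLP and RF.

All three are scikit-learn-style estimators (``fit`` / ``predict`` /
``predict_scores``, ``get_params`` / ``set_params``) so they compose with
pipelines and model selection.  ``predict_scores`` always returns one finite
score column per training class, aligned with ``classes_`` — the contract the
metric and permutation-importance layers rely on.

The SVM consumes Gram matrices built by :mod:`chemorigin.kernels`; features
are z-scored on the training split by default because the 70 components span
four orders of magnitude in units (% down to μg/g) and the Gaussian width
range σ² ∈ [10, 50] is only meaningful on a standardized scale.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .kernels import KernelSpec, gram
from .synthesis import ChemTable

__all__ = [
    "KernelSVC",
    "MLPOriginClassifier",
    "ForestOriginClassifier",
    "train_svm",
    "train_bpnn",
    "train_rf",
    "predict",
]

# Published tuning ranges for the two baseline models
BPNN_RANGES = {"hidden_layers": (1, 5), "neurons_per_layer": (2, 40),
               "learning_rate": (0.001, 0.1)}
RF_RANGES = {"n_trees": (50, 200), "min_samples_leaf": (2, 10)}


class _StandardizeMixin:
    def _fit_scaler(self, X: np.ndarray) -> np.ndarray:
        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            return self.scaler_.transform(X)
        self.scaler_ = None
        return X

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with {self.n_features_in_}")
        return self.scaler_.transform(X) if self.scaler_ is not None else X


class KernelSVC(_StandardizeMixin, ClassifierMixin, BaseEstimator):
    """Soft-margin multiclass SVM on a precomputed kernel Gram matrix.

    Parameters
    ----------
    kernel_spec : KernelSpec
        Kernel family and parameters (see :mod:`chemorigin.kernels`).
    C : float, default 1.0
        Soft-margin regularization constant (applied per binary subproblem).
    multiclass : {'one-vs-one', 'one-vs-rest'}, default 'one-vs-one'
        Binary decomposition scheme.  One-vs-one uses pairwise voting with
        OvR-shaped decision values; one-vs-rest trains one machine per class.
    standardize : bool, default True
        z-score features using statistics of the training split only.
    """

    def __init__(self, kernel_spec: KernelSpec | None = None, C: float = 1.0,
                 multiclass: str = "one-vs-one", standardize: bool = True):
        self.kernel_spec = kernel_spec
        self.C = C
        self.multiclass = multiclass
        self.standardize = standardize

    def _spec(self) -> KernelSpec:
        return self.kernel_spec if self.kernel_spec is not None else KernelSpec()

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not self.C > 0:
            raise ValueError("C must be positive")
        if self.multiclass not in ("one-vs-one", "one-vs-rest"):
            raise ValueError(f"unknown multiclass scheme {self.multiclass!r}")
        if np.unique(y).size < 2:
            raise ValueError("training data must contain at least two classes")
        self.n_features_in_ = X.shape[1]
        Xs = self._fit_scaler(X)
        self.X_train_ = Xs
        G = gram(Xs, Xs, self._spec())
        if self.multiclass == "one-vs-one":
            self.estimator_ = SVC(kernel="precomputed", C=self.C,
                                  decision_function_shape="ovr")
        else:
            self.estimator_ = OneVsRestClassifier(SVC(kernel="precomputed", C=self.C))
        self.estimator_.fit(G, y)
        self.classes_ = self.estimator_.classes_
        self.class_support_ = {c: int((y == c).sum()) for c in self.classes_}
        return self

    def _gram_to_train(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return gram(self._transform(X), self.X_train_, self._spec())

    def predict(self, X):
        return self.estimator_.predict(self._gram_to_train(X))

    def decision_function(self, X):
        scores = self.estimator_.decision_function(self._gram_to_train(X))
        if scores.ndim == 1:  # binary: expand to one column per class
            scores = np.column_stack([-scores, scores])
        return scores

    def predict_scores(self, X):
        return self.decision_function(X)


class MLPOriginClassifier(_StandardizeMixin, ClassifierMixin, BaseEstimator):
    """Backpropagation MLP baseline with the published tuning ranges enforced.

    Hidden layers in [1, 5], neurons per layer in [2, 40], learning rate in
    [0.001, 0.1].  Internals follow conventional defaults: rectified-linear
    activations, Adam, early stopping on a 10 % validation carve-out, at most
    ``max_epochs`` epochs.  Deterministic under ``seed``.
    """

    def __init__(self, hidden_layers: int = 3, neurons_per_layer: int = 31,
                 learning_rate: float = 0.001, max_epochs: int = 500,
                 activation: str = "relu", early_stopping: bool = True,
                 standardize: bool = True, seed: int = 0):
        self.hidden_layers = hidden_layers
        self.neurons_per_layer = neurons_per_layer
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.activation = activation
        self.early_stopping = early_stopping
        self.standardize = standardize
        self.seed = seed

    def fit(self, X, y):
        for name in BPNN_RANGES:
            lo, hi = BPNN_RANGES[name]
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside allowed range [{lo}, {hi}]")
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        Xs = self._fit_scaler(X)
        self.estimator_ = MLPClassifier(
            hidden_layer_sizes=(int(self.neurons_per_layer),) * int(self.hidden_layers),
            learning_rate_init=self.learning_rate, activation=self.activation,
            max_iter=self.max_epochs, early_stopping=self.early_stopping,
            validation_fraction=0.1, random_state=self.seed,
        )
        self.estimator_.fit(Xs, y)
        self.classes_ = self.estimator_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(self._transform(X))

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(self._transform(X))

    def predict_scores(self, X):
        return self.predict_proba(X)


class ForestOriginClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest baseline with the published tuning ranges enforced.

    Trees in [50, 200], minimum samples per leaf in [2, 10]; scale-invariant,
    so no standardization is applied.  Deterministic under ``seed``.
    """

    def __init__(self, n_trees: int = 151, min_samples_leaf: int = 2, seed: int = 0):
        self.n_trees = n_trees
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed

    def fit(self, X, y):
        for name in RF_RANGES:
            lo, hi = RF_RANGES[name]
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside allowed range [{lo}, {hi}]")
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.estimator_ = RandomForestClassifier(
            n_estimators=int(self.n_trees),
            min_samples_leaf=int(self.min_samples_leaf),
            random_state=self.seed,
        )
        self.estimator_.fit(X, y)
        self.classes_ = self.estimator_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(np.asarray(X, dtype=float))

    def predict_scores(self, X):
        return self.predict_proba(X)


# -- ChemTable-level wrappers -------------------------------------------------

def _check_classes(y: np.ndarray, expected_classes) -> None:
    if expected_classes is not None:
        missing = sorted(set(expected_classes) - set(y))
        if missing:
            raise ValueError(f"classes absent from training data: {missing}")


def train_svm(table: ChemTable, kernel_spec: KernelSpec | None = None, *,
              C: float = 1.0, multiclass: str = "one-vs-one",
              standardize: bool = True, group_by: str = "region",
              expected_classes=None) -> KernelSVC:
    y = table.labels(group_by)
    _check_classes(y, expected_classes)
    return KernelSVC(kernel_spec=kernel_spec, C=C, multiclass=multiclass,
                     standardize=standardize).fit(table.values, y)


def train_bpnn(table: ChemTable, *, hidden_layers: int = 3,
               neurons_per_layer: int = 31, learning_rate: float = 0.001,
               seed: int = 0, group_by: str = "region",
               expected_classes=None, **kwargs) -> MLPOriginClassifier:
    y = table.labels(group_by)
    _check_classes(y, expected_classes)
    model = MLPOriginClassifier(hidden_layers=hidden_layers,
                                neurons_per_layer=neurons_per_layer,
                                learning_rate=learning_rate, seed=seed, **kwargs)
    return model.fit(table.values, y)


def train_rf(table: ChemTable, *, n_trees: int = 151, min_samples_leaf: int = 2,
             seed: int = 0, group_by: str = "region",
             expected_classes=None) -> ForestOriginClassifier:
    y = table.labels(group_by)
    _check_classes(y, expected_classes)
    model = ForestOriginClassifier(n_trees=n_trees,
                                   min_samples_leaf=min_samples_leaf, seed=seed)
    return model.fit(table.values, y)


def predict(model, table: ChemTable) -> tuple[np.ndarray, np.ndarray]:
    """Labels plus per-class score matrix for an evaluation table."""
    labels = model.predict(table.values)
    scores = model.predict_scores(table.values)
    if not np.all(np.isfinite(scores)):
        raise ValueError("score matrix contains non-finite entries")
    return labels, scores
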