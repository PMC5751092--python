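"""Extreme learning machine and multilayer perceptron classifiers.

Both are single-hidden-layer feedforward networks with logistic-sigmoid
hidden units, presented as scikit-learn estimators.

The ELM draws its input weights and biases uniformly from (-1, 1) under a
seed and solves the hidden-to-output weights in closed form through the
Moore-Penrose pseudoinverse of the hidden-layer output matrix — training is
non-iterative.  The number of hidden neurons ``L`` may not exceed the
number of training samples ``N``; at ``L = N`` the network interpolates the
training targets exactly.  Targets are coded {-1, +1} with decision
threshold 0.

The MLP trains the same architecture iteratively with full-batch
backpropagation (cross-entropy loss, constant learning rate, classical
momentum, optional early stopping on a held-out validation split).  Its
sigmoid output is thresholded at 0.5.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

__all__ = ["ELMClassifier", "MLPClassifier", "select_hidden_neurons"]


def _binary_classes(y) -> np.ndarray:
    classes = unique_labels(y)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes.size}")
    return classes


class ELMClassifier(BaseEstimator, ClassifierMixin):
    """Extreme learning machine for binary classification.

    Parameters
    ----------
    n_hidden : int
        Number of hidden neurons ``L``; must satisfy ``L <= N`` at fit time.
    random_state : int or None
        Seed of the random input weights; the hidden layers of two fits
        sharing a seed are prefix-nested across different ``n_hidden``.
    class_weight : {"balanced", None}
        "balanced" solves a weighted least-squares problem giving both
        classes equal total weight.
    alpha : float
        Optional ridge term on the output weights (0 = plain pseudoinverse).
    rcond : float
        Relative singular-value cutoff of the pseudoinverse.
    """

    def __init__(self, n_hidden: int = 100, random_state: int | None = None,
                 class_weight: str | None = None, alpha: float = 0.0,
                 rcond: float = 1e-10):
        self.n_hidden = n_hidden
        self.random_state = random_state
        self.class_weight = class_weight
        self.alpha = alpha
        self.rcond = rcond

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        n, d = X.shape
        if self.n_hidden > n:
            raise ValueError(
                f"n_hidden={self.n_hidden} exceeds the {n} training samples "
                "(the model requires L <= N)")
        self.classes_ = _binary_classes(y)
        t = np.where(y == self.classes_[1], 1.0, -1.0)

        rng = np.random.default_rng(self.random_state)
        # one draw per hidden unit keeps hidden layers prefix-nested in L
        ab = rng.uniform(-1.0, 1.0, size=(self.n_hidden, d + 1))
        self.input_weights_ = ab[:, :d]
        self.biases_ = ab[:, d]

        H = expit(X @ self.input_weights_.T + self.biases_)
        if self.class_weight == "balanced":
            w = np.where(t > 0, n / (2.0 * np.sum(t > 0)),
                         n / (2.0 * np.sum(t < 0)))
            sw = np.sqrt(w)
            H_solve, t_solve = H * sw[:, None], t * sw
        elif self.class_weight is None:
            H_solve, t_solve = H, t
        else:
            raise ValueError(f"unknown class_weight {self.class_weight!r}")

        if self.alpha > 0:
            A = H_solve.T @ H_solve + self.alpha * np.eye(self.n_hidden)
            self.output_weights_ = np.linalg.solve(A, H_solve.T @ t_solve)
        else:
            self.output_weights_ = np.linalg.lstsq(
                H_solve, t_solve, rcond=self.rcond)[0]
        self.n_features_in_ = d
        return self

    def decision_function(self, X):
        check_is_fitted(self, "output_weights_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        H = expit(X @ self.input_weights_.T + self.biases_)
        return H @ self.output_weights_

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[(scores >= 0).astype(int)]


class MLPClassifier(BaseEstimator, ClassifierMixin):
    """Single-hidden-layer perceptron trained by full-batch backpropagation.

    Hidden and output units are logistic sigmoids; the scalar output is
    thresholded at 0.5.  Training minimizes cross-entropy with a constant
    learning rate and classical momentum.  When ``validation_fraction > 0``
    and the training set is large enough (>= 10 samples), a held-out split
    drives early stopping with the given patience; otherwise all samples are
    used for the gradient and training runs for ``max_epochs``.
    """

    def __init__(self, n_hidden: int = 10, learning_rate: float = 0.01,
                 momentum: float = 0.9, max_epochs: int = 500,
                 patience: int = 20, validation_fraction: float = 0.1,
                 random_state: int | None = None):
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = _binary_classes(y)
        t = (y == self.classes_[1]).astype(float)
        n, d = X.shape
        q = self.n_hidden
        rng = np.random.default_rng(self.random_state)

        use_val = self.validation_fraction > 0 and n >= 10
        if use_val:
            n_val = max(1, int(round(self.validation_fraction * n)))
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            Xtr, ttr = X[tr_idx], t[tr_idx]
            Xval, tval = X[val_idx], t[val_idx]
        else:
            Xtr, ttr = X, t

        scale = np.sqrt(6.0 / (d + q))
        W1 = rng.uniform(-scale, scale, size=(d, q))
        th1 = np.zeros(q)
        W2 = rng.uniform(-scale, scale, size=q)
        th2 = 0.0
        vW1 = np.zeros_like(W1); vth1 = np.zeros_like(th1)
        vW2 = np.zeros_like(W2); vth2 = 0.0

        def forward(A, w1, o1, w2, o2):
            Z = expit(A @ w1 - o1)
            return Z, expit(Z @ w2 - o2)

        best = (W1.copy(), th1.copy(), W2.copy(), th2)
        best_loss = np.inf
        stall = 0
        m = Xtr.shape[0]
        for epoch_i in range(self.max_epochs):
            Z, out = forward(Xtr, W1, th1, W2, th2)
            delta2 = (out - ttr) / m                 # dL/d(pre-activation)
            gW2 = Z.T @ delta2
            gth2 = -delta2.sum()
            delta1 = np.outer(delta2, W2) * Z * (1.0 - Z)
            gW1 = Xtr.T @ delta1
            gth1 = -delta1.sum(axis=0)

            vW1 = self.momentum * vW1 - self.learning_rate * gW1
            vth1 = self.momentum * vth1 - self.learning_rate * gth1
            vW2 = self.momentum * vW2 - self.learning_rate * gW2
            vth2 = self.momentum * vth2 - self.learning_rate * gth2
            W1 += vW1; th1 += vth1; W2 += vW2; th2 += vth2

            if use_val:
                _, vout = forward(Xval, W1, th1, W2, th2)
                eps = 1e-12
                loss = -np.mean(tval * np.log(vout + eps)
                                + (1 - tval) * np.log(1 - vout + eps))
                if loss < best_loss - 1e-6:
                    best_loss = loss
                    best = (W1.copy(), th1.copy(), W2.copy(), th2)
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if use_val and np.isfinite(best_loss):
            W1, th1, W2, th2 = best

        self.hidden_weights_ = W1
        self.hidden_onsets_ = th1
        self.output_weights_ = W2
        self.output_onset_ = th2
        self.n_features_in_ = d
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "hidden_weights_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        Z = expit(X @ self.hidden_weights_ - self.hidden_onsets_)
        p1 = expit(Z @ self.output_weights_ - self.output_onset_)
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1] - 0.5

    def predict(self, X):
        p1 = self.predict_proba(X)[:, 1]
        return self.classes_[(p1 >= 0.5).astype(int)]


def make_classifier(kind: str, n_hidden: int, seed: int | None,
                    class_weight: str | None = "balanced",
                    **kwargs):
    """Factory shared by the cascade and the selection wrapper."""
    if kind == "elm":
        return ELMClassifier(n_hidden=n_hidden, random_state=seed,
                             class_weight=class_weight, **kwargs)
    if kind == "mlp":
        return MLPClassifier(n_hidden=n_hidden, random_state=seed, **kwargs)
    raise ValueError(f"unknown classifier kind {kind!r}")


def select_hidden_neurons(X, y, grid, classifier_kind: str = "elm",
                          seed: int | None = 0, n_splits: int = 5,
                          **classifier_kwargs) -> int:
    """Pick the hidden-neuron count with minimal mean 5-fold CV error.

    Folds are stratified by class; ties break to the smaller count.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid of hidden-neuron counts is empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    best_count, best_err = None, np.inf
    for count in sorted(grid):
        errs = []
        for tr, te in cv.split(X, y):
            clf = make_classifier(classifier_kind,
                                  min(count, tr.size), seed,
                                  **classifier_kwargs)
            clf.fit(X[tr], y[tr])
            errs.append(np.mean(clf.predict(X[te]) != y[te]))
        err = float(np.mean(errs))
        if err < best_err:                 # strict: ties keep smaller count
            best_err = err
            best_count = count
    return best_count
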