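"""Single-hidden-layer perceptron trained against soft class targets.

This is the posterior-probability model behind the Fisher-Information
metric: a feed-forward network with one tanh hidden layer (default 6
units) and a softmax output, trained by full-batch gradient descent with
momentum and an L2 weight-decay penalty, against *soft* targets -- the
voxel-level class proportions produced by label voting.  Training stops
once the mean per-example cross-entropy drops below ``error_tol`` or at
``max_epochs``.

The estimator follows scikit-learn conventions (``get_params``/
``set_params``, ``fit``/``predict_proba``, trailing-underscore fitted
attributes) and additionally exposes exact analytic input gradients of
the class posteriors, which the Fisher metric needs.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SoftLabelMLP(ClassifierMixin, BaseEstimator):
    """MLP posterior model p(c | spectrum) trained on soft targets.

    Parameters
    ----------
    hidden_units : int, default 6
        Size of the single tanh hidden layer.
    learning_rate : float, default 0.05
        Step size of full-batch gradient descent (on the mean loss).
    momentum : float, default 0.9
        Classical momentum coefficient.
    weight_decay : float, default 0.01
        Coefficient of the L2 penalty on the weight matrices (biases
        excluded), added to the cross-entropy loss.
    max_epochs : int, default 2000
        Epoch cap.
    error_tol : float, default 5e-3
        Stop once the mean per-example cross-entropy falls below this.
    init_scale : float, default 1.0
        Initial weights and biases drawn uniformly from
        ``[-init_scale, init_scale]``.
    random_state : int or None
        Seed for the weight initialisation.
    """

    def __init__(
        self,
        hidden_units: int = 6,
        learning_rate: float = 0.05,
        momentum: float = 0.9,
        weight_decay: float = 0.01,
        max_epochs: int = 2000,
        error_tol: float = 5e-3,
        init_scale: float = 1.0,
        random_state: int | None = None,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.error_tol = error_tol
        self.init_scale = init_scale
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _as_soft_targets(self, y, n_samples: int) -> np.ndarray:
        y = np.asarray(y)
        if y.ndim == 1:  # hard labels -> one-hot
            self.classes_ = np.unique(y)
            onehot = (y[:, None] == self.classes_[None, :]).astype(float)
            return onehot
        if y.shape[0] != n_samples:
            raise ValueError("X and y have inconsistent sample counts")
        if np.any(y < 0) or np.any(np.abs(y.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("soft targets must be rows on the probability simplex")
        self.classes_ = np.arange(1, y.shape[1] + 1)
        return y.astype(float)

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on spectra ``X`` (n_samples x n_features) and targets ``y``.

        ``y`` may be hard labels (1-D) or a simplex-valued soft-target
        matrix (n_samples x n_classes).  An optional held-out set is
        scored after training into ``validation_loss_`` /
        ``validation_accuracy_``.
        """
        X = check_array(X, dtype=float)
        Y = self._as_soft_targets(y, X.shape[0])
        if np.any(Y.sum(axis=0) == 0):
            raise ValueError("every class needs at least one training example")
        n, d = X.shape
        c = Y.shape[1]
        h = self.hidden_units
        rng = np.random.default_rng(self.random_state)
        s = self.init_scale
        W1 = rng.uniform(-s, s, (h, d))
        b1 = rng.uniform(-s, s, h)
        W2 = rng.uniform(-s, s, (c, h))
        b2 = rng.uniform(-s, s, c)
        vel = [np.zeros_like(p) for p in (W1, b1, W2, b2)]

        self.loss_curve_ = []
        lam, lr, mom = self.weight_decay, self.learning_rate, self.momentum
        for epoch in range(self.max_epochs):
            with np.errstate(over="ignore", invalid="ignore"):
                A = np.tanh(X @ W1.T + b1)      # n x h
                P = _softmax(A @ W2.T + b2)     # n x c
                ce = -np.sum(Y * np.log(np.maximum(P, 1e-300))) / n
                if not np.isfinite(ce):
                    raise DivergenceError(epoch)
                self.loss_curve_.append(ce)
                if ce < self.error_tol:
                    break
                dZ2 = (P - Y) / n                # n x c
                gW2 = dZ2.T @ A + 2 * lam * W2
                gb2 = dZ2.sum(axis=0)
                dA = (dZ2 @ W2) * (1.0 - A**2)   # n x h
                gW1 = dA.T @ X + 2 * lam * W1
                gb1 = dA.sum(axis=0)
                for p, v, g in zip((W1, b1, W2, b2), vel, (gW1, gb1, gW2, gb2)):
                    v *= mom
                    v -= lr * g
                    p += v

        self.coef_hidden_, self.intercept_hidden_ = W1, b1
        self.coef_output_, self.intercept_output_ = W2, b2
        self.n_features_in_ = d
        self.n_iter_ = len(self.loss_curve_)
        self.final_loss_ = self.loss_curve_[-1]
        if X_val is not None:
            Pv = self.predict_proba(X_val)
            Yv = np.asarray(y_val, dtype=float)
            if Yv.ndim == 1:
                Yv = (Yv[:, None] == self.classes_[None, :]).astype(float)
            self.validation_loss_ = float(
                -np.mean(np.sum(Yv * np.log(np.maximum(Pv, 1e-300)), axis=1))
            )
            self.validation_accuracy_ = float(
                np.mean(Pv.argmax(axis=1) == Yv.argmax(axis=1))
            )
        return self

    # ------------------------------------------------------------------

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = np.tanh(X @ self.coef_hidden_.T + self.intercept_hidden_)
        P = _softmax(A @ self.coef_output_.T + self.intercept_output_)
        return A, P

    def predict_proba(self, X) -> np.ndarray:
        """Class posteriors; rows sum to one."""
        check_is_fitted(self, "coef_hidden_")
        X = check_array(np.atleast_2d(X), dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self._forward(X)[1]

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def input_gradients(self, X) -> np.ndarray:
        """Exact gradients d p_c / d x, shape (n_samples, n_classes, n_features).

        Because the posteriors live on the simplex, the gradients of all
        classes at a point sum to the zero vector.
        """
        check_is_fitted(self, "coef_hidden_")
        X = check_array(np.atleast_2d(X), dtype=float)
        A, P = self._forward(X)
        # dz/dx per sample: (c x h) @ diag(1-a^2) @ (h x d)
        JZ = np.einsum("ch,nh,hd->ncd", self.coef_output_, 1.0 - A**2, self.coef_hidden_)
        # softmax Jacobian: dp_c/dz_j = p_c (delta_cj - p_j)
        return P[:, :, None] * (JZ - np.einsum("nj,njd->nd", P, JZ)[:, None, :])
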