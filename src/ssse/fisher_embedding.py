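"""Fisher-Information metric and Euclidean embedding of spectra.

A trained posterior model p(c | x) induces a Riemannian metric on the
data space, the Fisher-Information (FI) metric

    J(x) = sum_c p(c|x) grad log p(c|x) grad log p(c|x)^T,

which stretches directions along which class membership changes and
collapses directions the classifier is indifferent to.  Pairwise
distances under this metric are approximated by dividing the straight
segment between two spectra into ``n_segments`` pieces and summing
``sqrt(delta^T J(m_t) delta)`` at the segment midpoints.

Classical multidimensional scaling (double-centring of the squared
distances followed by an eigendecomposition) then maps the spectra into
a Euclidean space that preserves this distance structure, where
convexity-constrained factorisation applies.

Arrays here follow the scikit-learn orientation: rows are voxels/samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .mlp import SoftLabelMLP

PROB_FLOOR = 1e-12


class DegenerateEmbeddingError(ValueError):
    """The distance matrix admits no positive-eigenvalue MDS axis."""


def train_mlp(X, targets, X_val=None, y_val=None, **hyper) -> SoftLabelMLP:
    """Fit a :class:`SoftLabelMLP` on spectra (rows) and soft targets."""
    return SoftLabelMLP(**hyper).fit(X, targets, X_val=X_val, y_val=y_val)


def posteriors(model: SoftLabelMLP, x) -> np.ndarray:
    """Class posterior vector for a single spectrum."""
    return model.predict_proba(np.atleast_2d(x))[0]


def posterior_input_gradients(model: SoftLabelMLP, x) -> np.ndarray:
    """Analytic C x D matrix of posterior gradients at one spectrum."""
    return model.input_gradients(np.atleast_2d(x))[0]


def fi_local_metric(model: SoftLabelMLP, x, prob_floor: float = PROB_FLOOR) -> np.ndarray:
    """The local FI metric J(x), a symmetric PSD D x D matrix."""
    p = np.maximum(posteriors(model, x), prob_floor)
    grads = posterior_input_gradients(model, x)  # C x D
    # sum_c p_c (grad p_c / p_c)(grad p_c / p_c)^T = sum_c grad_c grad_c^T / p_c
    return (grads / p[:, None]).T @ grads


def _directional_quadratic(model: SoftLabelMLP, M: np.ndarray, V: np.ndarray,
                           prob_floor: float) -> np.ndarray:
    """``v^T J(m) v`` for each row pair (m, v), without forming J.

    Uses the forward-mode identity dp = p * (dz - <p, dz>) for the
    softmax head, so the cost is linear in D.
    """
    W1, b1 = model.coef_hidden_, model.intercept_hidden_
    W2, b2 = model.coef_output_, model.intercept_output_
    A = np.tanh(M @ W1.T + b1)
    Z = A @ W2.T + b2
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    P = E / E.sum(axis=1, keepdims=True)
    dA = (1.0 - A**2) * (V @ W1.T)
    dZ = dA @ W2.T
    dP = P * (dZ - np.sum(P * dZ, axis=1, keepdims=True))
    return np.sum(dP**2 / np.maximum(P, prob_floor), axis=1)


def fi_pairwise_distances(
    model: SoftLabelMLP,
    X,
    n_segments: int = 10,
    prob_floor: float = PROB_FLOOR,
    chunk_pairs: int = 512,
) -> np.ndarray:
    """Symmetric matrix of piecewise FI distances between all rows of X.

    The straight line from x_a to x_b is cut into ``n_segments`` equal
    segments; each contributes ``sqrt(delta^T J(midpoint) delta)``.  Only
    one ordering per pair is evaluated and mirrored, so the result is
    exactly symmetric with a zero diagonal.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    ia, ib = np.triu_indices(n, k=1)
    D = np.zeros((n, n))
    t_frac = (np.arange(n_segments) + 0.5) / n_segments
    for lo in range(0, len(ia), chunk_pairs):
        a = ia[lo:lo + chunk_pairs]
        b = ib[lo:lo + chunk_pairs]
        delta = (X[b] - X[a]) / n_segments                     # pairs x D
        mids = X[a][:, None, :] + t_frac[None, :, None] * (X[b] - X[a])[:, None, :]
        q = _directional_quadratic(
            model,
            mids.reshape(-1, X.shape[1]),
            np.repeat(delta, n_segments, axis=0),
            prob_floor,
        ).reshape(len(a), n_segments)
        d = np.sqrt(np.maximum(q, 0.0)).sum(axis=1)
        D[a, b] = d
        D[b, a] = d
    return D


@dataclass
class Embedding:
    """Classical-MDS coordinates (rows = points) with spectrum bookkeeping."""

    coords: np.ndarray           # n x m
    eigenvalues: np.ndarray      # retained (positive, descending)
    n_components: int
    negative_mass: float         # |sum of negative eigenvalues| / positive mass


def mds_embed(distances, variance_keep: float = 0.99) -> Embedding:
    """Classical MDS of a distance matrix.

    Double-centres ``-0.5 * D**2``, eigendecomposes, and keeps the
    smallest number of axes whose positive eigenvalues cover
    ``variance_keep`` of the total positive-eigenvalue mass.  Negative
    eigenvalues (non-Euclidean residual) are discarded and their relative
    mass reported.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    n = D.shape[0]
    B = -0.5 * D**2
    B -= B.mean(axis=0, keepdims=True)
    B -= B.mean(axis=1, keepdims=True)
    vals, vecs = np.linalg.eigh(B)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    tol = max(abs(vals[0]), abs(vals[-1]), 1.0) * 1e-12 if n else 0.0
    pos = vals > tol
    if not pos.any():
        raise DegenerateEmbeddingError("no positive eigenvalue: nothing to embed")
    pos_vals = vals[pos]
    pos_mass = pos_vals.sum()
    neg_mass = float(-vals[vals < -tol].sum()) / pos_mass if pos_mass > 0 else 0.0
    m = int(np.searchsorted(np.cumsum(pos_vals) / pos_mass, variance_keep) + 1)
    m = min(m, len(pos_vals))
    coords = vecs[:, :m] * np.sqrt(pos_vals[:m])
    return Embedding(
        coords=coords, eigenvalues=pos_vals[:m], n_components=m, negative_mass=neg_mass
    )


class FisherEmbedding(TransformerMixin, BaseEstimator):
    """Transformer: spectra -> Euclidean coordinates under the FI metric.

    Composes a fitted :class:`SoftLabelMLP` posterior model with the
    piecewise FI distance and classical MDS.  Like other MDS-style
    transformers it only supports ``fit_transform`` (the embedding is
    defined jointly over the fitted set, not pointwise).

    Parameters
    ----------
    posterior_model : SoftLabelMLP
        A *fitted* posterior model.
    n_segments : int, default 10
        Segments of the piecewise line-integral distance.
    variance_keep : float, default 0.99
        Positive-eigenvalue mass retained by MDS.
    """

    def __init__(
        self,
        posterior_model: SoftLabelMLP | None = None,
        n_segments: int = 10,
        variance_keep: float = 0.99,
    ):
        self.posterior_model = posterior_model
        self.n_segments = n_segments
        self.variance_keep = variance_keep

    def fit_transform(self, X, y=None) -> np.ndarray:
        if self.posterior_model is None:
            raise ValueError("posterior_model must be a fitted SoftLabelMLP")
        self.distance_matrix_ = fi_pairwise_distances(
            self.posterior_model, X, n_segments=self.n_segments
        )
        emb = mds_embed(self.distance_matrix_, variance_keep=self.variance_keep)
        self.embedding_ = emb.coords
        self.eigenvalues_ = emb.eigenvalues
        self.n_components_ = emb.n_components
        self.negative_mass_ = emb.negative_mass
        return emb.coords

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self
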