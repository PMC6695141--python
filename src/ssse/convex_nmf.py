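"""Convexity-constrained non-negative matrix factorisation.

Convex-NMF factorises a data matrix ``Y`` (one data vector per column,
mixed sign allowed) as ``Y ~ Y W G^T`` with ``W, G >= 0``: each source
``(Y W)[:, j]`` is constrained to be a (nonnegative, after rescaling
convex) combination of the observed data vectors, which keeps sources
interpretable as "spectra that could have been measured", and each data
vector is a positive-only mixture of the sources.  Fitting uses the
standard multiplicative updates built on the positive/negative part
decomposition of ``Y^T Y``, initialised from a k-means clustering of the
data vectors (cluster indicators smoothed by 0.2), which makes the
objective non-increasing at every iteration.

The same factorisation serves two roles: applied directly to spectra it
is the unsupervised source-extraction baseline; applied to
Fisher-metric MDS coordinates it is the final stage of the
segmentation-guided method, after which the convexity weights ``W`` are
carried back to the original spectra to read off spectral-domain
sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted

_EPS = 1e-12  # zero-locking guard inside multiplicative-update denominators


class DegenerateSourceError(ValueError):
    """A convexity-weight column is identically zero."""


@dataclass
class ConvexFactors:
    """Raw factors of ``Y ~ Y W G^T`` plus the per-iteration objective."""

    W: np.ndarray                 # N x k, >= 0
    G: np.ndarray                 # N x k, >= 0
    objective_trace: np.ndarray   # ||Y - Y W G^T||_F^2 per iteration


@dataclass
class SourceSet:
    """Spectral-domain sources and the convex weights that built them."""

    S_spec: np.ndarray            # D x k
    weights: np.ndarray           # N x k, columns sum to 1


@dataclass
class MixingMatrix:
    """Per-voxel source abundances.

    ``H`` is the raw k x N mixing matrix compensating the convex-weight
    normalisation (so ``Y W G^T = Y W_hat H`` exactly); ``proportions``
    is its column-normalised display form.
    """

    H: np.ndarray
    proportions: np.ndarray


class ConvexNMF(TransformerMixin, BaseEstimator):
    """Scikit-learn style Convex-NMF decomposition.

    Data follow the scikit-learn orientation (rows are samples); the
    factorisation above applies to ``Y = X.T``.

    Parameters
    ----------
    n_components : int
        Number of sources ``k``.
    max_iter : int, default 500
        Cap on multiplicative-update iterations.
    tol : float, default 1e-6
        Stop when the relative objective change drops below this.
    random_state : int or None
        Seed for the k-means initialisation.

    Attributes
    ----------
    components_ : ndarray, k x n_features
        Sources, convex combinations of the fitted samples.
    W_, G_ : ndarray, n_samples x k
        Raw factor matrices.
    objective_trace_ : ndarray
        Frobenius objective per iteration (non-increasing).
    """

    def __init__(self, n_components: int = 2, max_iter: int = 500,
                 tol: float = 1e-6, random_state: int | None = None):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit_transform(self, X, y=None) -> np.ndarray:
        X = check_array(X, dtype=float)
        factors = convex_nmf(
            X.T, self.n_components, max_iter=self.max_iter, tol=self.tol,
            seed=self.random_state,
        )
        self.W_, self.G_ = factors.W, factors.G
        self.objective_trace_ = factors.objective_trace
        self.n_iter_ = len(factors.objective_trace)
        self.reconstruction_err_ = float(np.sqrt(factors.objective_trace[-1]))
        sources = spectral_sources(X.T, factors)
        self.components_ = sources.S_spec.T
        self.normalized_weights_ = sources.weights
        self.n_features_in_ = X.shape[1]
        return mixing_proportions(factors).H.T

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def transform(self, X) -> np.ndarray:
        """Nonnegative least-squares projection of new samples on the sources."""
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        S = self.components_.T
        return np.stack([nnls(S, x)[0] for x in X])


def convex_nmf(Y, k: int, max_iter: int = 500, tol: float = 1e-6,
               seed: int | None = None, init: str = "clustered") -> ConvexFactors:
    """Factorise ``Y`` (features x samples, mixed sign) as ``Y W G^T``.

    Multiplicative updates on ``W`` and ``G`` using the decomposition
    ``A = Y^T Y = A+ - A-`` with ``A+ = (|A|+A)/2``.  The default
    initialisation is a k-means clustering of the columns (indicator +
    0.2 smoothing, W additionally divided by cluster sizes);
    ``init="random"`` draws both factors uniformly instead, which is the
    useful choice for multi-restart searches (k-means is essentially
    deterministic on small inputs, so clustered restarts coincide).
    """
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y must be finite")
    n = Y.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of data vectors ({n})")

    if init == "clustered":
        clusters = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(Y.T)
        Ind = np.equal.outer(clusters, np.arange(k)).astype(float)
        sizes = np.maximum(Ind.sum(axis=0), 1.0)
        G = Ind + 0.2
        W = (Ind + 0.2) / sizes
    elif init == "random":
        rng = np.random.default_rng(seed)
        W = rng.uniform(0.01, 1.0, (n, k))
        G = rng.uniform(0.01, 1.0, (n, k))
    else:
        raise ValueError("init must be 'clustered' or 'random'")

    A = Y.T @ Y
    Ap = (np.abs(A) + A) / 2.0
    Am = (np.abs(A) - A) / 2.0

    def objective(W, G):
        # ||Y||^2 - 2 tr(G W^T A) + tr(W^T A W G^T G), avoids D x N products
        return float(
            np.trace(A)
            - 2.0 * np.sum((A @ W) * G)
            + np.sum((W.T @ A @ W) * (G.T @ G))
        )

    trace = [objective(W, G)]
    for _ in range(max_iter):
        G *= np.sqrt((Ap @ W + G @ (W.T @ Am @ W)) /
                     np.maximum(Am @ W + G @ (W.T @ Ap @ W), _EPS))
        GtG = G.T @ G
        W *= np.sqrt((Ap @ G + Am @ W @ GtG) /
                     np.maximum(Am @ G + Ap @ W @ GtG, _EPS))
        obj = objective(W, G)
        trace.append(obj)
        prev = trace[-2]
        if abs(prev - obj) <= tol * max(abs(prev), _EPS):
            break
    return ConvexFactors(W=W, G=G, objective_trace=np.asarray(trace))


def spectral_sources(X_spectra, factors: ConvexFactors) -> SourceSet:
    """Back-project convexity weights onto spectra: ``S = X @ W_hat``.

    ``W`` columns are rescaled to unit sum so every source is an explicit
    convex combination of the observed voxel spectra, regardless of the
    space the factorisation ran in.
    """
    X_spectra = np.asarray(X_spectra, dtype=float)
    if X_spectra.shape[1] != factors.W.shape[0]:
        raise ValueError("spectra count does not match factor rows")
    colsums = factors.W.sum(axis=0)
    if np.any(colsums <= 0):
        raise DegenerateSourceError("a convexity-weight column is zero")
    W_hat = factors.W / colsums
    return SourceSet(S_spec=X_spectra @ W_hat, weights=W_hat)


def mixing_proportions(factors: ConvexFactors) -> MixingMatrix:
    """Mixing matrix compensated for the convex-weight normalisation.

    ``H = diag(colsum W) G^T`` keeps ``Y W_hat H`` identical to
    ``Y W G^T``; the display form normalises each voxel's abundances to
    proportions (uniform, with a warning, for an all-zero column).
    """
    colsums = factors.W.sum(axis=0)
    H = factors.G.T * colsums[:, None]
    totals = H.sum(axis=0)
    k = H.shape[0]
    if np.any(totals <= 0):
        warnings.warn("all-zero abundance column; proportions set uniform")
    proportions = np.where(totals > 0, H / np.where(totals > 0, totals, 1.0), 1.0 / k)
    return MixingMatrix(H=H, proportions=proportions)
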