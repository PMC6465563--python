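"""Scikit-learn style estimator wrapping the full prediction pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import AssociationMatrix
from .kernels import gip_kernel, neighbor_restrict_normalize
from .propagation import bidirectional_scores, fuse

__all__ = ["BidirectionalLabelPropagation"]


class BidirectionalLabelPropagation(BaseEstimator):
    """Bipartite link prediction by bidirectional label propagation.

    Given a binary disease x microbe association matrix ``A``, the model

    1. computes Gaussian interaction profile kernel similarities between
       diseases (rows of ``A``) and between microbes (columns of ``A``);
    2. restricts each similarity row to a neighbor set and renormalizes it
       to a row-stochastic network;
    3. propagates the association labels over both networks, accumulating
       the iterates until the L1 change falls below ``threshold``;
    4. fuses the two directional score sums into one score matrix
       ``W = beta * W_LPM + (1 - beta) * W_LPD``.

    High fused scores for unobserved pairs flag candidate associations.

    Parameters
    ----------
    alpha : float, default=0.2
        Absorption probability: weight of the propagated neighbor labels at
        each update (the node retains its previous label with 1 - alpha).
    beta : float, default=0.75
        Fusion weight of the microbe-network score matrix.
    k_neighbors : int, default=5
        Neighbor-set size parameter K passed to the network construction.
    neighbor_mode : {"literal", "topk"}, default="literal"
        "literal" keeps all nodes except self and the K least similar;
        "topk" keeps only the K most similar nodes.
    gamma_prime_d, gamma_prime_m : float, default=1.0
        Raw GIP bandwidths for the disease and microbe kernels.
    gamma_fallback : bool, default=False
        Use gamma = gamma_prime when every profile is all-zero instead of
        raising (needed inside cross-validation folds).
    threshold : float, default=1e-12
        Convergence threshold P on the entry-wise L1 iterate change.
    max_iter : int, default=1000
        Safety cap on propagation iterations.
    classic_lp : bool, default=False
        Use the conventional recursion (propagate the previous iterate)
        instead of the constant-term recursion.

    Attributes
    ----------
    scores_ : ndarray of shape (n_diseases, n_microbes)
        Fused prediction score matrix W.
    w_lpd_, w_lpm_ : ndarray
        Directional score sums (both in disease x microbe orientation).
    kernel_d_, kernel_m_ : ndarray
        GIP kernel matrices SD and SM.
    network_d_, network_m_ : ndarray
        Row-normalized neighbor-restricted networks SD* and SM*.
    n_iter_d_, n_iter_m_ : int
        Propagation rounds used on each network.

    Examples
    --------
    >>> import numpy as np
    >>> from bilap import BidirectionalLabelPropagation
    >>> A = np.array([[1., 0., 1.], [0., 1., 0.]])
    >>> W = BidirectionalLabelPropagation(k_neighbors=0).fit_predict(A)
    >>> W.shape
    (2, 3)
    """

    def __init__(
        self,
        alpha: float = 0.2,
        beta: float = 0.75,
        k_neighbors: int = 5,
        neighbor_mode: str = "literal",
        gamma_prime_d: float = 1.0,
        gamma_prime_m: float = 1.0,
        gamma_fallback: bool = False,
        threshold: float = 1e-12,
        max_iter: int = 1000,
        classic_lp: bool = False,
    ):
        self.alpha = alpha
        self.beta = beta
        self.k_neighbors = k_neighbors
        self.neighbor_mode = neighbor_mode
        self.gamma_prime_d = gamma_prime_d
        self.gamma_prime_m = gamma_prime_m
        self.gamma_fallback = gamma_fallback
        self.threshold = threshold
        self.max_iter = max_iter
        self.classic_lp = classic_lp

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, AssociationMatrix):
            return X.A
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        return X

    def fit(self, X, y=None):
        """Fit on a binary association matrix (or :class:`AssociationMatrix`)."""
        A = self._as_array(X)
        self.kernel_d_ = gip_kernel(A, self.gamma_prime_d, self.gamma_fallback)
        self.kernel_m_ = gip_kernel(A.T, self.gamma_prime_m, self.gamma_fallback)
        self.network_d_, self.neighbor_sets_d_ = neighbor_restrict_normalize(
            self.kernel_d_, self.k_neighbors, self.neighbor_mode
        )
        self.network_m_, self.neighbor_sets_m_ = neighbor_restrict_normalize(
            self.kernel_m_, self.k_neighbors, self.neighbor_mode
        )
        self.w_lpd_, self.w_lpm_, trace_d, trace_m = bidirectional_scores(
            A,
            self.network_d_,
            self.network_m_,
            alpha=self.alpha,
            threshold=self.threshold,
            max_iter=self.max_iter,
            classic=self.classic_lp,
        )
        self.n_iter_d_ = trace_d.n_iterations
        self.n_iter_m_ = trace_m.n_iterations
        self.trace_d_ = trace_d
        self.trace_m_ = trace_m
        self.scores_ = fuse(self.w_lpd_, self.w_lpm_, self.beta)
        self.n_features_in_ = A.shape[1]
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the fused score matrix."""
        return self.fit(X).scores_

    def predict(self, X=None) -> np.ndarray:
        """Return the fitted fused score matrix (``X`` is ignored)."""
        check_is_fitted(self, "scores_")
        return self.scores_
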