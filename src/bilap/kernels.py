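"""Gaussian interaction profile (GIP) kernels and KNN-restricted normalization.

The GIP kernel scores two entities by the Euclidean distance between their
binary association profiles:

    S(i, j) = exp(-gamma * ||p_i - p_j||^2),
    gamma   = gamma_prime / mean_k ||p_k||^2,

so the bandwidth adapts to the average number of associations per entity.
Because the kernel is strictly positive, the similarity graph is complete;
before label propagation each row is restricted to a neighbor set Q_i and
renormalized to sum to one over Q_i.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gip_bandwidth", "gip_kernel", "neighbor_restrict_normalize"]

NEIGHBOR_MODES = ("literal", "topk")


def gip_bandwidth(profiles: np.ndarray, gamma_prime: float = 1.0,
                  fallback: bool = False) -> float:
    """Bandwidth gamma = gamma_prime / mean squared profile norm.

    If every profile is all-zero the mean is 0; by default this raises, but
    with ``fallback`` gamma = gamma_prime is returned (all distances are
    then 0 anyway, giving the all-ones kernel).  Cross-validation folds can
    hit this case when a singleton profile loses its only association.
    """
    if gamma_prime <= 0:
        raise ValueError(f"gamma_prime must be > 0, got {gamma_prime}")
    profiles = np.asarray(profiles, dtype=float)
    mean_sq = float((profiles**2).sum(axis=1).mean())
    if mean_sq == 0.0:
        if not fallback:
            raise ValueError(
                "all interaction profiles are all-zero: GIP bandwidth is "
                "undefined (enable gamma fallback to use gamma = gamma_prime)"
            )
        return float(gamma_prime)
    return float(gamma_prime) / mean_sq


def gip_kernel(profiles: np.ndarray, gamma_prime: float = 1.0,
               fallback: bool = False) -> np.ndarray:
    """Gaussian interaction profile kernel matrix of a set of binary profiles.

    Parameters
    ----------
    profiles
        ``(n, m)`` binary matrix, one profile per row.  For diseases pass
        the adjacency matrix ``A`` (rows are disease profiles); for microbes
        pass ``A.T`` (rows are microbe profiles).
    gamma_prime
        Raw bandwidth before normalization by the mean squared norm.
    fallback
        Passed to :func:`gip_bandwidth` for the all-zero degenerate case.

    Returns
    -------
    ``(n, n)`` symmetric matrix with unit diagonal and entries in (0, 1].
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 1:
        raise ValueError("profiles must be a non-empty 2-D matrix")
    if not np.isin(profiles, (0.0, 1.0)).all():
        raise ValueError("profiles must be binary")
    gamma = gip_bandwidth(profiles, gamma_prime, fallback)
    # Squared Euclidean distance via dot products; exact for 0/1 profiles.
    norms = (profiles**2).sum(axis=1)
    d2 = norms[:, None] + norms[None, :] - 2.0 * (profiles @ profiles.T)
    np.maximum(d2, 0.0, out=d2)
    S = np.exp(-gamma * d2)
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    return S


def neighbor_restrict_normalize(
    S: np.ndarray, k: int = 5, mode: str = "literal"
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Restrict each kernel row to a neighbor set Q_i and renormalize.

    Two readings of the neighbor set are supported:

    ``literal``
        Q_i = every node except i itself and the ``k`` nodes LEAST similar
        to i, so ``|Q_i| = n - 1 - k``.
    ``topk``
        Q_i = the ``k`` nodes MOST similar to i (standard KNN graph).

    Ties at the cut are broken by ascending node index.  Entries outside
    Q_i are zero (including the diagonal); retained entries are divided by
    their row sum, so each non-empty row of the result sums to one.

    Returns the normalized matrix and the per-row neighbor index arrays.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if mode not in NEIGHBOR_MODES:
        raise ValueError(f"neighbor mode must be one of {NEIGHBOR_MODES}, got {mode!r}")
    if not 0 <= k <= n - 1:
        raise ValueError(f"k must satisfy 0 <= k <= n-1 = {n - 1}, got {k}")
    S_star = np.zeros_like(S)
    neighbor_sets: list[np.ndarray] = []
    others = np.arange(n)
    for i in range(n):
        cand = others[others != i]
        sims = S[i, cand]
        if mode == "literal":
            # drop the k least similar; lexsort ties by ascending index
            asc = cand[np.lexsort((cand, sims))]
            q = np.sort(asc[k:])
        else:
            desc = cand[np.lexsort((cand, -sims))]
            q = np.sort(desc[:k])
        neighbor_sets.append(q)
        if q.size:
            S_star[i, q] = S[i, q] / S[i, q].sum()
    return S_star, neighbor_sets
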