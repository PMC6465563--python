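"""Bidirectional label propagation on the two similarity networks.

Each direction iterates, from the initial label matrix L^0 (the adjacency
matrix, or its transpose on the microbe side),

    L^k = alpha * S* @ L^0 + (1 - alpha) * L^{k-1},

where S* is the row-normalized neighbor-restricted similarity network.
Note the propagated term is CONSTANT across iterations (the recursion mixes
toward the fixed point S* @ L^0), which gives the exact closed form

    L^k = (1 - (1-alpha)^k) * S* @ L^0  +  (1-alpha)^k * L^0,

so the entry-wise L1 change decays exactly geometrically:
||L^k - L^{k-1}||_1 = (1-alpha)^{k-1} ||L^1 - L^0||_1.  Iteration stops at
the first k where the change drops below the threshold P, and the score is
the running sum L^0 + L^1 + ... + L^n.  An optional ``classic`` recursion
(alpha * S* @ L^{k-1} + (1-alpha) * L^0, conventional label propagation) is
available for comparison.

The two directional score sums are fused as

    W = beta * W_LPM + (1 - beta) * W_LPD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PropagationTrace",
    "propagate",
    "closed_form_iterate",
    "predict_n_iterations",
    "bidirectional_scores",
    "fuse",
]


@dataclass
class PropagationTrace:
    """Outcome of one directional propagation run.

    ``score_sum`` is the accumulated sum of the iterates L^0 .. L^n;
    ``truncated`` is set when ``max_iter`` was reached before the L1 change
    fell below the threshold.  ``history`` holds every iterate when
    requested (diagnostics/tests only).
    """

    n_iterations: int
    final_change: float
    score_sum: np.ndarray = field(repr=False)
    truncated: bool = False
    history: list[np.ndarray] | None = field(default=None, repr=False)


def propagate(
    S_star: np.ndarray,
    L0: np.ndarray,
    alpha: float = 0.2,
    threshold: float = 1e-12,
    max_iter: int = 1000,
    classic: bool = False,
    keep_history: bool = False,
) -> PropagationTrace:
    """Iterate label propagation to convergence and accumulate the iterates.

    Parameters
    ----------
    S_star
        ``(n, n)`` row-normalized neighbor-restricted similarity matrix.
    L0
        ``(n, m)`` initial label matrix (one row per network node).
    alpha
        Absorption probability in (0, 1]: weight of the propagated term.
    threshold
        Convergence threshold P on the entry-wise L1 change.
    classic
        Use the conventional recursion propagating the previous iterate.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    S_star = np.asarray(S_star, dtype=float)
    L0 = np.asarray(L0, dtype=float)
    if S_star.ndim != 2 or S_star.shape[0] != S_star.shape[1]:
        raise ValueError("S_star must be square")
    if L0.shape[0] != S_star.shape[0]:
        raise ValueError(
            f"L0 has {L0.shape[0]} rows but the network has {S_star.shape[0]} nodes"
        )
    const = alpha * (S_star @ L0) if not classic else None
    retain = 1.0 - alpha
    L_prev = L0.copy()
    total = L0.copy()
    history = [L0.copy()] if keep_history else None
    n_iter = 0
    change = np.inf
    for k in range(1, max_iter + 1):
        if classic:
            L = alpha * (S_star @ L_prev) + retain * L0
        else:
            L = const + retain * L_prev
        change = float(np.abs(L - L_prev).sum())
        total += L
        if keep_history:
            history.append(L.copy())
        n_iter = k
        L_prev = L
        if change < threshold:
            return PropagationTrace(n_iter, change, total, False, history)
    return PropagationTrace(n_iter, change, total, True, history)


def closed_form_iterate(S_star: np.ndarray, L0: np.ndarray, alpha: float, k: int) -> np.ndarray:
    """Analytic k-th iterate of the default (constant-term) recursion."""
    r = (1.0 - alpha) ** k
    return (1.0 - r) * (S_star @ L0) + r * L0


def predict_n_iterations(
    S_star: np.ndarray, L0: np.ndarray, alpha: float, threshold: float
) -> int:
    """Predicted stopping iteration from the exact geometric decay.

    The first change is c1 = ||L^1 - L^0||_1 = alpha * ||S* L0 - L0||_1 and
    subsequent changes are c1 * (1-alpha)^{k-1}; the loop stops at the first
    k >= 1 with that below the threshold.
    """
    c1 = alpha * float(np.abs(S_star @ L0 - L0).sum())
    if c1 < threshold:
        return 1
    if alpha == 1.0:
        return 2  # change is exactly 0 from the second iteration on
    # smallest k with (1-alpha)^(k-1) * c1 < P
    k = int(np.ceil(np.log(threshold / c1) / np.log(1.0 - alpha))) + 1
    while c1 * (1.0 - alpha) ** (k - 2) < threshold and k > 1:
        k -= 1
    while c1 * (1.0 - alpha) ** (k - 1) >= threshold:
        k += 1
    return k


def bidirectional_scores(
    A: np.ndarray,
    SD_star: np.ndarray,
    SM_star: np.ndarray,
    alpha: float = 0.2,
    threshold: float = 1e-12,
    max_iter: int = 1000,
    classic: bool = False,
) -> tuple[np.ndarray, np.ndarray, PropagationTrace, PropagationTrace]:
    """Run propagation on both networks and return both score matrices.

    The disease network propagates the rows of ``A``; the microbe network
    propagates the rows of ``A.T`` and its score sum is transposed back to
    disease x microbe orientation so the two outputs are directly fusable.
    Returns ``(W_LPD, W_LPM, disease_trace, microbe_trace)``.
    """
    A = np.asarray(A, dtype=float)
    n_d, n_m = A.shape
    if SD_star.shape != (n_d, n_d):
        raise ValueError(
            f"disease network is {SD_star.shape} but A has {n_d} disease rows"
        )
    if SM_star.shape != (n_m, n_m):
        raise ValueError(
            f"microbe network is {SM_star.shape} but A has {n_m} microbe columns"
        )
    trace_d = propagate(SD_star, A, alpha, threshold, max_iter, classic)
    trace_m = propagate(SM_star, A.T, alpha, threshold, max_iter, classic)
    return trace_d.score_sum, trace_m.score_sum.T, trace_d, trace_m


def fuse(W_LPD: np.ndarray, W_LPM: np.ndarray, beta: float = 0.75) -> np.ndarray:
    """Weighted fusion W = beta * W_LPM + (1 - beta) * W_LPD."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    W_LPD = np.asarray(W_LPD, dtype=float)
    W_LPM = np.asarray(W_LPM, dtype=float)
    if W_LPD.shape != W_LPM.shape:
        raise ValueError(f"shape mismatch: {W_LPD.shape} vs {W_LPM.shape}")
    return beta * W_LPM + (1.0 - beta) * W_LPD
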