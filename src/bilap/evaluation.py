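"""Cross-validation, ROC/AUC, and parameter sweeps.

Evaluation follows the link-prediction convention for curated association
data: every known pair is a positive, every pair never observed together is
a negative, and a test positive is ranked against the negative pool by its
fused prediction score.  Leave-one-out removes one known association at a
time; repeated k-fold removes a random fifth (say) of them at once and
averages over many random partitions.

By default the similarity kernels are recomputed inside every fold after
the test edges are zeroed — otherwise the held-out edge leaks into the
Gaussian interaction profile kernels.  The leaky variant is available via
``refit_similarity=False`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone

from .data import AssociationMatrix
from .estimator import BidirectionalLabelPropagation
from .kernels import gip_kernel, neighbor_restrict_normalize
from .propagation import bidirectional_scores, fuse

__all__ = [
    "CVResult",
    "RocCurve",
    "auc_rank",
    "roc_points",
    "loocv",
    "kfold_cv",
    "sweep",
]


def auc_rank(positive_scores, negative_scores) -> float:
    """Rank-based AUC (Mann-Whitney statistic, midrank tie convention).

    The fraction of (positive, negative) score pairs with the positive
    strictly higher, counting ties as one half.
    """
    pos = np.asarray(positive_scores, dtype=float).ravel()
    neg = np.asarray(negative_scores, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class RocCurve:
    """Empirical ROC curve: aligned threshold / TPR / FPR arrays.

    The curve starts at (0, 0) (threshold above every score) and ends at
    (1, 1); thresholds are the distinct scores in descending order.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray

    def auc(self) -> float:
        """Trapezoidal area under the curve."""
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_points(positive_scores, negative_scores) -> RocCurve:
    """Empirical ROC over all distinct score thresholds.

    Its trapezoidal area equals :func:`auc_rank` on the same scores (the
    midrank tie convention corresponds to the diagonal segments trapezoids
    integrate exactly).
    """
    pos = np.asarray(positive_scores, dtype=float).ravel()
    neg = np.asarray(negative_scores, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    # indices where the score changes: one ROC point per distinct threshold
    distinct = np.flatnonzero(np.diff(scores)) if scores.size > 1 else np.array([], int)
    idx = np.r_[distinct, scores.size - 1]
    tps = np.cumsum(labels)[idx]
    fps = np.cumsum(~labels)[idx]
    return RocCurve(
        thresholds=scores[idx],
        tpr=np.r_[0.0, tps / pos.size],
        fpr=np.r_[0.0, fps / neg.size],
    )


@dataclass
class CVResult:
    """Cross-validation outcome.

    ``auc`` is the headline number: the per-fold-averaged AUC for LOOCV
    (or the pooled AUC under ``pooling="pooled"``), and the mean of the
    per-repeat AUCs for k-fold.  ``repeats`` / ``auc_mean`` / ``auc_std``
    are populated by k-fold only; the std is the sample standard deviation
    over repeat means.
    """

    auc: float
    fold_assignments: dict[tuple[int, int], int] = field(default_factory=dict)
    test_scores: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    negative_scores: list[np.ndarray] = field(default_factory=list, repr=False)
    repeats: list[float] | None = None
    auc_mean: float | None = None
    auc_std: float | None = None


def _as_array(X) -> np.ndarray:
    if isinstance(X, AssociationMatrix):
        return np.asarray(X.A, dtype=float)
    return np.asarray(X, dtype=float)


def _cv_estimator(estimator, gamma_fallback: bool) -> BidirectionalLabelPropagation:
    est = clone(estimator) if estimator is not None else BidirectionalLabelPropagation()
    if gamma_fallback:
        est.set_params(gamma_fallback=True)
    return est


def _fold_scores(est: BidirectionalLabelPropagation, A_masked: np.ndarray,
                 networks: tuple[np.ndarray, np.ndarray] | None) -> np.ndarray:
    """Fused scores for one fold; reuse full-data networks if provided."""
    if networks is None:
        return est.fit_predict(A_masked)
    sd_star, sm_star = networks
    w_lpd, w_lpm, _, _ = bidirectional_scores(
        A_masked, sd_star, sm_star,
        alpha=est.alpha, threshold=est.threshold,
        max_iter=est.max_iter, classic=est.classic_lp,
    )
    return fuse(w_lpd, w_lpm, est.beta)


def _full_networks(est: BidirectionalLabelPropagation, A: np.ndarray):
    sd = gip_kernel(A, est.gamma_prime_d, est.gamma_fallback)
    sm = gip_kernel(A.T, est.gamma_prime_m, est.gamma_fallback)
    sd_star, _ = neighbor_restrict_normalize(sd, est.k_neighbors, est.neighbor_mode)
    sm_star, _ = neighbor_restrict_normalize(sm, est.k_neighbors, est.neighbor_mode)
    return sd_star, sm_star


def loocv(
    X,
    estimator: BidirectionalLabelPropagation | None = None,
    refit_similarity: bool = True,
    gamma_fallback: bool = True,
    pooling: str = "mean",
) -> CVResult:
    """Leave-one-out cross-validation over the known associations.

    Each known pair is zeroed in turn, the entire pipeline is re-run on the
    reduced matrix (kernels included, unless ``refit_similarity=False``),
    and the held-out pair's fused score is ranked against the scores of all
    pairs that are negative in the ORIGINAL matrix.

    ``pooling="mean"`` averages the per-fold win fractions (each test pair
    against its own fold's negative pool); ``pooling="pooled"`` ranks all
    test scores against all folds' negative scores in one global AUC.
    """
    if pooling not in ("mean", "pooled"):
        raise ValueError(f"pooling must be 'mean' or 'pooled', got {pooling!r}")
    A = _as_array(X)
    known = np.argwhere(A == 1.0)
    if known.shape[0] < 2:
        raise ValueError("need at least 2 known associations for LOOCV")
    neg_mask = A == 0.0
    if not neg_mask.any():
        raise ValueError("no negative pairs: every disease-microbe pair is known")
    est = _cv_estimator(estimator, gamma_fallback)
    networks = None if refit_similarity else _full_networks(est, A)
    result = CVResult(auc=np.nan)
    wins = []
    for fold, (i, j) in enumerate(known):
        A_fold = A.copy()
        A_fold[i, j] = 0.0
        W = _fold_scores(est, A_fold, networks)
        s = W[i, j]
        negs = W[neg_mask]
        wins.append(((negs < s).sum() + 0.5 * (negs == s).sum()) / negs.size)
        result.fold_assignments[(int(i), int(j))] = fold
        result.test_scores.append(((int(i), int(j)), float(s)))
        result.negative_scores.append(negs)
    if pooling == "mean":
        result.auc = float(np.mean(wins))
    else:
        result.auc = auc_rank(
            [s for _, s in result.test_scores], np.concatenate(result.negative_scores)
        )
    return result


def kfold_cv(
    X,
    n_folds: int = 5,
    n_repeats: int = 100,
    seed: int = 0,
    estimator: BidirectionalLabelPropagation | None = None,
    refit_similarity: bool = True,
    gamma_fallback: bool = True,
) -> CVResult:
    """Repeated k-fold cross-validation over the known associations.

    Per repeat, the known pairs are partitioned uniformly at random into
    ``n_folds`` groups (seeded; repeat r uses ``seed + r``).  All test
    edges of a fold are zeroed simultaneously, the pipeline is re-run, and
    the fold AUC ranks the test pairs' scores against the negative pool.
    The repeat AUC is the mean over folds; the result reports the mean and
    sample standard deviation over repeats.
    """
    A = _as_array(X)
    known = np.argwhere(A == 1.0)
    n_known = known.shape[0]
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    if n_folds > n_known:
        raise ValueError(f"n_folds = {n_folds} exceeds the {n_known} known pairs")
    if n_repeats < 1:
        raise ValueError(f"n_repeats must be >= 1, got {n_repeats}")
    neg_mask = A == 0.0
    if not neg_mask.any():
        raise ValueError("no negative pairs: every disease-microbe pair is known")
    est = _cv_estimator(estimator, gamma_fallback)
    networks = None if refit_similarity else _full_networks(est, A)
    result = CVResult(auc=np.nan)
    repeat_aucs = []
    for r in range(n_repeats):
        rng = np.random.default_rng(seed + r)
        order = rng.permutation(n_known)
        fold_aucs = []
        for fold, members in enumerate(np.array_split(order, n_folds)):
            A_fold = A.copy()
            rows, cols = known[members, 0], known[members, 1]
            A_fold[rows, cols] = 0.0
            W = _fold_scores(est, A_fold, networks)
            fold_aucs.append(auc_rank(W[rows, cols], W[neg_mask]))
            if r == 0:
                for m in members:
                    result.fold_assignments[(int(known[m, 0]), int(known[m, 1]))] = fold
                result.negative_scores.append(W[neg_mask])
                result.test_scores.extend(
                    ((int(i), int(j)), float(W[i, j])) for i, j in known[members]
                )
        repeat_aucs.append(float(np.mean(fold_aucs)))
    result.repeats = repeat_aucs
    result.auc_mean = float(np.mean(repeat_aucs))
    result.auc_std = float(np.std(repeat_aucs, ddof=1)) if n_repeats > 1 else 0.0
    result.auc = result.auc_mean
    return result


_SWEEPABLE = ("alpha", "beta", "k_neighbors")


def sweep(
    X,
    param_name: str,
    grid,
    protocol: str = "loocv",
    estimator: BidirectionalLabelPropagation | None = None,
    **cv_kwargs,
) -> tuple[pd.DataFrame, float]:
    """Evaluate a grid of values for one pipeline parameter.

    Runs one full cross-validation per grid value with every other
    parameter at its configured value.  Returns a ``(value, auc)`` table
    and the argmax value.
    """
    if param_name not in _SWEEPABLE:
        raise ValueError(f"param_name must be one of {_SWEEPABLE}, got {param_name!r}")
    if protocol not in ("loocv", "kfold"):
        raise ValueError(f"protocol must be 'loocv' or 'kfold', got {protocol!r}")
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    base = clone(estimator) if estimator is not None else BidirectionalLabelPropagation()
    rows = []
    for value in grid:
        est = clone(base)
        est.set_params(**{param_name: int(value) if param_name == "k_neighbors" else value})
        if protocol == "loocv":
            res = loocv(X, estimator=est, **cv_kwargs)
        else:
            res = kfold_cv(X, estimator=est, **cv_kwargs)
        rows.append((value, res.auc))
    table = pd.DataFrame(rows, columns=[param_name, "auc"])
    best = table.loc[table["auc"].idxmax(), param_name]
    return table, float(best)
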