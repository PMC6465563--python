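"""Synthetic bipartite association data with planted block structure.

A bipartite stochastic block model stands in for a curated association
database: diseases and microbes are assigned round-robin to communities,
and a pair is associated with probability ``p_in`` when their communities
match and ``p_out`` otherwise.  With ``p_in >> p_out`` held-out edges are
recoverable from the community signal, so the whole pipeline can be
exercised and benchmarked without any external download.  The default
shape (40 x 300) mirrors the aspect ratio of curated microbe-disease
collections, where microbes far outnumber diseases.
"""

from __future__ import annotations

import numpy as np

from .data import AssociationMatrix

__all__ = ["generate", "holdout_split", "shuffle_associations"]


def generate(
    n_diseases: int = 40,
    n_microbes: int = 300,
    n_blocks: int = 5,
    p_in: float = 0.3,
    p_out: float = 0.005,
    seed: int = 0,
) -> tuple[AssociationMatrix, tuple[np.ndarray, np.ndarray]]:
    """Draw a block-structured binary association matrix.

    Returns the matrix plus the ground-truth block labels of diseases and
    microbes (for diagnostics).  Deterministic given ``seed``.
    """
    if n_diseases < 2 or n_microbes < 2:
        raise ValueError("need at least 2 diseases and 2 microbes")
    if n_blocks < 1 or n_blocks > min(n_diseases, n_microbes):
        raise ValueError(
            f"n_blocks must be in [1, {min(n_diseases, n_microbes)}], got {n_blocks}"
        )
    if not 0.0 <= p_out < p_in <= 1.0:
        raise ValueError(f"need 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    rng = np.random.default_rng(seed)
    d_blocks = np.arange(n_diseases) % n_blocks
    m_blocks = np.arange(n_microbes) % n_blocks
    match = d_blocks[:, None] == m_blocks[None, :]
    p = np.where(match, p_in, p_out)
    A = (rng.random((n_diseases, n_microbes)) < p).astype(float)
    diseases = [f"disease_{i:03d}" for i in range(n_diseases)]
    microbes = [f"microbe_{j:03d}" for j in range(n_microbes)]
    return AssociationMatrix(diseases, microbes, A), (d_blocks, m_blocks)


def shuffle_associations(assoc: AssociationMatrix, seed: int = 0) -> AssociationMatrix:
    """Destroy all structure by scattering the same number of edges uniformly.

    The returned matrix has identical shape, identifiers, and edge count,
    with edge positions drawn uniformly at random — the null against which
    block-structure recovery is judged (expected AUC 0.5).
    """
    rng = np.random.default_rng(seed)
    flat = assoc.A.ravel()
    shuffled = np.zeros_like(flat)
    idx = rng.choice(flat.size, size=int(flat.sum()), replace=False)
    shuffled[idx] = 1.0
    return AssociationMatrix(
        list(assoc.diseases), list(assoc.microbes), shuffled.reshape(assoc.A.shape)
    )


def holdout_split(
    assoc: AssociationMatrix, fraction: float, seed: int = 0
) -> tuple[AssociationMatrix, list[tuple[int, int]]]:
    """Zero a seeded uniform sample of known pairs; return them for scoring.

    The training matrix and the held-out pair list partition the original
    edge set.  ``fraction`` of the edges (rounded, at least 1 required) is
    held out.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    known = np.argwhere(assoc.A == 1.0)
    if known.shape[0] < 2:
        raise ValueError("need at least 2 known pairs to split")
    n_held = int(round(fraction * known.shape[0]))
    if n_held == 0:
        raise ValueError(
            f"fraction {fraction} of {known.shape[0]} pairs rounds to zero held-out edges"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(known.shape[0], size=n_held, replace=False)
    train = assoc.copy()
    held = [(int(i), int(j)) for i, j in known[chosen]]
    for i, j in held:
        train.A[i, j] = 0.0
    return train, held
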