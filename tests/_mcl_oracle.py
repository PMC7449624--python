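"""Independent reference implementation of Markov clustering for tests.

A direct dense transcription of the algorithm's definition — column
normalisation, expansion by matrix power, entrywise inflation, pruning —
kept deliberately separate from the package's implementation: clusters are
read off as connected components of the converged matrix's nonzero pattern
rather than via attractor bookkeeping.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def mcl_reference(
    S: np.ndarray,
    inflation: float,
    expansion: int = 2,
    prune_below: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> list[frozenset[int]]:
    """Cluster a symmetric non-negative matrix; returns node-index sets."""
    M = np.array(S, dtype=float)
    n = M.shape[0]
    # self-loops on zero-diagonal nodes: column max, fallback 1
    for j in range(n):
        if M[j, j] == 0:
            M[j, j] = M[:, j].max() if M[:, j].max() > 0 else 1.0
    M = M / M.sum(axis=0)
    for _ in range(max_iter):
        new = np.linalg.matrix_power(M, expansion) ** inflation
        # prune, but never a column's largest entry
        top = new.max(axis=0)
        new[(new < prune_below) & (new < top)] = 0.0
        new = new / new.sum(axis=0)
        if np.abs(new - M).max() < tol:
            M = new
            break
        M = new
    graph = csr_matrix((M + M.T) > 0)
    n_comp, labels = connected_components(graph, directed=False)
    return [frozenset(np.nonzero(labels == c)[0]) for c in range(n_comp)]
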