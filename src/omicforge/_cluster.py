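"""Deterministic agglomerative clustering with explicit tie-breaking.

Rank-correlation distances over a handful of tissues are discrete, so exact
ties between merge candidates are routine rather than exceptional.  Generic
linkage implementations resolve such ties by data-structure order, which
makes the dendrogram depend on input ordering.  Here merges are resolved
deterministically: among all candidate pairs within ``tie_tol`` of the
minimum distance, the pair whose clusters contain the smallest original leaf
indices merges first.  The output is a scipy-compatible linkage matrix, so
``scipy.cluster.hierarchy`` (fcluster, cophenet, dendrogram) applies
downstream unchanged.
"""

from __future__ import annotations

import numpy as np

__all__ = ["linkage_matrix"]

#: Distinct average-of-rational distances differ by far more than this for
#: the cluster sizes this package handles; candidates closer than the
#: tolerance are treated as exactly tied.
TIE_TOL = 1e-9


def linkage_matrix(dist: np.ndarray, method: str = "average", tie_tol: float = TIE_TOL) -> np.ndarray:
    """Agglomerate a full square distance matrix into a linkage matrix.

    Supports average (UPGMA), complete and single linkage via the
    Lance-Williams updates.  Ties are broken by the smallest original leaf
    index contained in the candidate pair (then the second-smallest).
    """
    if method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage method {method!r}")
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least two items to cluster")
    size = 2 * n - 1
    D = np.full((size, size), np.inf)
    D[:n, :n] = dist
    np.fill_diagonal(D, np.inf)
    sizes = np.zeros(size, dtype=np.int64)
    sizes[:n] = 1
    min_leaf = np.arange(size)  # smallest original leaf per cluster
    active = list(range(n))
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = D[np.ix_(active, active)]
        dmin = sub.min()
        ii, jj = np.where(sub <= dmin + tie_tol)
        candidates = [
            (active[i], active[j]) for i, j in zip(ii, jj) if i < j
        ]
        a, b = min(
            candidates,
            key=lambda p: tuple(sorted((min_leaf[p[0]], min_leaf[p[1]]))),
        )
        d_ab = D[a, b]
        new = n + step
        others = [c for c in active if c not in (a, b)]
        if others:
            da = D[a, others]
            db = D[b, others]
            if method == "average":
                upd = (sizes[a] * da + sizes[b] * db) / (sizes[a] + sizes[b])
            elif method == "complete":
                upd = np.maximum(da, db)
            else:
                upd = np.minimum(da, db)
            D[new, others] = upd
            D[others, new] = upd
        sizes[new] = sizes[a] + sizes[b]
        min_leaf[new] = min(min_leaf[a], min_leaf[b])
        lo, hi = sorted((a, b), key=lambda c: min_leaf[c])
        Z[step] = (lo, hi, max(d_ab, 0.0), sizes[new])
        active = [c for c in active if c not in (a, b)] + [new]
    # enforce monotone heights against ulp-level Lance-Williams wobble
    np.maximum.accumulate(Z[:, 2], out=Z[:, 2])
    return Z
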