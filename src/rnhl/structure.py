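"""Structure-similarity (Z-score) preprocessing and average-linkage clustering.

The all-against-all DALI-style Z-score matrix over family representative
structures is symmetrized, floored (entries strictly below 6 are zeroed:
below that, structural similarity within this fold is not considered
significant), converted to distances by an affine shift, and clustered
by unweighted average linkage.  Cutting the dendrogram at k clusters
recovers the major structural groups (e.g. the split between the
reversed-C-terminal-helix exonucleases and the endonucleases).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import BoundsError, ConfigurationError, InputError


@dataclass(frozen=True)
class StructureParams:
    z_floor: float = 6.0

    def __post_init__(self):
        if self.z_floor < 0:
            raise ConfigurationError("z_floor must be >= 0")


def preprocess_zmatrix(
    Z: pd.DataFrame, params: StructureParams | None = None
) -> pd.DataFrame:
    """Symmetrize as (Z+Zᵀ)/2 and zero off-diagonal entries < z_floor.

    The floor is strict (an entry equal to the floor survives) and the
    diagonal is left untouched.
    """
    params = params or StructureParams()
    if Z.shape[0] != Z.shape[1]:
        raise InputError(f"Z matrix is not square: {Z.shape}")
    if list(Z.index) != list(Z.columns):
        if set(Z.index) != set(Z.columns):
            raise InputError("row and column labels differ")
        Z = Z.loc[:, Z.index]
    A = Z.to_numpy(dtype=float)
    diag = A.diagonal().copy()
    S = (A + A.T) / 2.0
    S[S < params.z_floor] = 0.0
    np.fill_diagonal(S, diag)
    return pd.DataFrame(S, index=Z.index, columns=Z.index)


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge tree.

    ``leaves`` are the item labels (cluster ids 0..n-1); merge t joins
    cluster ids ``merges[t][0]`` and ``merges[t][1]`` (new id n+t) at
    height ``merges[t][2]``.  Heights are non-decreasing.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self):
        n = len(self.leaves)
        if len(self.merges) != max(n - 1, 0):
            raise InputError(f"{len(self.merges)} merges for {n} leaves")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise InputError("merge heights must be non-decreasing")

    def to_linkage(self) -> np.ndarray:
        """SciPy-style linkage matrix (for plotting/inspection)."""
        n = len(self.leaves)
        sizes = {i: 1 for i in range(n)}
        out = np.zeros((len(self.merges), 4))
        for t, (a, b, h) in enumerate(self.merges):
            sizes[n + t] = sizes[a] + sizes[b]
            out[t] = [a, b, h, sizes[n + t]]
        return out

    def to_newick(self) -> str:
        """Ultrametric Newick; branch lengths from half merge heights."""
        n = len(self.leaves)
        reprs: dict[int, str] = {i: self.leaves[i] for i in range(n)}
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        for t, (a, b, h) in enumerate(self.merges):
            la = (h - height[a]) / 2.0
            lb = (h - height[b]) / 2.0
            reprs[n + t] = f"({reprs[a]}:{la:.6g},{reprs[b]}:{lb:.6g})"
            height[n + t] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return reprs[root] + ";"


def average_linkage_tree(S: pd.DataFrame) -> Dendrogram:
    """Agglomerate a similarity matrix by unweighted average linkage.

    Similarities are converted to distances by the affine shift
    ``d = max(offdiagonal S) − S`` (which preserves the merge order of
    mean-similarity linkage); ties are broken by the smallest leaf
    labels of the candidate pair.
    """
    if S.shape[0] != S.shape[1] or list(S.index) != list(S.columns):
        raise InputError("similarity matrix must be square and labeled")
    n = S.shape[0]
    if n < 2:
        raise InputError("need at least two items to cluster")
    A = S.to_numpy(dtype=float)
    if not np.allclose(A, A.T):
        raise InputError("similarity matrix must be symmetric")
    off = A[~np.eye(n, dtype=bool)]
    shift = off.max() if off.size else 0.0
    D = shift - A
    np.fill_diagonal(D, 0.0)

    leaves = tuple(str(x) for x in S.index)
    active: dict[int, tuple[int, str]] = {
        i: (1, leaves[i]) for i in range(n)
    }  # id -> (size, min leaf label)
    dist: dict[frozenset, float] = {
        frozenset((i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                tuple(sorted(active[c][1] for c in kv[0])),
            ),
        )
        pair, h = best
        a, b = sorted(pair)
        sa, la = active[a]
        sb, lb = active[b]
        new = next_id
        next_id += 1
        for other in list(active):
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new, other))] = (sa * da + sb * db) / (sa + sb)
        dist.pop(pair)
        del active[a], active[b]
        active[new] = (sa + sb, min(la, lb))
        merges.append((a, b, h))
    return Dendrogram(leaves=leaves, merges=tuple(merges))


def cut_tree(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Partition induced by removing the k−1 highest merges.

    Returns leaf label -> cluster id, ids ordered by cluster size
    descending (ties by smallest leaf label).
    """
    n = len(dendrogram.leaves)
    if not (1 <= k <= n):
        raise BoundsError(f"k={k} out of range for {n} leaves")
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    for t, (a, b, _) in enumerate(dendrogram.merges[: n - k]):
        members[n + t] = members.pop(a) | members.pop(b)
    groups = sorted(
        (sorted(m) for m in members.values()), key=lambda m: (-len(m), m[0])
    )
    out: dict[str, int] = {}
    for cid, group in enumerate(groups):
        for i in group:
            out[dendrogram.leaves[i]] = cid
    return out


class StructureClustering(ClusterMixin, BaseEstimator):
    """Floor + symmetrize a Z-score matrix, average-linkage, cut at k.

    sklearn-style estimator over a precomputed labeled Z-score matrix;
    after ``fit``, ``labels_`` holds the k-cluster partition in row
    order and ``dendrogram_`` the full merge tree.
    """

    def __init__(self, n_clusters: int = 2, z_floor: float = 6.0):
        self.n_clusters = n_clusters
        self.z_floor = z_floor

    def fit(self, X, y=None):
        Z = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        S = preprocess_zmatrix(Z, StructureParams(self.z_floor))
        self.similarity_ = S
        self.dendrogram_ = average_linkage_tree(S)
        part = cut_tree(self.dendrogram_, self.n_clusters)
        self.index_ = [str(x) for x in S.index]
        self.labels_ = np.array([part[x] for x in self.index_])
        return self
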