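"""Domain-architecture strings, Damerau–Levenshtein distance, and MCL.

Each protein's significant (e-value < 1e-5), nonoverlapping domain hits
are turned into an ordered token string.  Architectures are compared
all-against-all by Damerau–Levenshtein distance (optimal-string-
alignment variant by default; the unrestricted algorithm is selectable),
clustered with the Markov Cluster Algorithm at inflation I = 8, and the
resulting clusters ranked by size to surface the most abundant
architectures per family.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import ConfigurationError, InputError


# ---------------------------------------------------------------------------
# architecture strings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureParams:
    """Significance filter and overlap policy for hit tables."""

    evalue_max: float = 1e-5

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ConfigurationError("evalue_max must be > 0")


@dataclass(frozen=True)
class ArchitectureString:
    """Ordered domain tokens of one protein (may be empty)."""

    protein_id: str
    tokens: tuple[str, ...]

    def __str__(self) -> str:
        return "+".join(self.tokens)


def build_architecture(
    hits: pd.DataFrame, params: ArchitectureParams | None = None
) -> ArchitectureString:
    """Nonoverlapping, position-ordered composition string for one protein.

    Hits at or above the e-value cutoff are dropped; the rest are made
    nonoverlapping by iteratively keeping the best-e-value hit (ties by
    earlier start, then token) and discarding anything overlapping it by
    at least one residue.  Survivors are ordered by start coordinate.
    """
    params = params or ArchitectureParams()
    pids = set(hits["protein_id"]) if len(hits) else set()
    if len(pids) > 1:
        raise InputError(f"hit table mixes proteins: {sorted(pids)}")
    pid = next(iter(pids)) if pids else ""

    rows = []
    for irow, row in enumerate(hits.itertuples(index=False)):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            raise InputError(f"row {irow}: non-integer coordinates")
        if start < 1 or end < start:
            raise InputError(
                f"row {irow}: malformed coordinates start={start} end={end}"
            )
        ev = float(row.e_value)
        if ev < params.evalue_max:
            rows.append((ev, start, str(row.domain_token), end))

    kept: list[tuple[int, int, str]] = []  # (start, end, token)
    for ev, start, token, end in sorted(rows):
        if all(end < ks or start > ke for ks, ke, _ in kept):
            kept.append((start, end, token))
    kept.sort()
    return ArchitectureString(pid, tuple(tok for _, _, tok in kept))


def build_architectures(
    hits: pd.DataFrame, params: ArchitectureParams | None = None
) -> list[ArchitectureString]:
    """One architecture per protein, in order of first appearance."""
    order = list(dict.fromkeys(hits["protein_id"]))
    groups = dict(tuple(g) for g in hits.groupby("protein_id", sort=False))
    return [build_architecture(groups[pid], params) for pid in order]


# ---------------------------------------------------------------------------
# Damerau–Levenshtein distance
# ---------------------------------------------------------------------------

def dl_distance(
    a: Sequence[str], b: Sequence[str], variant: str = "osa"
) -> int:
    """Edit distance with adjacent transpositions between token lists.

    ``variant="osa"`` (default) is the optimal-string-alignment
    restriction (no substring edited twice); ``variant="dl"`` is the
    unrestricted Damerau–Levenshtein algorithm.
    """
    if variant == "osa":
        return _osa_distance(tuple(a), tuple(b))
    if variant == "dl":
        return _true_dl_distance(tuple(a), tuple(b))
    raise InputError(f"unknown variant {variant!r}")


def _osa_distance(a: tuple, b: tuple) -> int:
    la, lb = len(a), len(b)
    d = np.zeros((la + 1, lb + 1), dtype=np.int64)
    d[:, 0] = np.arange(la + 1)
    d[0, :] = np.arange(lb + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i, j] = min(d[i - 1, j] + 1, d[i, j - 1] + 1, d[i - 1, j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i, j] = min(d[i, j], d[i - 2, j - 2] + 1)
    return int(d[la, lb])


def _true_dl_distance(a: tuple, b: tuple) -> int:
    # Lowrance–Wagner dynamic program with per-token last-occurrence table
    la, lb = len(a), len(b)
    maxdist = la + lb
    d = np.zeros((la + 2, lb + 2), dtype=np.int64)
    d[0, :] = maxdist
    d[:, 0] = maxdist
    d[1, 1:] = np.arange(lb + 1)
    d[1:, 1] = np.arange(la + 1)
    last_row: dict[str, int] = {}
    for i in range(1, la + 1):
        last_col = 0
        for j in range(1, lb + 1):
            i1 = last_row.get(b[j - 1], 0)
            j1 = last_col
            cost = 0 if a[i - 1] == b[j - 1] else 1
            if cost == 0:
                last_col = j
            d[i + 1, j + 1] = min(
                d[i, j] + cost,
                d[i + 1, j] + 1,
                d[i, j + 1] + 1,
                d[i1, j1] + (i - i1 - 1) + 1 + (j - j1 - 1),
            )
        last_row[a[i - 1]] = i
    return int(d[la + 1, lb + 1])


def architecture_distance_matrix(
    strings: Sequence[ArchitectureString], variant: str = "osa"
) -> pd.DataFrame:
    """Symmetric integer DL-distance matrix over architecture strings."""
    if not strings:
        raise InputError("need at least one architecture string")
    ids = [s.protein_id for s in strings]
    n = len(strings)
    D = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dl_distance(
                strings[i].tokens, strings[j].tokens, variant
            )
    return pd.DataFrame(D, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCLParams:
    """Markov Cluster Algorithm settings (inflation I = 8 by default)."""

    inflation: float = 8.0
    expansion: int = 2
    prune_threshold: float = 1e-6
    max_iterations: int = 200
    convergence_tol: float = 1e-8

    def __post_init__(self):
        if self.inflation <= 1:
            raise ConfigurationError("inflation must be > 1")
        if self.expansion < 2:
            raise ConfigurationError("expansion must be >= 2")


class MarkovClustering(ClusterMixin, BaseEstimator):
    """MCL over a precomputed nonnegative distance matrix.

    Distances are mapped to similarities ``s = 1/(1+d)`` with unit
    self-loops, columns are normalized to a stochastic matrix, and
    expansion (matrix power) alternates with inflation (entrywise power
    + renormalization) and pruning until the iterate stabilizes.
    Clusters are the connected components of the converged attractor
    structure; labels are ordered by cluster size descending, ties by
    smallest member index.
    """

    def __init__(
        self,
        inflation: float = 8.0,
        expansion: int = 2,
        prune_threshold: float = 1e-6,
        max_iterations: int = 200,
        convergence_tol: float = 1e-8,
    ):
        self.inflation = inflation
        self.expansion = expansion
        self.prune_threshold = prune_threshold
        self.max_iterations = max_iterations
        self.convergence_tol = convergence_tol

    def fit(self, X, y=None, on_iteration=None):
        MCLParams(
            self.inflation, self.expansion, self.prune_threshold,
            self.max_iterations, self.convergence_tol,
        )
        D = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        labels_idx = (
            [str(c) for c in X.index] if isinstance(X, pd.DataFrame)
            else [str(i) for i in range(D.shape[0])]
        )
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise InputError("distance matrix must be square")
        if not np.allclose(D, D.T):
            raise InputError("distance matrix must be symmetric")
        if (D < 0).any():
            raise InputError("distances must be nonnegative")
        n = D.shape[0]

        M = 1.0 / (1.0 + D)
        np.fill_diagonal(M, 1.0)
        M = M / M.sum(axis=0, keepdims=True)
        it = 0
        for it in range(1, self.max_iterations + 1):
            prev = M
            M = np.linalg.matrix_power(M, self.expansion)
            M = np.power(M, self.inflation)
            M = M / M.sum(axis=0, keepdims=True)
            M[M < self.prune_threshold] = 0.0  # prune after renormalizing
            M = M / M.sum(axis=0, keepdims=True)
            if on_iteration is not None:
                on_iteration(M.copy())
            if np.abs(M - prev).max() < self.convergence_tol:
                break
        self.n_iter_ = it
        self.matrix_ = M

        support = nx.Graph()
        support.add_nodes_from(range(n))
        ii, jj = np.nonzero(M > self.prune_threshold)
        support.add_edges_from((int(i), int(j)) for i, j in zip(ii, jj) if i != j)
        comps = sorted(
            (sorted(c) for c in nx.connected_components(support)),
            key=lambda c: (-len(c), c[0]),
        )
        labels = np.empty(n, dtype=np.int64)
        for cid, comp in enumerate(comps):
            labels[comp] = cid
        self.labels_ = labels
        self.index_ = labels_idx
        return self


def mcl_cluster(
    distances: pd.DataFrame | np.ndarray,
    params: MCLParams | None = None,
    on_iteration=None,
) -> dict[str, int]:
    """Functional wrapper over :class:`MarkovClustering`; id -> cluster."""
    params = params or MCLParams()
    est = MarkovClustering(
        inflation=params.inflation,
        expansion=params.expansion,
        prune_threshold=params.prune_threshold,
        max_iterations=params.max_iterations,
        convergence_tol=params.convergence_tol,
    )
    est.fit(distances, on_iteration=on_iteration)
    return dict(zip(est.index_, (int(v) for v in est.labels_)))


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedArchitecture:
    cluster: int
    size: int
    consensus: tuple[str, ...]


def rank_architectures(
    partition: Mapping[str, int], strings: Sequence[ArchitectureString]
) -> list[RankedArchitecture]:
    """Clusters sorted by size (desc, ties by smallest member id), with the
    most frequent exact token sequence of each cluster as its consensus."""
    by_id = {s.protein_id: s for s in strings}
    missing = [pid for pid in by_id if pid not in partition]
    if missing:
        raise InputError(f"partition does not cover: {sorted(missing)[:5]}")
    clusters: dict[int, list[str]] = {}
    for pid in by_id:
        clusters.setdefault(partition[pid], []).append(pid)
    ranked = sorted(clusters.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    out = []
    for cid, members in ranked:
        counts = Counter(by_id[pid].tokens for pid in members)
        # ties by lexicographically smallest token sequence
        best_count = max(counts.values())
        consensus = min(t for t, c in counts.items() if c == best_count)
        out.append(RankedArchitecture(cid, len(members), consensus))
    return out
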