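"""All-against-all similarity, CLANS-style layout, and threshold clustering.

Pairwise significance is computed by exact Smith–Waterman local
alignment (BLOSUM62, affine gaps) converted to a *P*-value through the
Karlin–Altschul form ``E = K·m·n·exp(−λS)``, ``p = 1 − exp(−E)`` with
configurable calibration constants.  The similarity graph is embedded by
a Fruchterman–Reingold-style force simulation (attraction proportional
to ``−log10 p`` along significant edges, repulsion between all pairs),
and clusters are extracted as connected components of the subgraph at a
*P*-value threshold — the reproducible analog of reading clusters off a
CLANS map.  Redundancy reduction follows the greedy incremental scheme
of CD-HIT-style tools at an 80% identity default, and per-cluster
representative selection prefers structurally characterized / curated
members first, then maximal dissimilarity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from .errors import ConfigurationError, InputError
from .graph import SimilarityGraph
from .records import SequenceRecord

logger = logging.getLogger(__name__)

UNASSIGNED = -1

#: cap on the attractive edge weight −log10(p)
_LOG_P_CAP = 200.0
#: smallest representable p-value (avoids log(0) after underflow)
_P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# pairwise significance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringParams:
    """Local-alignment scoring and Karlin–Altschul calibration constants."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    K: float = 0.041
    lam: float = 0.267

    def make_aligner(self, mode: str = "local") -> PairwiseAligner:
        aligner = PairwiseAligner(
            mode=mode,
            substitution_matrix=substitution_matrices.load(self.matrix),
            open_gap_score=-abs(self.gap_open),
            extend_gap_score=-abs(self.gap_extend),
        )
        return aligner


def karlin_altschul_p(score: float, m: int, n: int, params: ScoringParams) -> float:
    """P-value of a local alignment score via E = K·m·n·exp(−λS)."""
    E = params.K * m * n * math.exp(-params.lam * score)
    p = -math.expm1(-E)
    return max(p, _P_FLOOR)


def pairwise_similarity(
    records: Sequence[SequenceRecord],
    scoring: ScoringParams | None = None,
) -> SimilarityGraph:
    """Exact all-vs-all local alignment graph with Karlin–Altschul p-values.

    Pairs whose p-value rounds up to 1.0 get no edge.
    """
    scoring = scoring or ScoringParams()
    if len(records) < 2:
        raise InputError("need at least two records")
    for r in records:
        if not r.seq:
            raise InputError(f"record {r.id!r} has an empty sequence")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate record ids")
    aligner = scoring.make_aligner("local")
    graph = SimilarityGraph(ids)
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            score = aligner.score(a.seq, b.seq)
            p = karlin_altschul_p(score, len(a.seq), len(b.seq), scoring)
            if p < 1.0:
                graph.add_edge(a.id, b.id, p, score=score)
    return graph


# ---------------------------------------------------------------------------
# force-directed layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayoutParams:
    """Force-simulation settings for the CLANS-style embedding."""

    dims: int = 2
    p_threshold: float = 1.0  # edges with larger p exert no attraction
    attraction_scale: float = 1.0
    repulsion_scale: float = 1.0
    step_size: float = 0.1
    max_iterations: int = 500
    convergence_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.dims not in (2, 3):
            raise ConfigurationError("dims must be 2 or 3")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ConfigurationError("convergence_tol must be > 0")


@dataclass
class Embedding:
    """Result of the force-directed layout."""

    coordinates: dict[str, np.ndarray]
    iterations_run: int
    final_mean_displacement: float
    mean_displacements: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        nodes = list(self.coordinates)
        arr = np.vstack([self.coordinates[n] for n in nodes])
        cols = ["x", "y", "z"][: arr.shape[1]]
        return pd.DataFrame(arr, index=nodes, columns=cols)

    def distance(self, u: str, v: str) -> float:
        return float(np.linalg.norm(self.coordinates[u] - self.coordinates[v]))


class ClansEmbedding(TransformerMixin, BaseEstimator):
    """Force-directed 2D/3D embedding of a sequence-similarity graph.

    sklearn-style transformer over a precomputed p-value matrix or a
    :class:`~rnhl.graph.SimilarityGraph`.  Attraction along each
    significant edge is proportional to ``min(−log10 p, 200)`` times the
    current distance; repulsion between every node pair decays as
    1/distance; per-iteration displacement is capped by a step size
    annealed linearly to zero.
    """

    def __init__(
        self,
        dims: int = 2,
        p_threshold: float = 1.0,
        attraction_scale: float = 1.0,
        repulsion_scale: float = 1.0,
        step_size: float = 0.1,
        max_iterations: int = 500,
        convergence_tol: float = 1e-4,
        seed: int = 0,
    ):
        self.dims = dims
        self.p_threshold = p_threshold
        self.attraction_scale = attraction_scale
        self.repulsion_scale = repulsion_scale
        self.step_size = step_size
        self.max_iterations = max_iterations
        self.convergence_tol = convergence_tol
        self.seed = seed

    def _params(self) -> LayoutParams:
        return LayoutParams(
            dims=self.dims,
            p_threshold=self.p_threshold,
            attraction_scale=self.attraction_scale,
            repulsion_scale=self.repulsion_scale,
            step_size=self.step_size,
            max_iterations=self.max_iterations,
            convergence_tol=self.convergence_tol,
            seed=self.seed,
        )

    def fit(self, X, y=None):
        """Run the force simulation.  X: SimilarityGraph or p-value DataFrame."""
        nodes, weights = _attraction_weights(X, self._params())
        params = self._params()
        n = len(nodes)
        if n == 0:
            raise InputError("empty graph")
        rng = np.random.default_rng(params.seed)
        pos = rng.uniform(0.0, 1.0, size=(n, params.dims))
        if weights.sum() == 0 and n > 1:
            logger.warning(
                "no significant edges at p <= %g; layout is repulsion-only",
                params.p_threshold,
            )
        mean_disp = 0.0
        history: list[float] = []
        it = 0
        for it in range(1, params.max_iterations + 1):
            temp = params.step_size * (1.0 - (it - 1) / params.max_iterations)
            diff = pos[None, :, :] - pos[:, None, :]  # diff[i, j] = xj - xi
            dist = np.linalg.norm(diff, axis=-1)
            np.fill_diagonal(dist, np.inf)
            dist = np.maximum(dist, 1e-9)  # coincident points
            unit = diff / dist[..., None]
            dist_att = np.where(np.isfinite(dist), dist, 0.0)  # no self-terms
            # attraction toward neighbours, repulsion from everyone
            force = (params.attraction_scale * weights * dist_att)[..., None] * unit
            force -= (params.repulsion_scale / dist)[..., None] * unit
            net = force.sum(axis=1)
            norm = np.linalg.norm(net, axis=-1, keepdims=True)
            cap = np.minimum(norm, temp)
            step = np.where(norm > 0, net / np.maximum(norm, 1e-12) * cap, 0.0)
            pos = pos + step
            mean_disp = float(np.linalg.norm(step, axis=-1).mean())
            history.append(mean_disp)
            if mean_disp < params.convergence_tol:
                break
        self.nodes_ = nodes
        self.embedding_ = Embedding(
            coordinates={node: pos[i].copy() for i, node in enumerate(nodes)},
            iterations_run=it,
            final_mean_displacement=mean_disp,
            mean_displacements=history,
        )
        return self

    def transform(self, X=None):
        return np.vstack([self.embedding_.coordinates[n] for n in self.nodes_])


def _attraction_weights(X, params: LayoutParams) -> tuple[list[str], np.ndarray]:
    """Symmetric matrix of capped −log10(p) attraction weights."""
    if isinstance(X, SimilarityGraph):
        nodes = X.nodes
        idx = {n: i for i, n in enumerate(nodes)}
        W = np.zeros((len(nodes), len(nodes)))
        for u, v, p in X.edges():
            if p <= params.p_threshold:
                w = min(-math.log10(max(p, _P_FLOOR)), _LOG_P_CAP)
                W[idx[u], idx[v]] = W[idx[v], idx[u]] = w
        return nodes, W
    P = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    nodes = [str(c) for c in P.index]
    arr = P.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise InputError("p-value matrix must be square")
    with np.errstate(divide="ignore"):
        W = np.minimum(-np.log10(np.maximum(arr, _P_FLOOR)), _LOG_P_CAP)
    W[arr > params.p_threshold] = 0.0
    np.fill_diagonal(W, 0.0)
    W = np.maximum(W, 0.0)
    return nodes, (W + W.T) / 2.0


def clans_layout(graph: SimilarityGraph, params: LayoutParams | None = None) -> Embedding:
    """Functional wrapper over :class:`ClansEmbedding`."""
    params = params or LayoutParams()
    est = ClansEmbedding(
        dims=params.dims,
        p_threshold=params.p_threshold,
        attraction_scale=params.attraction_scale,
        repulsion_scale=params.repulsion_scale,
        step_size=params.step_size,
        max_iterations=params.max_iterations,
        convergence_tol=params.convergence_tol,
        seed=params.seed,
    )
    est.fit(graph)
    return est.embedding_


# ---------------------------------------------------------------------------
# threshold cluster extraction
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Node -> cluster id (or UNASSIGNED = -1) at one p-value threshold."""

    labels: dict[str, int]
    threshold_used: float

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, lab in self.labels.items():
            if lab != UNASSIGNED:
                out.setdefault(lab, set()).add(node)
        return out

    def n_unassigned(self) -> int:
        return sum(1 for v in self.labels.values() if v == UNASSIGNED)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["id", "cluster"]
        ).assign(threshold=self.threshold_used)


class ThresholdClustering(ClusterMixin, BaseEstimator):
    """Connected-component clustering of the similarity graph at a p cutoff.

    Clusters are the size->=2 connected components of the subgraph
    keeping edges with ``p <= p_threshold``; singletons are UNASSIGNED
    (-1).  Cluster ids are assigned in decreasing component size, ties
    broken by smallest member id.
    """

    def __init__(self, p_threshold: float = 1e-12):
        self.p_threshold = p_threshold

    def fit(self, X, y=None):
        if self.p_threshold <= 0:
            raise ConfigurationError("p_threshold must be > 0")
        if isinstance(X, SimilarityGraph):
            sub = X.subgraph_at(self.p_threshold)
        else:
            P = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
            sub = nx.Graph()
            nodes = [str(c) for c in P.index]
            sub.add_nodes_from(nodes)
            arr = P.to_numpy(dtype=float)
            for i in range(len(nodes)):
                for j in range(i + 1, len(nodes)):
                    if arr[i, j] <= self.p_threshold:
                        sub.add_edge(nodes[i], nodes[j])
        components = [set(c) for c in nx.connected_components(sub)]
        real = sorted(
            (c for c in components if len(c) >= 2),
            key=lambda c: (-len(c), min(c)),
        )
        labels: dict[str, int] = {n: UNASSIGNED for n in sub.nodes}
        for cid, comp in enumerate(real):
            for node in comp:
                labels[node] = cid
        self.assignment_ = ClusterAssignment(labels, self.p_threshold)
        self.nodes_ = sorted(labels)
        self.labels_ = np.array([labels[n] for n in self.nodes_])
        return self


def calibrate_threshold(graph: SimilarityGraph, default: float = 1e-12) -> float:
    """Data-driven clustering threshold from the edge p-value distribution.

    The reproducible analog of choosing a cutoff by eye on a CLANS map:
    if the log10 p-values are clearly bimodal (widest consecutive gap
    spanning at least two orders of magnitude), the threshold is placed
    mid-gap; otherwise the conventional default is returned.
    """
    logs = sorted(math.log10(p) for _, _, p in graph.edges())
    if len(logs) < 2:
        return default
    width, lo, hi = max(
        (b - a, a, b) for a, b in zip(logs, logs[1:])
    )
    if width < 2.0:
        return default
    return 10 ** ((lo + hi) / 2.0)


def extract_clusters(graph: SimilarityGraph, p_threshold: float) -> ClusterAssignment:
    """Functional wrapper over :class:`ThresholdClustering`."""
    return ThresholdClustering(p_threshold).fit(graph).assignment_


def nested_clusters(
    graph: SimilarityGraph, thresholds: Sequence[float]
) -> list[ClusterAssignment]:
    """Cluster at a strictly decreasing ladder of thresholds (loose→strict).

    Partitions are automatically nested because each stricter subgraph
    is a subgraph of the looser one.
    """
    thresholds = list(thresholds)
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise InputError("thresholds must be strictly decreasing")
    return [extract_clusters(graph, t) for t in thresholds]


# ---------------------------------------------------------------------------
# redundancy reduction and representative selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RedundancyParams:
    identity_threshold: float = 0.80

    def __post_init__(self):
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ConfigurationError("identity_threshold must be in (0, 1]")


def global_identity(
    a: str, b: str, scoring: ScoringParams | None = None
) -> float:
    """Exact matches in a global alignment over the shorter length."""
    scoring = scoring or ScoringParams()
    aligner = scoring.make_aligner("global")
    alignment = aligner.align(a, b)[0]
    return alignment.counts().identities / min(len(a), len(b))


def reduce_redundancy(
    records: Sequence[SequenceRecord],
    params: RedundancyParams | None = None,
    scoring: ScoringParams | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Greedy incremental redundancy reduction (CD-HIT-style).

    Sequences are processed longest-first (ties by id); each joins the
    first existing representative with identity >= threshold, otherwise
    it founds a new representative.  Returns (representative ids,
    member id -> representative id for the removed sequences).
    """
    params = params or RedundancyParams()
    if not records:
        raise InputError("empty record list")
    by_id = {r.id: r for r in records}
    order = sorted(records, key=lambda r: (-len(r.seq), r.id))
    reps: list[str] = []
    membership: dict[str, str] = {}
    for rec in order:
        placed = False
        for rep in reps:
            if (
                global_identity(rec.seq, by_id[rep].seq, scoring)
                >= params.identity_threshold
            ):
                membership[rec.id] = rep
                placed = True
                break
        if not placed:
            reps.append(rec.id)
    return reps, membership


@dataclass(frozen=True)
class RepresentativeParams:
    n_per_cluster: int = 2
    preference_order: tuple[str, ...] = ("has_structure", "curated_annotation")

    def __post_init__(self):
        if self.n_per_cluster < 1:
            raise ConfigurationError("n_per_cluster must be >= 1")


def select_representatives(
    assignment: ClusterAssignment,
    metadata: Mapping[str, Mapping[str, bool]],
    params: RepresentativeParams | None = None,
    sequences: Mapping[str, str] | None = None,
    scoring: ScoringParams | None = None,
) -> dict[int, list[str]]:
    """Pick representatives per cluster: preferred flags first, then diversity.

    The first representative maximizes the preference flags in order
    (ties by smallest id).  Each subsequent one is the member with the
    lowest maximal pairwise identity to those already chosen — the most
    dissimilar remaining sequence — which requires ``sequences``.
    Clusters smaller than ``n_per_cluster`` return all members.
    """
    params = params or RepresentativeParams()
    missing = [
        n for n, lab in assignment.labels.items()
        if lab != UNASSIGNED and n not in metadata
    ]
    if missing:
        raise InputError(f"metadata missing for ids: {sorted(missing)[:5]} ...")
    out: dict[int, list[str]] = {}
    for cid, members in sorted(assignment.clusters().items()):
        if not members:
            logger.warning("cluster %s is empty; skipped", cid)
            continue
        if len(members) <= params.n_per_cluster:
            out[cid] = sorted(members)
            continue

        def pref_key(sid: str):
            flags = metadata[sid]
            return tuple(
                0 if flags.get(f, False) else 1 for f in params.preference_order
            ) + (sid,)

        chosen = [min(members, key=pref_key)]
        remaining = sorted(members - {chosen[0]})
        while len(chosen) < params.n_per_cluster and remaining:
            if sequences is None:
                raise InputError(
                    "sequences are required to pick dissimilarity-based "
                    "secondary representatives"
                )
            best = min(
                remaining,
                key=lambda sid: (
                    max(
                        global_identity(sequences[sid], sequences[c], scoring)
                        for c in chosen
                    ),
                    sid,
                ),
            )
            chosen.append(best)
            remaining.remove(best)
        out[cid] = chosen
    return out
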