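"""Desk-scale combined-evidence tree inference and clade scoring.

The combined character matrix (sequence + weighted morphological
columns) is summarized as a multiplicity-weighted mismatch distance,
a family tree is inferred by neighbor joining, and branch confidence is
estimated by bootstrap resampling of the expanded columns.  This is the
reproducible in-repo substitute for a 10-million-generation Bayesian
analysis on the same matrix: the full-fidelity NEXUS export for
external MCMC software lives in :mod:`rnhl.encoding`.  Planted clades
are scored as recovered when they appear as bipartitions of the
unrooted tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .encoding import GAP, MISSING, CharacterMatrix
from .errors import InputError

#: supports below this are hidden in reports (display only, not computation)
SUPPORT_DISPLAY_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# tree container
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths and optional bipartition supports."""

    tree: dendropy.Tree
    support: dict[frozenset, float] | None = None

    @property
    def taxa(self) -> frozenset:
        return frozenset(l.taxon.label for l in self.tree.leaf_node_iter())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as the side not containing the
        lexicographically smallest taxon."""
        all_taxa = self.taxa
        n = len(all_taxa)
        ref = min(all_taxa)
        out: set[frozenset] = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if ref in side:
                side = all_taxa - side
            if 2 <= len(side) <= n - 2:
                out.add(side)
        return out

    def canonical_split(self, taxa: Iterable) -> frozenset:
        side = frozenset(taxa)
        if min(self.taxa) in side:
            side = self.taxa - side
        return side

    def rf_distance(self, other: "PhyloTree") -> int:
        if self.taxa != other.taxa:
            raise InputError("taxon sets differ")
        return len(self.bipartitions() ^ other.bipartitions())

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip()


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _state_codes(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Integer-coded states (missing/gap = -1) and column multiplicities."""
    n = len(matrix.taxa)
    C = len(matrix.columns)
    X = np.empty((n, C), dtype=np.int64)
    w = np.empty(C, dtype=np.float64)
    for c, col in enumerate(matrix.columns):
        symbols = {}
        for t, s in enumerate(col.states):
            if s in (GAP, MISSING):
                X[t, c] = -1
            else:
                X[t, c] = symbols.setdefault(s, len(symbols))
        w[c] = col.multiplicity
    return X, w


def combined_distance(matrix: CharacterMatrix) -> pd.DataFrame:
    """Multiplicity-weighted mismatch fraction between every taxon pair.

    Columns where either taxon is gapped or missing are excluded
    pairwise; a pair with no comparable columns is an error.
    """
    if len(matrix.taxa) < 3:
        raise InputError("need at least three taxa")
    X, w = _state_codes(matrix)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = (X[i] >= 0) & (X[j] >= 0)
            denom = w[comp].sum()
            if denom == 0:
                raise InputError(
                    f"taxa {matrix.taxa[i]!r} and {matrix.taxa[j]!r} share no "
                    "comparable columns"
                )
            mism = w[comp & (X[i] != X[j])].sum()
            D[i, j] = D[j, i] = mism / denom
    return pd.DataFrame(D, index=matrix.taxa, columns=matrix.taxa)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: pd.DataFrame) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are resolved toward the pair whose clusters
    carry the smallest leaf labels; negative branch lengths are clamped
    to zero with the deficit moved to the sibling branch.  Exact on
    additive distances.
    """
    if D.shape[0] != D.shape[1] or list(D.index) != list(D.columns):
        raise InputError("distance matrix must be square with matching labels")
    if not np.allclose(D.to_numpy(), D.to_numpy().T):
        raise InputError("distance matrix must be symmetric")
    labels = [str(x) for x in D.index]
    if len(labels) < 3:
        raise InputError("need at least three taxa")

    ns = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(node)
    mins = list(labels)  # min leaf label per active cluster
    M = D.to_numpy(dtype=float).copy()

    def attach(parent: dendropy.Node, child: dendropy.Node, length: float):
        parent.add_child(child)
        child.edge.length = max(0.0, float(length))

    while len(nodes) > 3:
        n = len(nodes)
        r = M.sum(axis=1)
        Q = (n - 2) * M - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-10)
        i, j = min(
            ((int(a), int(b)) for a, b in ties if a < b),
            key=lambda ij: tuple(sorted((mins[ij[0]], mins[ij[1]]))),
        )
        li = M[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = M[i, j] - li
        if li < 0:
            lj, li = M[i, j], 0.0
        if lj < 0:
            li, lj = M[i, j], 0.0
        parent = dendropy.Node()
        attach(parent, nodes[i], li)
        attach(parent, nodes[j], lj)
        newrow = (M[i] + M[j] - M[i, j]) / 2.0
        keep = [k for k in range(n) if k not in (i, j)]
        M = np.vstack([M[keep][:, keep], newrow[keep][None, :]])
        M = np.hstack([M, np.append(newrow[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        mins = [mins[k] for k in keep] + [min(mins[i], mins[j])]

    la = (M[0, 1] + M[0, 2] - M[1, 2]) / 2.0
    lb = (M[0, 1] + M[1, 2] - M[0, 2]) / 2.0
    lc = (M[0, 2] + M[1, 2] - M[0, 1]) / 2.0
    root = dendropy.Node()
    for node, length in zip(nodes, (la, lb, lc)):
        attach(root, node, length)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree=tree)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    matrix: CharacterMatrix,
    n_replicates: int = 100,
    seed: int = 0,
    resample: bool = True,
) -> PhyloTree:
    """NJ tree with bootstrap supports from multiplicity-aware resampling.

    Each column contributes ``multiplicity`` resampling tickets; every
    replicate draws expanded-width tickets with replacement, rebuilds
    the weighted distance matrix and the NJ tree, and the support of
    each original bipartition is the fraction of replicates containing
    it.  ``resample=False`` runs identity replicates (all supports 1).
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    base = neighbor_joining(combined_distance(matrix))
    base_bips = base.bipartitions()

    X, w = _state_codes(matrix)
    n, C = X.shape
    comp = (X[:, None, :] >= 0) & (X[None, :, :] >= 0)  # n x n x C
    mism = comp & (X[:, None, :] != X[None, :, :])
    tickets = np.repeat(np.arange(C), w.astype(np.int64))
    W = len(tickets)
    rng = np.random.default_rng(seed)
    labels = list(matrix.taxa)

    counts_list = []
    for _ in range(n_replicates):
        if resample:
            draw = tickets[rng.integers(0, W, size=W)]
            counts_list.append(np.bincount(draw, minlength=C).astype(float))
        else:
            counts_list.append(w.copy())

    hits = {bip: 0 for bip in base_bips}
    for counts in counts_list:
        denom = np.einsum("ijc,c->ij", comp, counts)
        num = np.einsum("ijc,c->ij", mism, counts)
        with np.errstate(invalid="ignore", divide="ignore"):
            Drep = np.where(denom > 0, num / np.maximum(denom, 1e-300), 1.0)
        np.fill_diagonal(Drep, 0.0)
        rep_tree = neighbor_joining(
            pd.DataFrame(Drep, index=labels, columns=labels)
        )
        for bip in rep_tree.bipartitions() & base_bips:
            hits[bip] += 1

    support = {bip: hits[bip] / n_replicates for bip in base_bips}
    # annotate internal nodes for Newick output
    all_taxa = base.taxa
    ref = min(all_taxa)
    for node in base.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_taxa - side
        if side in support:
            node.label = f"{support[side]:.3f}"
    base.support = support
    return base


# ---------------------------------------------------------------------------
# clade scoring
# ---------------------------------------------------------------------------

@dataclass
class CladeReport:
    """Recovery of planted clades on the inferred tree."""

    clades: dict[str, frozenset]
    recovered: dict[str, bool]
    support: dict[str, float | None]
    rf_distance: int | None = None

    @property
    def n_recovered(self) -> int:
        return sum(self.recovered.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.clades:
            s = self.support[name]
            rows.append(
                {
                    "clade": name,
                    "size": len(self.clades[name]),
                    "recovered": self.recovered[name],
                    "support": (
                        s if s is not None and s > SUPPORT_DISPLAY_THRESHOLD else None
                    ),
                }
            )
        return pd.DataFrame(rows)


def compare_clades(
    tree: PhyloTree,
    truth: Mapping[str, Iterable] | PhyloTree,
) -> CladeReport:
    """Score planted clades (or a full truth topology) against a tree.

    A planted clade is recovered iff its taxon set appears as a
    bipartition of the unrooted tree; Robinson–Foulds distance is
    reported when a truth tree is given.
    """
    if isinstance(truth, PhyloTree):
        rf = tree.rf_distance(truth)
        clades = {
            f"split_{k}": bip for k, bip in enumerate(sorted(truth.bipartitions(), key=sorted))
        }
    else:
        rf = None
        clades = {str(name): frozenset(members) for name, members in truth.items()}
        for name, members in clades.items():
            extra = members - tree.taxa
            if extra:
                raise InputError(f"clade {name!r} has unknown taxa: {sorted(extra)}")
    bips = tree.bipartitions()
    recovered: dict[str, bool] = {}
    support: dict[str, float | None] = {}
    for name, members in clades.items():
        side = tree.canonical_split(members)
        recovered[name] = side in bips
        support[name] = (
            tree.support.get(side) if (tree.support and recovered[name]) else None
        )
    return CladeReport(clades=clades, recovered=recovered, support=support, rf_distance=rf)
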