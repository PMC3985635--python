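"""The all-against-all sequence-similarity graph.

Nodes are sequence identifiers; an edge carries the significance
(*P*-value) of the best local alignment between the two sequences and,
when available, the raw alignment score it was derived from.  The graph
is the substrate both for the force-directed layout and for threshold
cluster extraction.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError


class SimilarityGraph:
    """Undirected graph of pairwise alignment significances.

    Invariants: no self-edges, at most one edge per unordered pair,
    every ``p`` in ``(0, 1]``.
    """

    def __init__(self, nodes: Iterable[str] = ()):
        self._g = nx.Graph()
        self._g.add_nodes_from(nodes)

    # -- construction -------------------------------------------------
    def add_node(self, node: str) -> None:
        self._g.add_node(node)

    def add_edge(self, u: str, v: str, p: float, score: float | None = None) -> None:
        if u == v:
            raise InputError(f"self-edge on node {u!r} is not allowed")
        if not (0.0 < p <= 1.0):
            raise InputError(f"p-value {p!r} for edge ({u}, {v}) outside (0, 1]")
        self._g.add_edge(u, v, p=float(p), score=score)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], nodes: Iterable[str] = ()
    ) -> "SimilarityGraph":
        g = cls(nodes)
        for u, v, p in edges:
            g.add_edge(u, v, p)
        return g

    # -- queries -------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def p(self, u: str, v: str) -> float | None:
        """P-value of edge (u, v), or None if absent."""
        data = self._g.get_edge_data(u, v)
        return None if data is None else data["p"]

    def score(self, u: str, v: str) -> float | None:
        data = self._g.get_edge_data(u, v)
        return None if data is None else data.get("score")

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, data in self._g.edges(data=True):
            yield u, v, data["p"]

    def subgraph_at(self, p_threshold: float) -> nx.Graph:
        """networkx view keeping only edges with p <= threshold."""
        keep = [
            (u, v) for u, v, data in self._g.edges(data=True) if data["p"] <= p_threshold
        ]
        sub = nx.Graph()
        sub.add_nodes_from(self._g.nodes)
        sub.add_edges_from(keep)
        return sub

    def p_matrix(self, order: list[str] | None = None) -> pd.DataFrame:
        """Dense symmetric matrix of p-values; missing edges are 1.0."""
        order = self.nodes if order is None else list(order)
        idx = {n: i for i, n in enumerate(order)}
        mat = np.ones((len(order), len(order)))
        for u, v, p in self.edges():
            if u in idx and v in idx:
                mat[idx[u], idx[v]] = mat[idx[v], idx[u]] = p
        np.fill_diagonal(mat, 0.0)
        return pd.DataFrame(mat, index=order, columns=order)

    # -- IO ------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        rows = [(u, v, p) for u, v, p in self.edges()]
        pd.DataFrame(rows, columns=["id1", "id2", "p_value"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, nodes: Iterable[str] = ()) -> "SimilarityGraph":
        df = pd.read_csv(path, sep="\t")
        required = {"id1", "id2", "p_value"}
        if not required.issubset(df.columns):
            raise InputError(
                f"edge table {path} must have columns {sorted(required)}"
            )
        g = cls(nodes)
        for row in df.itertuples(index=False):
            g.add_edge(str(row.id1), str(row.id2), float(row.p_value))
        return g
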