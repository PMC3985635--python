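"""Similarity graph, layout, threshold clustering, redundancy, representatives."""

import math

import numpy as np
import pytest

from rnhl.errors import InputError
from rnhl.graph import SimilarityGraph
from rnhl.records import SequenceRecord
from rnhl.similarity import (
    UNASSIGNED,
    ClusterAssignment,
    LayoutParams,
    RedundancyParams,
    RepresentativeParams,
    ScoringParams,
    calibrate_threshold,
    clans_layout,
    extract_clusters,
    global_identity,
    karlin_altschul_p,
    nested_clusters,
    pairwise_similarity,
    reduce_redundancy,
    select_representatives,
)


def _records(seqs):
    return [SequenceRecord(id=f"s{i}", seq=s) for i, s in enumerate(seqs)]


class TestPairwiseSimilarity:
    def test_identical_pair_more_significant_than_random(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        ident = "".join(rng.choice(aa, 300))
        r1, r2 = "".join(rng.choice(aa, 300)), "".join(rng.choice(aa, 300))
        g = pairwise_similarity(_records([ident, ident, r1, r2]))
        p_same = g.p("s0", "s1")
        p_rand = g.p("s2", "s3") or 1.0  # may have been dropped as p ~ 1
        assert p_same < p_rand

    def test_order_invariance(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        a, b = ("".join(rng.choice(aa, 150)) for _ in range(2))
        g1 = pairwise_similarity(_records([a, b]))
        g2 = pairwise_similarity(_records([b, a]))
        assert g1.p("s0", "s1") == g2.p("s0", "s1")

    def test_p_value_matches_karlin_altschul_arithmetic(self, rng):
        """Recompute p = 1 - exp(-K m n exp(-lambda S)) from the raw score."""
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        a, b = ("".join(rng.choice(aa, 120)) for _ in range(2))
        scoring = ScoringParams()
        g = pairwise_similarity(_records([a, b]), scoring)
        S = g.score("s0", "s1")
        p = g.p("s0", "s1")
        E = scoring.K * 120 * 120 * math.exp(-scoring.lam * S)
        assert p == pytest.approx(1.0 - math.exp(-E), rel=1e-9)

    def test_empty_sequence_names_record(self):
        with pytest.raises(InputError, match="bad"):
            pairwise_similarity(
                [SequenceRecord("ok", "ACDEF"), SequenceRecord("bad", "")]
            )


class TestClansLayout:
    def test_strong_edge_pulls_nodes_together(self):
        g = SimilarityGraph(["a", "b"])
        g.add_edge("a", "b", 1e-30)
        params = LayoutParams(seed=4, max_iterations=300)
        rng = np.random.default_rng(params.seed)
        initial = rng.uniform(0, 1, (2, 2))
        d0 = float(np.linalg.norm(initial[0] - initial[1]))
        emb = clans_layout(g, params)
        assert emb.distance("a", "b") < d0

    def test_single_node_unmoved(self):
        g = SimilarityGraph(["only"])
        params = LayoutParams(seed=9)
        emb = clans_layout(g, params)
        expected = np.random.default_rng(9).uniform(0, 1, (1, 2))
        assert np.allclose(emb.coordinates["only"], expected[0])
        assert emb.final_mean_displacement == 0.0

    def test_planted_families_separate(self):
        """Three 4-node cliques at p=1e-20, no cross edges: within-family
        mean distance < between-family mean distance, for 5 seeds."""
        nodes = [f"f{i}_{j}" for i in range(3) for j in range(4)]
        g = SimilarityGraph(nodes)
        for i in range(3):
            for j in range(4):
                for k in range(j + 1, 4):
                    g.add_edge(f"f{i}_{j}", f"f{i}_{k}", 1e-20)
        for seed in range(5):
            emb = clans_layout(g, LayoutParams(seed=seed, max_iterations=400))
            within, between = [], []
            for a in nodes:
                for b in nodes:
                    if a < b:
                        (within if a[:2] == b[:2] else between).append(
                            emb.distance(a, b)
                        )
            assert np.mean(within) < np.mean(between)

    def test_annealing_caps_displacement(self):
        """With strong forces the capped step follows the linearly annealed
        temperature, so displacement is non-increasing late in the run."""
        g = SimilarityGraph(["a", "b", "c"])
        g.add_edge("a", "b", 1e-50)
        g.add_edge("b", "c", 1e-50)
        g.add_edge("a", "c", 1e-50)
        emb = clans_layout(
            g,
            LayoutParams(
                seed=1, max_iterations=200, convergence_tol=1e-12,
                attraction_scale=10.0,
            ),
        )
        tail = emb.mean_displacements[-len(emb.mean_displacements) // 10:]
        assert all(b <= a + 1e-12 for a, b in zip(tail, tail[1:]))

    def test_isolated_graph_still_returns_layout(self):
        g = SimilarityGraph(["a", "b", "c"])
        emb = clans_layout(g, LayoutParams(seed=0, max_iterations=50))
        assert set(emb.coordinates) == {"a", "b", "c"}


class TestExtractClusters:
    def test_two_cliques(self):
        g = SimilarityGraph()
        for base in ("a", "b"):
            for i in range(5):
                for j in range(i + 1, 5):
                    g.add_edge(f"{base}{i}", f"{base}{j}", 1e-20)
        a = extract_clusters(g, 1e-12)
        sizes = sorted(len(m) for m in a.clusters().values())
        assert sizes == [5, 5]

    def test_threshold_below_all_edges(self):
        g = SimilarityGraph()
        g.add_edge("x", "y", 1e-5)
        a = extract_clusters(g, 1e-12)
        assert all(v == UNASSIGNED for v in a.labels.values())

    def test_matches_dfs_oracle_on_random_graphs(self, rng):
        """Component structure equals an independent depth-first search."""
        for trial in range(20):
            nodes = [f"n{i}" for i in range(30)]
            g = SimilarityGraph(nodes)
            edges = []
            for i in range(30):
                for j in range(i + 1, 30):
                    if rng.random() < 0.05:
                        p = 10.0 ** -rng.uniform(1, 20)
                        g.add_edge(nodes[i], nodes[j], p)
                        edges.append((nodes[i], nodes[j], p))
            thr = 1e-10
            a = extract_clusters(g, thr)
            # oracle: iterative DFS over the thresholded adjacency list
            adj = {n: set() for n in nodes}
            for u, v, p in edges:
                if p <= thr:
                    adj[u].add(v)
                    adj[v].add(u)
            seen, comps = set(), []
            for n in nodes:
                if n in seen:
                    continue
                stack, comp = [n], set()
                while stack:
                    x = stack.pop()
                    if x in comp:
                        continue
                    comp.add(x)
                    stack.extend(adj[x] - comp)
                seen |= comp
                comps.append(comp)
            oracle = {frozenset(c) for c in comps if len(c) >= 2}
            mine = {frozenset(m) for m in a.clusters().values()}
            assert mine == oracle
            # partition invariant
            assert sum(len(m) for m in mine) + a.n_unassigned() == len(nodes)

    def test_cluster_ids_ordered_by_size(self):
        g = SimilarityGraph()
        for i in range(4):
            g.add_edge(f"big{i}", f"big{(i + 1) % 4}", 1e-20)
        g.add_edge("sm0", "sm1", 1e-20)
        a = extract_clusters(g, 1e-12)
        clusters = a.clusters()
        assert len(clusters[0]) == 4 and len(clusters[1]) == 2


class TestNestedClusters:
    def _hierarchy_graph(self):
        # 2 superclusters x 2 families x 3 members
        g = SimilarityGraph()
        fams = {}
        for s in range(2):
            for f in range(2):
                ids = [f"s{s}f{f}m{m}" for m in range(3)]
                fams[(s, f)] = ids
                for i in range(3):
                    for j in range(i + 1, 3):
                        g.add_edge(ids[i], ids[j], 1e-20)
            a, b = fams[(s, 0)], fams[(s, 1)]
            for x in a:
                for y in b:
                    g.add_edge(x, y, 1e-10)
        return g, fams

    def test_two_level_hierarchy_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        g, fams = self._hierarchy_graph()
        loose, strict = nested_clusters(g, [1e-9, 1e-12])
        ids = sorted(loose.labels)
        super_truth = [i[1] for i in ids]
        fam_truth = [i[1:4] for i in ids]
        assert adjusted_rand_score(super_truth, [loose.labels[i] for i in ids]) == 1.0
        assert adjusted_rand_score(fam_truth, [strict.labels[i] for i in ids]) == 1.0

    def test_nestedness_property(self):
        g, _ = self._hierarchy_graph()
        loose, strict = nested_clusters(g, [1e-9, 1e-12])
        for members in strict.clusters().values():
            parents = {loose.labels[m] for m in members}
            assert len(parents) == 1

    def test_single_threshold_equals_extract(self):
        g, _ = self._hierarchy_graph()
        (only,) = nested_clusters(g, [1e-9])
        assert only.labels == extract_clusters(g, 1e-9).labels

    def test_non_monotone_thresholds_rejected(self):
        g, _ = self._hierarchy_graph()
        with pytest.raises(InputError):
            nested_clusters(g, [1e-12, 1e-9])


class TestReduceRedundancy:
    def test_identical_sequences_collapse(self):
        recs = _records(["ACDEFGHIKL" * 3] * 3)
        reps, membership = reduce_redundancy(recs)
        assert len(reps) == 1 and len(membership) == 2

    def test_all_dissimilar_all_representatives(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        recs = _records(["".join(rng.choice(aa, 60)) for _ in range(5)])
        reps, membership = reduce_redundancy(recs)
        assert len(reps) == 5 and not membership

    def test_matches_naive_greedy_oracle(self, rng):
        """Same output as a plain quadratic re-execution of the greedy rule."""
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        base = ["".join(rng.choice(aa, 50)) for _ in range(5)]
        seqs = []
        for b in base:
            seqs.append(b)
            for _ in range(3):
                s = list(b)
                for k in rng.choice(50, rng.integers(0, 20), replace=False):
                    s[k] = rng.choice(aa)
                seqs.append("".join(s))
        recs = _records(seqs)
        reps, membership = reduce_redundancy(recs)

        thr = 0.80
        order = sorted(recs, key=lambda r: (-len(r.seq), r.id))
        o_reps, o_mem = [], {}
        for rec in order:
            for rep in o_reps:
                if global_identity(rec.seq, dict((r.id, r.seq) for r in recs)[rep]) >= thr:
                    o_mem[rec.id] = rep
                    break
            else:
                o_reps.append(rec.id)
        assert reps == o_reps and membership == o_mem

    def test_representative_invariants(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(aa, 40))
        seqs = [base]
        for _ in range(9):
            s = list(base)
            for k in rng.choice(40, rng.integers(0, 15), replace=False):
                s[k] = rng.choice(aa)
            seqs.append("".join(s))
        recs = _records(seqs)
        by_id = {r.id: r.seq for r in recs}
        reps, membership = reduce_redundancy(recs)
        for member, rep in membership.items():
            assert global_identity(by_id[member], by_id[rep]) >= 0.80
        for i, a in enumerate(reps):
            for b in reps[i + 1:]:
                assert global_identity(by_id[a], by_id[b]) < 0.80


class TestSelectRepresentatives:
    def test_singleton_cluster_returns_member(self):
        a = ClusterAssignment({"x": 0, "y": 0, "z": 1, "w": 1, "v": 1}, 1e-12)
        # note: clusters() only reports labeled clusters
        reps = select_representatives(
            a, {i: {} for i in "xyzwv"},
            RepresentativeParams(n_per_cluster=2),
            sequences={"z": "AAAA", "w": "AAAA", "v": "CCCC"},
        )
        assert reps[0] == ["x", "y"]

    def test_structure_flag_preferred(self):
        a = ClusterAssignment({"x": 0, "y": 0, "z": 0}, 1e-12)
        meta = {"x": {}, "y": {"has_structure": True}, "z": {}}
        reps = select_representatives(
            a, meta, RepresentativeParams(n_per_cluster=1)
        )
        assert reps[0] == ["y"]

    def test_second_representative_is_most_dissimilar(self):
        a = ClusterAssignment({"x": 0, "y": 0, "z": 0}, 1e-12)
        meta = {"x": {"has_structure": True}, "y": {}, "z": {}}
        seqs = {"x": "AAAAAAAAAA", "y": "AAAAAAAACC", "z": "AADDDDDDDD"}
        reps = select_representatives(
            a, meta, RepresentativeParams(n_per_cluster=2), sequences=seqs
        )
        assert reps[0] == ["x", "z"]


class TestCalibrateThreshold:
    def test_bimodal_gap_found(self):
        g = SimilarityGraph()
        g.add_edge("a", "b", 1e-40)
        g.add_edge("c", "d", 1e-5)
        t = calibrate_threshold(g)
        assert 1e-40 < t < 1e-5

    def test_unimodal_falls_back_to_default(self):
        g = SimilarityGraph()
        g.add_edge("a", "b", 1e-5)
        g.add_edge("c", "d", 2e-5)
        assert calibrate_threshold(g) == 1e-12
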