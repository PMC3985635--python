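"""End-to-end combined-evidence pipeline on a synthetic superfamily.

Chains the stages the way the full-scale analysis chains them: simulate
sequences → all-vs-all similarity graph → threshold clustering into
families → two representatives per family → conservation characters per
family → interfamily group character → weighted combined matrix → NJ
tree with bootstrap supports → planted-clade recovery report.

The interfamily similarity groups come from profile–profile clustering
in the full-scale analysis; here they are emulated from the planted
clades with a *coherence* parameter: each family joins its clade's
group with probability ``group_coherence`` and otherwise forms a stray
singleton group (the typical failure mode of profile clustering is a
diverged family dropping out of its group, not joining a wrong one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import encoding, similarity, tree
from .synthetic import SuperfamilyConfig, SyntheticDataset, simulate_superfamily
from .tree import CladeReport, PhyloTree


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    assignment: similarity.ClusterAssignment
    representatives: dict[int, list[str]]
    matrix: encoding.CharacterMatrix
    tree: PhyloTree
    clade_report: CladeReport

    @property
    def n_clades_supported(self) -> int:
        """Planted clades recovered with bootstrap support > 0.5."""
        return sum(
            1
            for name, rec in self.clade_report.recovered.items()
            if rec and (self.clade_report.support[name] or 0.0) > 0.5
        )


def run_combined_pipeline(
    config: SuperfamilyConfig,
    group_coherence: float = 0.9,
    n_bootstrap: int = 100,
    seed: int = 0,
    weights: encoding.WeightScheme | None = None,
) -> PipelineResult:
    """Simulate, cluster, encode, infer, and score clade recovery."""
    ds = simulate_superfamily(config)
    rng = np.random.default_rng(seed)

    graph = similarity.pairwise_similarity(ds.records)
    threshold = similarity.calibrate_threshold(graph)
    assignment = similarity.extract_clusters(graph, threshold)

    meta = {
        r.id: {
            "has_structure": r.has_structure,
            "curated_annotation": r.curated_annotation,
        }
        for r in ds.records
    }
    seqs = {r.id: r.seq for r in ds.records}
    reps = similarity.select_representatives(
        assignment, meta, similarity.RepresentativeParams(n_per_cluster=2),
        sequences=seqs,
    )

    # per-cluster conservation characters from the member alignment
    # (substitution-only simulation: member sequences are the alignment)
    cons_by_cluster = {
        cid: encoding.conservation_characters(
            {sid: seqs[sid] for sid in members}, ds.position_columns
        )
        for cid, members in assignment.clusters().items()
    }

    # noisy interfamily groups: clusters keyed by their majority clade
    cluster_clade: dict[int, str] = {}
    for cid, members in assignment.clusters().items():
        fams = [ds.family_truth[sid] for sid in members]
        majority = max(set(fams), key=fams.count)
        cluster_clade[cid] = ds.clade_truth[majority]
    groups: dict[int, str] = {}
    for cid in sorted(cluster_clade):
        if rng.random() < group_coherence:
            groups[cid] = cluster_clade[cid]
        else:
            groups[cid] = f"stray_{cid}"

    core_alignment: dict[str, str] = {}
    cons_by_taxon: dict[str, list[int]] = {}
    group_by_taxon: dict[int, str] = {}
    for cid, rep_ids in reps.items():
        for sid in rep_ids:
            core_alignment[sid] = seqs[sid]
            cons_by_taxon[sid] = cons_by_cluster[cid]
            group_by_taxon[sid] = groups[cid]
    group_char = encoding.encode_group_character(group_by_taxon)

    matrix = encoding.build_combined_matrix(
        core_alignment, cons_by_taxon, group_char, weights=weights
    )
    result_tree = tree.bootstrap_support(
        matrix, n_replicates=n_bootstrap, seed=int(rng.integers(0, 2**31 - 1))
    )

    planted = {
        clade: {
            sid
            for sid in core_alignment
            if ds.clade_truth[ds.family_truth[sid]] == clade
        }
        for clade in sorted(set(ds.clade_truth.values()))
    }
    report = tree.compare_clades(result_tree, planted)
    return PipelineResult(
        dataset=ds,
        assignment=assignment,
        representatives=reps,
        matrix=matrix,
        tree=result_tree,
        clade_report=report,
    )
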