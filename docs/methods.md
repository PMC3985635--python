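# Methods

This note records the models, numerical choices and known limitations of
the `rnhl` pipeline, in the order of its stages.

## Pairwise significance and similarity clustering

Pairwise similarity is computed by exact Smith–Waterman local alignment
(BLOSUM62, affine gaps −11/−1 via Biopython's `PairwiseAligner`) instead
of heuristic BLAST, and converted to a significance with the
Karlin–Altschul form *E = K·m·n·e^(−λS)*, *p = 1 − e^(−E)* with default
ungapped-style constants *K* = 0.041, *λ* = 0.267 (configurable in
`ScoringParams`).  These constants are calibration parameters, not fitted
values: they preserve the monotone score→significance mapping that the
downstream thresholds rely on.  Pairs whose *p* rounds to 1.0 get no
edge; underflowing *p* is floored at 1e−300 so the layout's −log10
weights stay finite (they are capped at 200 anyway).

Cluster extraction is automated as connected components of the subgraph
at a *P*-value threshold.  The full-scale analysis delineated clusters
by eye on a force-directed map, which is not reproducible; components at
the same thresholds are the closest objective analog.  Both the
embedding and the component partition are emitted so a user can compare.
`calibrate_threshold` offers a data-driven alternative: if the log10 *p*
values are bimodal (widest gap ≥ 2 orders of magnitude), the cutoff is
placed mid-gap; otherwise the conventional 1e−12 is used.

The layout is a Fruchterman–Reingold variant: attraction along each
significant edge proportional to min(−log10 *p*, 200) times the current
distance, repulsion ∝ 1/distance between all pairs, per-node
displacement capped by a step size annealed linearly to zero.  The
annealing cap is what makes late-phase displacement non-increasing; with
weak forces the uncapped displacement can fluctuate below the cap, which
is why convergence is judged on mean displacement, not monotonicity.

Redundancy reduction follows the greedy incremental scheme of CD-HIT:
longest sequence first (ties by id), each sequence joins the first
representative at ≥80% identity (exact matches in a global alignment
divided by the shorter length), otherwise founds a new one.
Representative selection prefers structure-bearing, then curated
sequences; the second representative is the member with the lowest
maximal identity to those already chosen ("relatively dissimilar" is not
quantified in the source workflow; lowest pairwise identity is our
reading, and it requires the sequences to be passed in).

## Conservation encoding

Seven active-site positions are scored per family.  A position's
presence character is 1 iff the combined frequency of its allowed
residues is strictly greater than 0.5 — the only cutoff stated anywhere
in the source workflow, reused for the presence character, with exactly
0.5 encoding 0.  Gaps count in the denominator so a mostly-gapped column
is never "conserved".  Residue-specific characters use the same cutoff
per residue.  The per-position character counts are calibrated to total
exactly 20: the five D/E positions emit 3 characters each (presence, D,
E), α1 (E only) emits 2, and β4 (D/E/H) emits 3 with His folded into the
presence character only.  The exact breakdown used at full scale is in
unavailable supplementary material; this is the unique natural
assignment reaching 20 and is configurable via `CorePositionSpec`.

The combined matrix multiplies each conservation column ×3 and the
single interfamily-group column ×20 (configurable `WeightScheme`; a
multiplicity of 0 drops a block, used for weight-sensitivity analyses).
The NEXUS writer physically duplicates multiplied columns, emits a
mixed(protein+standard) data block, charsets, and an MCMC command block
with ngen = 10 000 000, burninfrac = 0.25 and the <0.05 split-frequency
convergence note.  Morphological states are written as digits; a column
needing more than the 10 states the standard datatype supports raises a
`FormatError` rather than silently extending the symbol set (in-memory
matrices may still hold up to 36 states for distance computations).  A
structured comment records the column layout so the module's own reader
round-trips taxa, states and multiplicities losslessly.

The exo/endo classifier is a majority vote over four indicators: the
exonuclease-type extra β1 acidic; the α2-vs-β4 location of the second
catalytic residue; the β5 acidic (half weight — shared by resolvases);
and the C-terminal helix orientation (reversed in most 3′–5′
exonucleases).  Fewer than two informative indicators, or a tie, yields
`indeterminate`.

## Domain architectures

Hits at e-value ≥ 1e−5 (strict <) are dropped; survivors are made
non-overlapping by greedily keeping the best e-value (ties by earlier
start, then token) and discarding anything overlapping a kept hit by one
residue or more.  Damerau–Levenshtein distance defaults to the
optimal-string-alignment restriction; the unrestricted Lowrance–Wagner
algorithm is selectable (`variant="dl"`) — the two differ only on
patterns like CA→ABC, which real architectures rarely exhibit.

MCL runs on similarities *s* = 1/(1+d) (the source workflow passes a
distance matrix without stating the transform; this maps 0→1
monotonically and keeps entries nonnegative) with unit self-loops to
prevent period-2 oscillation.  Each iteration expands (matrix square),
inflates entrywise (default *I* = 8), renormalizes, prunes entries below
1e−6 *after* renormalization (pruning the raw inflated values can zero
the whole matrix), renormalizes again, and stops when the iterate
changes by <1e−8.  Clusters are connected components of the converged
support.  At inflation 8 the granularity is high: clustering is
meaningful within a family or across a moderate number of families, but
a very large all-vs-all matrix of weakly similar architectures (every
pair at s ≥ 1/(1+d_max)) lets the dense weak background dominate the
flow — which is why the full-scale workflow, and our acceptance script,
run MCL within each family.

## Structure clustering

The Z-score matrix is symmetrized as (Z+Zᵀ)/2 (whether the full-scale
analysis symmetrized or used one triangle is unstated), entries strictly
below the floor (default 6) are zeroed, and the diagonal is untouched.
Average linkage runs on distances d = max(off-diagonal S) − S; the
affine shift preserves the merge order mean-similarity linkage would
give.  Ties break toward the pair carrying the smallest leaf labels, so
runs are deterministic.  Merge heights are non-decreasing by
construction and asserted.  `cut_tree(k)` removes the k−1 highest
merges.

## Tree inference

The combined matrix is summarized by multiplicity-weighted mismatch
fractions, ignoring columns where either taxon is gapped or missing; a
pair with no comparable columns is an error.  Neighbor joining uses the
standard Q criterion with deterministic tie-breaking by leaf label;
negative branch lengths are clamped to zero with the deficit moved to
the sibling branch.  NJ is exact on additive matrices (property-tested
on random 8-taxon trees).

Bootstrap replicates resample the *expanded* columns: a column of
multiplicity m holds m tickets, so the morphological weighting carries
into the resampling distribution.  Support of an original bipartition is
the fraction of replicate trees containing it.  This NJ+bootstrap route
deliberately replaces 10M-generation Bayesian MCMC, which is not
desk-scale; the NEXUS export preserves full fidelity for users who want
the original inference, and the 0.5 support display threshold is applied
at reporting only.

## Synthetic data: what it emulates, and what it does not

The generator states one world and the tests measure it; its defaults
are not tuned to any test outcome.

* **Identities.**  Divergence is substitution-only (uniform over the 19
  non-identical residues), so alignment columns equal sequence positions
  and column bookkeeping is exact.  Because two descendants of one
  ancestor at per-site retention r agree pairwise at only
  r² + (1−r)²/19, the requested within/between identities are treated as
  *pairwise* targets and the retention is obtained by inverting that
  relation (`retention_for_pairwise_identity`); pairwise identities
  below the 0.05 floor of the curve map to full divergence.
* **Catalytic motifs.**  Canonical residues are planted at seven fixed
  core columns; each member carries its family's canonical residue with
  probability `motif_presence` (default 1.0), otherwise a random
  non-allowed residue.  `clade_patterned_config` gives each planted
  clade a distinct 3-subset of the positions, so clades are separated by
  at least two positions of conservation signal.
* **Clades.**  The planted clade structure is morphological only: family
  ancestors diverge from one master uniformly, so the *sequences* carry
  no clade signal — deliberately mirroring the finding that sequence
  data alone leave deep branches unresolved.  The interfamily group
  character is emulated from clade truth at a coherence (default 0.9):
  an incoherent family forms a stray singleton group, the typical
  failure mode of profile–profile clustering (a diverged family drops
  out of its group rather than joining a wrong one).
* **Architectures.**  Each family receives a planted decoration pattern
  (2–3 tokens from a 31-token decoration vocabulary around the core
  domain token), rejection-sampled to lie ≥3 edits from every other
  family's pattern — the generator plants *groups*, so separability is
  part of the stated world, and real Pfam token vocabularies are large
  enough that collisions are rare.  Each member's pattern is perturbed
  with probability `decoration_rate` (default 0.05): one decoration
  dropped or swapped.  Decoy hits at e-value 1e−3 are planted on ~30% of
  proteins and must be removed by the 1e−5 filter.
* **Z-scores.**  Same-clade pairs draw N(15, σ), cross-clade N(2, σ)
  with σ = 0.5 by default, symmetric, diagonal at max+10 so
  self-similarity can never merge late.

What a green test does **not** establish: robustness to indels and
alignment error, to non-uniform substitution processes, to families of
wildly unequal size, to architecture vocabularies with token frequencies
as skewed as Pfam's, or to structure matrices with the block-overlap
ambiguity of real DALI scores.  The synthetic world is a correctness
harness, not a realism benchmark.

## Known limitations

* O(N²) exact alignments limit the similarity stage to a few hundred
  sequences per run; the TSV edge-list input bypasses alignment for
  larger precomputed graphs.
* The automated component clustering can split or merge differently from
  hand-drawn cluster boundaries on a force-directed map; both artifacts
  are emitted for inspection.
* NJ+bootstrap supports are not posterior probabilities; they share only
  the acceptance surface (which clades are recovered above 0.5).
* MCL inflation 8 is intentionally granular; use it within families or
  across well-separated groups, not on very large weakly-similar sets.
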