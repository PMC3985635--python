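# rnhl

Combined-evidence classification toolkit for the RNase H-like (RNHL)
nuclease superfamily — and, more generally, for any highly diverged
protein superfamily where sequence alone cannot resolve deep
relationships.

## The problem

The RNHL superfamily (RNases H, transposases, integrases, Argonaute/Piwi
slicers, Holliday-junction resolvases, many 3′–5′ exonucleases) shares a
five-stranded mixed β-sheet core (strand order 32145) and a two-metal-ion
catalytic mechanism, but its members have diverged so far that ordinary
sequence phylogenetics leaves the deep branches unresolved.  The remedy
implemented here is a multi-stage *combined-evidence* pipeline:

1. **Similarity clustering** — an all-vs-all Smith–Waterman graph whose
   edge significances come from the Karlin–Altschul form
   *E = K·m·n·e^(−λS)*, *p = 1 − e^(−E)*; a CLANS-style force-directed
   embedding for inspection; families extracted as connected components
   at a *P*-value threshold (1e−12 conventionally, or calibrated from
   the bimodality of the edge *p* distribution); CD-HIT-style greedy
   redundancy reduction at 80% identity; two representatives per family
   (structure/curation first, then maximal dissimilarity).
2. **Conservation encoding** — seven canonical active-site positions
   (β1 D/E, the RNase H2-type and exonuclease-type extra β1 acidics,
   α1 E, β4 D/E/H, α2 D/E, β5 D/E) scored per family from the alignment
   column (strictly >50%, gaps in the denominator) and encoded as 20
   binary "morphological" characters — e.g. Asp conserved, Glu not, is
   `1-1-0`.  Interfamily similarity groups become one multistate
   character.  The combined matrix weights the group column ×20 and each
   conservation column ×3 and is exported as mixed-datatype NEXUS
   (ngen=10 000 000, burn-in 0.25) for external Bayesian software.
3. **Domain architectures** — significant (e < 1e−5), non-overlapping
   domain hits become ordered token strings, compared by
   Damerau–Levenshtein distance (OSA by default), clustered per family
   with the Markov Cluster Algorithm at inflation *I* = 8, and ranked by
   size to surface each family's dominant architecture.
4. **Structure clustering** — an all-vs-all DALI-style Z-score matrix,
   floored below 6, clustered by unweighted average linkage.
5. **Tree inference** — a desk-scale substitute for the 10M-generation
   MCMC: multiplicity-weighted mismatch distances over the combined
   matrix, neighbor joining, and bootstrap supports from resampling the
   expanded columns; planted clades are scored as recovered bipartitions.
6. **Synthetic superfamilies** — a ground-truthed generator (families
   with controlled within/between identity, planted catalytic motifs,
   planted clades, per-family domain architectures, block-structured
   Z-score matrices) so every stage is testable without databases.

## Worked example

```python
import rnhl
from rnhl.pipeline import run_combined_pipeline
from rnhl.synthetic import clade_patterned_config

cfg = clade_patterned_config(12, 4, seqs_per_family=6, core_length=150, seed=42)
res = run_combined_pipeline(cfg, group_coherence=0.9, n_bootstrap=100, seed=42)

print(f"families recovered: {len(res.assignment.clusters())} clusters "
      f"({res.assignment.n_unassigned()} unassigned) at p <= {res.assignment.threshold_used:.2e}")
print(f"representatives: {sum(len(v) for v in res.representatives.values())}")
print(f"combined matrix: {len(res.matrix.taxa)} taxa x {res.matrix.expanded_width} expanded characters")
for name in sorted(res.clade_report.clades):
    print(f"  {name}: recovered={res.clade_report.recovered[name]} "
          f"support={res.clade_report.support[name]}")
```

prints

```
families recovered: 12 clusters (0 unassigned) at p <= 1.08e-18
representatives: 24
combined matrix: 24 taxa x 230 expanded characters
  clade01: recovered=True support=1.0
  clade02: recovered=True support=1.0
  clade03: recovered=True support=1.0
  clade04: recovered=True support=0.89
```

Twelve synthetic families (six members each, 150-residue core) are
recovered exactly by threshold clustering of the alignment graph; two
representatives per family carry their family's 20 conservation
characters (×3) and its similarity-group state (×20) next to 150
sequence columns (150 + 60 + 20 = 230); neighbor joining plus 100
bootstrap replicates then recovers all four planted clades, three with
full support.

A command-line interface mirrors the stages
(`rnhl simulate | cluster | encode | architectures | structclust | tree`);
run `rnhl --help` for the options of each subcommand.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch on a freshly simulated
40-family / 12-clade superfamily: similarity clustering vs family truth,
per-family MCL architecture ranking, average-linkage structure-clade
recovery, and NJ+bootstrap clade recovery on the combined matrix,
printing a summary and writing the JSON report to `--out`.
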