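"""Synthetic superfamily generator with known ground truth.

Every pipeline stage (similarity clustering, conservation encoding,
architecture clustering, structure clustering, tree inference) needs
inputs whose answer is known.  This module simulates a superfamily the
way the downstream statistics see one:

* a shared ungapped core alignment — one random master ancestor, per
  family ancestors diverged so that *pairwise* cross-family identity
  matches ``between_family_identity``, and members diverged from their
  family ancestor so that mean pairwise within-family identity matches
  ``within_family_identity`` (substitutions only, so alignment columns
  equal sequence positions);
* canonical catalytic residues planted at seven named core columns with
  per-(family, position) presence probabilities;
* a planted clade partition over families;
* per-protein domain-hit tables with family-specific architectures and
  sub-threshold decoy hits;
* a block-structured structure-similarity (Z-score) matrix over the
  planted clades.

All randomness flows from one seeded NumPy generator, with independent
substreams per family in index order, so a fixed seed reproduces the
dataset byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import CorePositionSpec, DEFAULT_POSITION_SPECS
from .errors import BoundsError, ConfigurationError
from .records import AMINO_ACIDS, SequenceRecord, write_fasta

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
_AA_INDEX = {chr(a): i for i, a in enumerate(_AA)}

#: core token plus a decoration vocabulary; real Pfam-derived token sets
#: number in the thousands, so collisions between family architectures are
#: rare — a few dozen tokens keep that property at desk scale
DEFAULT_ARCHITECTURE_VOCAB = (
    "RNHL", "HTH", "ZnF", "RVT", "PIN", "PDDEXK", "OB", "WH",
    "TPR", "ANK", "SH3", "KH", "S1", "HhH", "Tudor", "Chromo",
    "PHD", "RING", "BRCT", "PAS", "GAF", "WD40", "LRR", "FHA",
    "SAM", "PDZ", "BTB", "CUE", "UBA", "PUA", "TUDOR2", "HEAT",
)


def _seq_to_ints(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ConfigurationError(f"non-standard residue {exc} in sequence")


def _ints_to_seq(arr: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in arr)


def retention_for_pairwise_identity(pairwise_identity: float) -> float:
    """Per-site retention rate giving a target *pairwise* identity.

    Two sequences independently mutated from a common ancestor with
    per-site retention r (replacements uniform over the 19 other
    residues) agree at a site with probability r² + (1−r)²/19.  This
    inverts that relation; identities below the 0.05 floor of the curve
    map to full divergence (r = 0).
    """
    p = float(pairwise_identity)
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"identity {p} outside [0, 1]")
    a, b, c = 20.0 / 19.0, -2.0 / 19.0, 1.0 / 19.0 - p
    disc = b * b - 4 * a * c
    if disc < 0:
        return 0.0
    r = (-b + math.sqrt(disc)) / (2 * a)
    return min(1.0, max(0.0, r))


def mutate_preserving(
    seq: str,
    target_identity: float,
    preserved_sites: set[int] | Sequence[int] = (),
    rng: np.random.Generator | None = None,
) -> str:
    """Substitute residues to an expected identity, keeping some sites fixed.

    Each non-preserved site is replaced with probability
    ``1 − target_identity`` by a residue drawn uniformly from the 19
    non-identical amino acids; no indels, so positions are stable.
    """
    if not (0.0 <= target_identity <= 1.0):
        raise ConfigurationError(f"target_identity {target_identity} outside [0, 1]")
    rng = rng or np.random.default_rng()
    preserved = set(int(i) for i in preserved_sites)
    n = len(seq)
    for i in preserved:
        if not (0 <= i < n):
            raise BoundsError(f"preserved site {i} out of range for length {n}")
    if target_identity == 1.0 or n == 0:
        return seq
    arr = _seq_to_ints(seq)
    mutable = np.array([i not in preserved for i in range(n)])
    hit = mutable & (rng.random(n) < (1.0 - target_identity))
    k = rng.integers(0, 19, size=n)
    repl = k + (k >= arr)  # uniform over the 19 residues != original
    arr = np.where(hit, repl, arr)
    return _ints_to_seq(arr)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SuperfamilyConfig:
    """Stated world for one simulated superfamily."""

    n_families: int = 12
    seqs_per_family: int = 10
    core_length: int = 200
    within_family_identity: float = 0.6
    between_family_identity: float = 0.15
    clade_partition: dict[str, str] | None = None
    position_specs: tuple[CorePositionSpec, ...] = DEFAULT_POSITION_SPECS
    position_columns: dict[str, int] | None = None
    motif_presence: dict[tuple[str, str], float] = field(default_factory=dict)
    architecture_vocab: tuple[str, ...] = DEFAULT_ARCHITECTURE_VOCAB
    core_token: str = "RNHL"
    decoration_rate: float = 0.05
    zscore_within: float = 15.0
    zscore_between: float = 2.0
    zscore_noise_sd: float = 0.5
    seed: int = 0

    def family_names(self) -> list[str]:
        if self.clade_partition is not None:
            return list(self.clade_partition)
        return [f"F{i + 1:03d}" for i in range(self.n_families)]

    def resolved_clades(self) -> dict[str, str]:
        if self.clade_partition is not None:
            return dict(self.clade_partition)
        names = self.family_names()
        half = (len(names) + 1) // 2
        return {f: ("C1" if i < half else "C2") for i, f in enumerate(names)}

    def resolved_position_columns(self) -> dict[str, int]:
        if self.position_columns is not None:
            return dict(self.position_columns)
        n = len(self.position_specs)
        return {
            spec.name: ((k + 1) * self.core_length) // (n + 1)
            for k, spec in enumerate(self.position_specs)
        }

    def validate(self) -> None:
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")
        if self.seqs_per_family < 1:
            raise ConfigurationError("seqs_per_family must be >= 1")
        if self.core_length < len(self.position_specs) + 1:
            raise ConfigurationError("core_length too small for the core positions")
        if not (0.0 < self.within_family_identity <= 1.0):
            raise ConfigurationError("within_family_identity must be in (0, 1]")
        if not (0.0 <= self.between_family_identity < 1.0):
            raise ConfigurationError("between_family_identity must be in [0, 1)")
        if self.between_family_identity >= self.within_family_identity:
            raise ConfigurationError(
                "between_family_identity must be < within_family_identity"
            )
        if self.clade_partition is not None and len(self.clade_partition) != self.n_families:
            raise ConfigurationError(
                "clade_partition must cover exactly n_families families"
            )
        for key, p in self.motif_presence.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"motif_presence[{key}] = {p} outside [0, 1]")
        if not (0.0 <= self.decoration_rate <= 1.0):
            raise ConfigurationError("decoration_rate must be in [0, 1]")
        if self.zscore_within <= self.zscore_between:
            raise ConfigurationError("zscore_within must exceed zscore_between")
        if self.zscore_noise_sd < 0:
            raise ConfigurationError("zscore_noise_sd must be >= 0")
        if self.core_token not in self.architecture_vocab:
            raise ConfigurationError("core_token must be in architecture_vocab")
        cols = self.resolved_position_columns()
        if len(set(cols.values())) != len(cols):
            raise ConfigurationError("position_columns assigns duplicate columns")
        for name, col in cols.items():
            if not (0 <= col < self.core_length):
                raise ConfigurationError(
                    f"position_columns[{name}] = {col} outside the core"
                )


def clade_patterned_config(
    n_families: int,
    n_clades: int,
    presence: float = 0.9,
    **overrides,
) -> SuperfamilyConfig:
    """Config whose clades differ by which catalytic positions they carry.

    Families are dealt round-robin into clades; each clade receives a
    distinct 3-subset of the seven core positions (so any two clades
    differ at >= 2 positions) whose canonical residues are planted with
    probability ``presence``; the remaining positions are planted with
    probability 0 (members carry random non-catalytic residues there).
    """
    specs = overrides.get("position_specs", DEFAULT_POSITION_SPECS)
    patterns = list(combinations(range(len(specs)), 3))
    if n_clades > len(patterns):
        raise ConfigurationError(f"at most {len(patterns)} distinct clades supported")
    families = [f"F{i + 1:03d}" for i in range(n_families)]
    clades = {f: f"clade{(i % n_clades) + 1:02d}" for i, f in enumerate(families)}
    presence_map: dict[tuple[str, str], float] = {}
    for i, fam in enumerate(families):
        pattern = patterns[i % n_clades]
        for k, spec in enumerate(specs):
            presence_map[(fam, spec.name)] = presence if k in pattern else 0.0
    overrides.setdefault("motif_presence", presence_map)
    return SuperfamilyConfig(
        n_families=n_families, clade_partition=clades, **overrides
    )


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything a pipeline run needs, plus its ground truth."""

    records: list[SequenceRecord]
    family_truth: dict[str, str]  # sequence id -> family
    clade_truth: dict[str, str]  # family -> clade
    alignments: dict[str, dict[str, str]]  # family -> {id: aligned row}
    position_columns: dict[str, int]  # position name -> 0-based core column
    hits: pd.DataFrame  # protein_id, domain_token, start, end, e_value
    zmatrix: pd.DataFrame  # families x families Z-scores
    config: SuperfamilyConfig

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, out / "sequences.fasta")
        aln_dir = out / "alignments"
        aln_dir.mkdir(exist_ok=True)
        for family, rows in self.alignments.items():
            with open(aln_dir / f"{family}.afa", "w") as fh:
                for sid, row in rows.items():
                    fh.write(f">{sid}\n{row}\n")
        pd.DataFrame(
            [(n, c + 1) for n, c in self.position_columns.items()],
            columns=["position_name", "alignment_column"],
        ).to_csv(out / "positions.tsv", sep="\t", index=False)
        self.hits.to_csv(out / "hits.tsv", sep="\t", index=False)
        self.zmatrix.to_csv(out / "zmatrix.tsv", sep="\t", index_label="")
        pd.DataFrame(
            sorted(self.family_truth.items()), columns=["id", "family"]
        ).to_csv(out / "family_truth.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.clade_truth.items()), columns=["family", "clade"]
        ).to_csv(out / "clade_truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_superfamily(config: SuperfamilyConfig) -> SyntheticDataset:
    """Simulate a full superfamily-shaped dataset from a validated config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    families = config.family_names()
    clades = config.resolved_clades()
    pos_cols = config.resolved_position_columns()
    pos_sites = set(pos_cols.values())

    master = _ints_to_seq(rng.integers(0, 20, size=config.core_length))
    r_between = retention_for_pairwise_identity(config.between_family_identity)
    r_within = retention_for_pairwise_identity(config.within_family_identity)

    streams = rng.spawn(len(families))
    arch_rng, z_rng = rng.spawn(2)

    records: list[SequenceRecord] = []
    family_truth: dict[str, str] = {}
    alignments: dict[str, dict[str, str]] = {}
    spec_by_name = {s.name: s for s in config.position_specs}

    for family, fs in zip(families, streams):
        ancestor = mutate_preserving(master, r_between, set(), fs)
        anc = list(ancestor)
        for name, col in pos_cols.items():
            anc[col] = spec_by_name[name].allowed_residues[0]
        ancestor = "".join(anc)

        rows: dict[str, str] = {}
        for j in range(config.seqs_per_family):
            sid = f"{family}_s{j + 1:02d}"
            seq = mutate_preserving(ancestor, r_within, pos_sites, fs)
            chars = list(seq)
            for name, col in pos_cols.items():
                spec = spec_by_name[name]
                p = config.motif_presence.get((family, name), 1.0)
                if fs.random() < p:
                    chars[col] = spec.allowed_residues[0]
                else:
                    others = [a for a in AMINO_ACIDS if a not in spec.allowed_residues]
                    chars[col] = others[int(fs.integers(0, len(others)))]
            seq = "".join(chars)
            records.append(
                SequenceRecord(
                    id=sid,
                    seq=seq,
                    family=family,
                    clade=clades[family],
                    has_structure=(j == 0),
                    curated_annotation=(j == 1),
                )
            )
            family_truth[sid] = family
            rows[sid] = seq
        alignments[family] = rows

    hits = simulate_architecture_set(
        vocab=config.architecture_vocab,
        family_truth=family_truth,
        core_token=config.core_token,
        decoration_rate=config.decoration_rate,
        rng=arch_rng,
    )
    zmatrix = simulate_zscore_matrix(
        clade_truth=clades,
        zscore_within=config.zscore_within,
        zscore_between=config.zscore_between,
        noise_sd=config.zscore_noise_sd,
        rng=z_rng,
    )
    return SyntheticDataset(
        records=records,
        family_truth=family_truth,
        clade_truth=clades,
        alignments=alignments,
        position_columns=pos_cols,
        hits=hits,
        zmatrix=zmatrix,
        config=config,
    )


#: e-value used for planted decoy hits; fails the default 1e-5 filter.
DECOY_EVALUE = 1e-3
_HIT_LEN = 150
_HIT_STRIDE = 200


def simulate_architecture_set(
    vocab: Sequence[str],
    family_truth: Mapping[str, str],
    core_token: str,
    decoration_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-protein domain hit tables with family-specific decorations.

    Every protein carries one core-token hit; its family's decoration
    tokens surround it in a fixed family pattern, each independently
    perturbed (dropped or swapped) with probability ``decoration_rate``.
    With probability 0.3 a decoy hit at e-value 1e-3 is appended; decoys
    are meant to be removed by the 1e-5 architecture filter.
    """
    vocab = list(vocab)
    if not vocab:
        raise ConfigurationError("architecture vocabulary is empty")
    decorations = [t for t in vocab if t != core_token]
    families = list(dict.fromkeys(family_truth.values()))

    from .architecture import dl_distance

    patterns: dict[str, list[str]] = {}
    taken: list[list[str]] = []
    for family in families:
        # rejection-sample so planted family patterns stay well separated in
        # edit space (>= 3 edits, so a one-edit member variant is still
        # closest to its own family); relax if the vocabulary is exhausted
        pattern: list[str] = [core_token]
        for attempt in range(300):
            if decorations:
                lo = min(2, len(decorations))
                n_dec = int(rng.integers(lo, min(3, len(decorations)) + 1))
                chosen = [
                    decorations[i]
                    for i in rng.choice(len(decorations), n_dec, replace=False)
                ]
            else:
                chosen = []
            insert_at = int(rng.integers(0, len(chosen) + 1))
            pattern = chosen[:insert_at] + [core_token] + chosen[insert_at:]
            min_d = 3 if attempt < 200 else (2 if attempt < 280 else 1)
            if all(dl_distance(pattern, p) >= min_d for p in taken):
                break
        taken.append(pattern)
        patterns[family] = pattern

    rows: list[tuple[str, str, int, int, float]] = []
    for pid, family in family_truth.items():
        tokens = list(patterns[family])
        # each member's pattern is perturbed with probability decoration_rate:
        # one decoration dropped or swapped (the core hit is never touched)
        dec_idx = [k for k, t in enumerate(tokens) if t != core_token]
        if dec_idx and rng.random() < decoration_rate:
            k = int(rng.choice(dec_idx))
            if rng.random() < 0.5:
                tokens.pop(k)
            else:
                tokens[k] = decorations[int(rng.integers(0, len(decorations)))]
        for k, tok in enumerate(tokens):
            start = k * _HIT_STRIDE + 1
            evalue = 10.0 ** (-float(rng.uniform(10, 30)))
            rows.append((pid, tok, start, start + _HIT_LEN - 1, evalue))
        if rng.random() < 0.3 and decorations:
            decoy = decorations[int(rng.integers(0, len(decorations)))]
            start = len(tokens) * _HIT_STRIDE + 1
            rows.append((pid, decoy, start, start + _HIT_LEN - 1, DECOY_EVALUE))
    return pd.DataFrame(
        rows, columns=["protein_id", "domain_token", "start", "end", "e_value"]
    )


def simulate_zscore_matrix(
    clade_truth: Mapping[str, str],
    zscore_within: float,
    zscore_between: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Block-structured symmetric Z-score matrix over families.

    Same-clade pairs draw around ``zscore_within``, cross-clade pairs
    around ``zscore_between``; the diagonal is set 10 units above the
    largest off-diagonal entry so self-similarity always dominates.
    """
    if zscore_within <= zscore_between:
        raise ConfigurationError("zscore_within must exceed zscore_between")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    fams = list(clade_truth)
    n = len(fams)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mean = (
                zscore_within
                if clade_truth[fams[i]] == clade_truth[fams[j]]
                else zscore_between
            )
            v = mean if noise_sd == 0 else float(rng.normal(mean, noise_sd))
            M[i, j] = M[j, i] = v
    off_max = M.max() if n > 1 else 0.0
    np.fill_diagonal(M, off_max + 10.0)
    return pd.DataFrame(M, index=fams, columns=fams)
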