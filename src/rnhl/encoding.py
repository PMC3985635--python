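"""Catalytic-site conservation scoring and combined character matrices.

The RNase H-like catalytic core carries up to seven canonical acidic
active-site positions (two-metal-ion catalysis): the invariant Asp/Glu
in strand β1; a second β1 Asp/Glu typical of RNases H2; a third β1
Glu/Asp typical of 3'-5' exonucleases; the α1 Glu of RNases H1; the β4
Asp/Glu/His; the α2 Asp/Glu of exonucleases; and the β5 Asp/Glu of
Holliday-junction resolvases and exonucleases.  Per family, conservation
at each position is read off the family multiple alignment and encoded
as binary "morphological" characters: one presence character (is *any*
allowed residue conserved at >50% of rows, gaps included in the
denominator) plus one character per explicitly encoded residue type
(e.g. Asp conserved, Glu not → ``1-1-0``).  The default seven-position
table emits exactly 20 characters.

Interfamily similarity groups (families clustered at a loose *P*-value
threshold) are encoded as one multistate character.  The conservation
block, the group character and the core sequence alignment are combined
into one weighted character matrix — conservation columns ×3, the group
column ×20 — and written as a mixed-datatype NEXUS file ready for
Bayesian inference, with a desk-scale distance/NJ route provided in
:mod:`rnhl.tree`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import BoundsError, FormatError, InputError

GAP = "-"
MISSING = "?"

#: verdicts of the activity classifier
EXONUCLEASE = "exonuclease_like"
ENDONUCLEASE = "endonuclease_like"
INDETERMINATE = "indeterminate"


# ---------------------------------------------------------------------------
# position specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorePositionSpec:
    """One canonical active-site position and how it is encoded.

    ``allowed_residues`` define what counts as "conserved" for the
    presence character; ``encoded_residues`` (a subset, by default all
    of them) each get their own residue-specific character.  The number
    of characters emitted is ``1 + len(encoded_residues)``.
    """

    name: str
    element: str
    allowed_residues: tuple[str, ...]
    encoded_residues: tuple[str, ...] | None = None

    def __post_init__(self):
        if not self.allowed_residues:
            raise InputError(f"position {self.name!r}: allowed_residues is empty")
        object.__setattr__(
            self, "allowed_residues", tuple(self.allowed_residues)
        )
        enc = self.allowed_residues if self.encoded_residues is None else tuple(
            self.encoded_residues
        )
        for r in enc:
            if r not in self.allowed_residues:
                raise InputError(
                    f"position {self.name!r}: encoded residue {r} not allowed"
                )
        object.__setattr__(self, "encoded_residues", enc)

    @property
    def n_characters(self) -> int:
        return 1 + len(self.encoded_residues)


#: Default seven-position table (20 characters in total).  β4 admits His
#: for the presence character but His gets no residue-specific column.
DEFAULT_POSITION_SPECS: tuple[CorePositionSpec, ...] = (
    CorePositionSpec("b1", "b1", ("D", "E")),
    CorePositionSpec("b1_h2", "b1", ("D", "E")),
    CorePositionSpec("b1_exo", "b1", ("E", "D"), ("D", "E")),
    CorePositionSpec("a1", "a1", ("E",)),
    CorePositionSpec("b4", "b4", ("D", "E", "H"), ("D", "E")),
    CorePositionSpec("a2", "a2", ("D", "E")),
    CorePositionSpec("b5", "b5", ("D", "E")),
)

N_CONSERVATION_CHARACTERS = sum(s.n_characters for s in DEFAULT_POSITION_SPECS)
assert N_CONSERVATION_CHARACTERS == 20


@dataclass(frozen=True)
class EncodingParams:
    """Conservation cutoff (strict > 0.5 by default) and column weights."""

    conserved_threshold: float = 0.5
    weights: "WeightScheme" = None  # type: ignore[assignment]

    def __post_init__(self):
        if not (0.0 < self.conserved_threshold < 1.0):
            raise InputError("conserved_threshold must be in (0, 1)")
        if self.weights is None:
            object.__setattr__(self, "weights", WeightScheme())


@dataclass(frozen=True)
class WeightScheme:
    """Column multiplicities balancing sequence vs non-sequence signal.

    The interfamily-similarity column is replicated ``similarity_multiplicity``
    times (default 20) and each of the 20 conservation columns
    ``conservation_multiplicity`` times (default 3).  A multiplicity of 0
    drops the block entirely (used for weight-sensitivity analyses).
    """

    similarity_multiplicity: int = 20
    conservation_multiplicity: int = 3

    def __post_init__(self):
        if self.similarity_multiplicity < 0 or self.conservation_multiplicity < 0:
            raise InputError("multiplicities must be non-negative")


# ---------------------------------------------------------------------------
# conservation scoring
# ---------------------------------------------------------------------------

def column_frequencies(
    alignment: Sequence[str] | Mapping[str, str], column: int
) -> dict[str, float]:
    """Residue frequencies (gap included) at one alignment column.

    Gaps count in the denominator, so a mostly-gapped column can never
    be called conserved.
    """
    rows = list(alignment.values()) if isinstance(alignment, Mapping) else list(alignment)
    if not rows:
        raise InputError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise InputError("alignment rows have unequal lengths")
    if not (0 <= column < width):
        raise BoundsError(f"column {column} out of range for width {width}")
    counts: dict[str, int] = {}
    for row in rows:
        res = row[column].upper()
        counts[res] = counts.get(res, 0) + 1
    n = len(rows)
    return {res: c / n for res, c in counts.items()}


def encode_position(
    freqs: Mapping[str, float],
    spec: CorePositionSpec,
    params: EncodingParams | None = None,
) -> list[int]:
    """Binary character vector for one position.

    Character 1 is the presence character (combined allowed-residue
    frequency strictly above the cutoff); each following character flags
    one explicitly encoded residue individually above the cutoff.
    """
    params = params or EncodingParams()
    t = params.conserved_threshold
    combined = sum(freqs.get(r, 0.0) for r in spec.allowed_residues)
    vec = [1 if combined > t else 0]
    for res in spec.encoded_residues:
        vec.append(1 if freqs.get(res, 0.0) > t else 0)
    return vec


def conservation_profile(
    alignment: Sequence[str] | Mapping[str, str],
    position_columns: Mapping[str, int],
) -> dict[str, dict[str, float]]:
    """Frequency table per named core position for one family alignment."""
    return {
        name: column_frequencies(alignment, col)
        for name, col in position_columns.items()
    }


def conservation_characters(
    alignment: Sequence[str] | Mapping[str, str],
    position_columns: Mapping[str, int],
    specs: Sequence[CorePositionSpec] = DEFAULT_POSITION_SPECS,
    params: EncodingParams | None = None,
) -> list[int]:
    """Concatenated character vector over all core positions (20 by default)."""
    vec: list[int] = []
    for spec in specs:
        if spec.name not in position_columns:
            raise InputError(f"no alignment column mapped for position {spec.name!r}")
        freqs = column_frequencies(alignment, position_columns[spec.name])
        vec.extend(encode_position(freqs, spec, params))
    return vec


def conserved_positions(
    alignment: Sequence[str] | Mapping[str, str],
    position_columns: Mapping[str, int],
    specs: Sequence[CorePositionSpec] = DEFAULT_POSITION_SPECS,
    params: EncodingParams | None = None,
) -> dict[str, bool]:
    """Presence-character verdict per position (input to the classifier)."""
    params = params or EncodingParams()
    out = {}
    for spec in specs:
        freqs = column_frequencies(alignment, position_columns[spec.name])
        out[spec.name] = encode_position(freqs, spec, params)[0] == 1
    return out


# ---------------------------------------------------------------------------
# group character
# ---------------------------------------------------------------------------

def encode_group_character(groups: Mapping[str, object]) -> dict[str, int]:
    """Interfamily-similarity groups as one multistate character.

    Families share a state iff they share a group; states are numbered
    0..G-1 in order of first appearance in the mapping.
    """
    state_of: dict[object, int] = {}
    out: dict[str, int] = {}
    for family, group in groups.items():
        if group not in state_of:
            state_of[group] = len(state_of)
        out[family] = state_of[group]
    return out


# ---------------------------------------------------------------------------
# combined character matrix
# ---------------------------------------------------------------------------

KIND_SEQUENCE = "sequence"
KIND_CONSERVATION = "conservation"
KIND_GROUP = "similarity_group"

#: in-memory state symbols (extended past the digits for large group counts;
#: the NEXUS writer enforces the 10-state standard-datatype limit separately)
_MORPH_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_NEXUS_SYMBOLS = "0123456789"


@dataclass(frozen=True)
class CharacterColumn:
    kind: str
    states: tuple[str, ...]  # one single-character state symbol per taxon
    multiplicity: int = 1

    def __post_init__(self):
        if self.multiplicity < 1:
            raise InputError("column multiplicity must be >= 1")
        if any(len(s) != 1 for s in self.states):
            raise InputError("states must be single symbols")


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxa × characters, each column with an integer multiplicity."""

    taxa: tuple[str, ...]
    columns: tuple[CharacterColumn, ...]

    def __post_init__(self):
        for i, col in enumerate(self.columns):
            if len(col.states) != len(self.taxa):
                raise InputError(
                    f"column {i}: {len(col.states)} states for {len(self.taxa)} taxa"
                )

    @property
    def expanded_width(self) -> int:
        return sum(c.multiplicity for c in self.columns)

    def expanded_rows(self) -> dict[str, str]:
        """Per-taxon character string with multiplied columns duplicated."""
        rows = {t: [] for t in self.taxa}
        for col in self.columns:
            for t, s in zip(self.taxa, col.states):
                rows[t].append(s * col.multiplicity)
        return {t: "".join(parts) for t, parts in rows.items()}


def build_combined_matrix(
    core_alignment: Mapping[str, str],
    conservation_chars: Mapping[str, Sequence[int]],
    group_char: Mapping[str, int],
    weights: WeightScheme | None = None,
) -> CharacterMatrix:
    """Combine sequence, conservation and group evidence into one matrix.

    All three inputs must cover the same taxa (family representatives
    carry their family's morphological states).  Column layout: L
    sequence columns at multiplicity 1, then the conservation columns at
    ``conservation_multiplicity``, then the single group column at
    ``similarity_multiplicity``.
    """
    weights = weights or WeightScheme()
    taxa = tuple(core_alignment)
    for name, other in (
        ("conservation_chars", conservation_chars),
        ("group_char", group_char),
    ):
        diff = set(taxa) ^ set(other)
        if diff:
            raise InputError(
                f"taxon sets of core_alignment and {name} differ: {sorted(diff)}"
            )

    columns: list[CharacterColumn] = []
    width = {len(s) for s in core_alignment.values()}
    if len(width) > 1:
        raise InputError("core alignment rows have unequal lengths")
    (L,) = width or {0}
    for j in range(L):
        states = tuple(core_alignment[t][j].upper() for t in taxa)
        columns.append(CharacterColumn(KIND_SEQUENCE, states, 1))

    n_cons = {len(v) for v in conservation_chars.values()}
    if len(n_cons) > 1:
        raise InputError("conservation vectors have unequal lengths")
    if weights.conservation_multiplicity >= 1:
        for j in range(next(iter(n_cons), 0)):
            states = tuple(str(int(conservation_chars[t][j])) for t in taxa)
            columns.append(
                CharacterColumn(KIND_CONSERVATION, states, weights.conservation_multiplicity)
            )
    if weights.similarity_multiplicity >= 1:
        states = tuple(_morph_symbol(group_char[t]) for t in taxa)
        columns.append(
            CharacterColumn(KIND_GROUP, states, weights.similarity_multiplicity)
        )
    return CharacterMatrix(taxa=taxa, columns=tuple(columns))


def _morph_symbol(state: int) -> str:
    state = int(state)
    if not (0 <= state < len(_MORPH_SYMBOLS)):
        raise FormatError(
            f"morphological state {state} exceeds the {len(_MORPH_SYMBOLS)}-symbol "
            "limit of the NEXUS standard datatype"
        )
    return _MORPH_SYMBOLS[state]


# ---------------------------------------------------------------------------
# NEXUS emission / parsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NexusMCMCBlock:
    """MCMC settings carried in the emitted NEXUS command block."""

    ngen: int = 10_000_000
    burnin_fraction: float = 0.25
    convergence_note: float = 0.05  # target average SD of split frequencies

    def __post_init__(self):
        if not (0.0 <= self.burnin_fraction < 1.0):
            raise InputError("burnin_fraction must be in [0, 1)")


def write_character_nexus(
    matrix: CharacterMatrix, mcmc_defaults: NexusMCMCBlock | None = None
) -> str:
    """Serialize the combined matrix as mixed-datatype NEXUS text.

    Sequence columns go into a protein partition and morphological
    columns into a standard partition; multiplied columns are physically
    duplicated.  A structured comment records the column layout so the
    module's own reader can reconstruct multiplicities losslessly.
    """
    mcmc = mcmc_defaults or NexusMCMCBlock()
    if not matrix.taxa or not matrix.columns:
        raise InputError("cannot write an empty character matrix")
    for col in matrix.columns:
        if col.kind != KIND_SEQUENCE:
            states = {s for s in col.states if s not in (GAP, MISSING)}
            if len(states) > 10 or any(s not in _NEXUS_SYMBOLS for s in states):
                raise FormatError(
                    "morphological column needs more than the 10 states the "
                    "standard datatype supports"
                )

    # run-length encode (kind, multiplicity) over columns
    runs: list[tuple[str, int, int]] = []
    for col in matrix.columns:
        if runs and runs[-1][0] == col.kind and runs[-1][1] == col.multiplicity:
            runs[-1] = (col.kind, col.multiplicity, runs[-1][2] + 1)
        else:
            runs.append((col.kind, col.multiplicity, 1))
    layout = ",".join(f"{k}:{m}x{c}" for k, m, c in runs)

    # expanded partition ranges (1-based, inclusive)
    seq_w = sum(c.multiplicity for c in matrix.columns if c.kind == KIND_SEQUENCE)
    total_w = matrix.expanded_width
    expanded_kinds: list[str] = []
    for col in matrix.columns:
        expanded_kinds.extend([col.kind] * col.multiplicity)
    if expanded_kinds[:seq_w] != [KIND_SEQUENCE] * seq_w or KIND_SEQUENCE in expanded_kinds[seq_w:]:
        raise FormatError("sequence columns must form a contiguous leading block")

    rows = matrix.expanded_rows()
    name_w = max(len(t) for t in matrix.taxa) + 2
    lines = ["#NEXUS", "", f"[&rnhl-columns {layout}]", "", "begin data;"]
    lines.append(f"\tdimensions ntax={len(matrix.taxa)} nchar={total_w};")
    if seq_w and seq_w < total_w:
        fmt = f"datatype=mixed(protein:1-{seq_w},standard:{seq_w + 1}-{total_w})"
    elif seq_w:
        fmt = "datatype=protein"
    else:
        fmt = "datatype=standard"
    lines.append(f"\tformat {fmt} interleave=no gap={GAP} missing={MISSING};")
    lines.append("\tmatrix")
    for t in matrix.taxa:
        lines.append(f"\t{t.ljust(name_w)}{rows[t]}")
    lines.append("\t;")
    lines.append("end;")
    lines.append("")
    lines.append("begin sets;")
    pos = 1
    for kind in (KIND_SEQUENCE, KIND_CONSERVATION, KIND_GROUP):
        w = sum(c.multiplicity for c in matrix.columns if c.kind == kind)
        if w:
            lines.append(f"\tcharset {kind} = {pos}-{pos + w - 1};")
            pos += w
    lines.append("end;")
    lines.append("")
    lines.append("begin mrbayes;")
    lines.append(
        f"\tmcmcp ngen={mcmc.ngen} burninfrac={mcmc.burnin_fraction:g} "
        f"stoprule=no;"
    )
    lines.append(
        f"\t[convergence target: average standard deviation of split "
        f"frequencies < {mcmc.convergence_note:g}]"
    )
    lines.append("end;")
    return "\n".join(lines) + "\n"


def read_character_nexus(text: str) -> tuple[CharacterMatrix, NexusMCMCBlock]:
    """Parse NEXUS text produced by :func:`write_character_nexus`."""
    m = re.search(r"\[&rnhl-columns ([^\]]+)\]", text)
    if not m:
        raise FormatError("missing column-layout comment; not a matrix we wrote")
    runs = []
    for item in m.group(1).split(","):
        kind, rest = item.split(":")
        mult, count = rest.split("x")
        runs.append((kind, int(mult), int(count)))

    mat = re.search(r"\bmatrix\s*\n(.*?)\n\s*;", text, re.S | re.I)
    if not mat:
        raise FormatError("no matrix block found")
    taxa: list[str] = []
    rows: dict[str, str] = {}
    for line in mat.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        name, chars = line.split(None, 1)
        taxa.append(name)
        rows[name] = chars.replace(" ", "")

    columns: list[CharacterColumn] = []
    pos = 0
    for kind, mult, count in runs:
        for _ in range(count):
            states = tuple(rows[t][pos] for t in taxa)
            for t in taxa:  # duplicated copies must agree
                if rows[t][pos : pos + mult] != rows[t][pos] * mult:
                    raise FormatError(f"inconsistent duplicated column at {pos} for {t}")
            columns.append(CharacterColumn(kind, states, mult))
            pos += mult
    matrix = CharacterMatrix(taxa=tuple(taxa), columns=tuple(columns))

    ngen = re.search(r"ngen=(\d+)", text)
    burn = re.search(r"burninfrac=([\d.eE+-]+)", text)
    conv = re.search(r"split\s+frequencies\s*<\s*([\d.eE+-]+)", text)
    mcmc = NexusMCMCBlock(
        ngen=int(ngen.group(1)) if ngen else 10_000_000,
        burnin_fraction=float(burn.group(1)) if burn else 0.25,
        convergence_note=float(conv.group(1)) if conv else 0.05,
    )
    return matrix, mcmc


# ---------------------------------------------------------------------------
# exo/endo classification
# ---------------------------------------------------------------------------

def classify_activity(
    profile: Mapping[str, bool],
    helix_orientation: str = "unknown",
) -> tuple[str, list[tuple[str, str]]]:
    """Rule-based exonuclease/endonuclease call for one family.

    Majority vote over four structural/conservation indicators:

    1. the extra β1 Glu/Asp (``b1_exo``) conserved → exonuclease;
    2. the second canonical catalytic residue sits in α2 in 3'-5'
       exonucleases but at the C-end of β4 in the endonucleases, so
       α2-only → exonuclease and β4-only → endonuclease;
    3. the β5 Asp/Glu, common in exonucleases, leans exonuclease at
       half weight (resolvases share it);
    4. a reversed C-terminal helix (polypeptide running antiparallel to
       β1) → exonuclease, parallel → endonuclease.

    Returns the verdict plus a per-indicator report; fewer than two
    informative indicators, or a tie, yields ``indeterminate``.
    """
    required = {"b1_exo", "b4", "a2", "b5"}
    missing = required - set(profile)
    if missing:
        raise InputError(f"profile missing positions: {sorted(missing)}")
    if helix_orientation not in ("parallel_to_b1", "reversed", "unknown"):
        raise InputError(f"unknown helix orientation {helix_orientation!r}")

    exo = endo = 0.0
    informative = 0
    report: list[tuple[str, str]] = []

    if profile["b1_exo"]:
        exo += 1
        informative += 1
        report.append(("b1_exo conserved", "exo"))
    else:
        report.append(("b1_exo absent", "uninformative"))

    if profile["a2"] and not profile["b4"]:
        exo += 1
        informative += 1
        report.append(("catalytic residue in a2, not b4", "exo"))
    elif profile["b4"] and not profile["a2"]:
        endo += 1
        informative += 1
        report.append(("catalytic residue in b4, not a2", "endo"))
    else:
        report.append(("a2/b4 ambiguous", "uninformative"))

    if profile["b5"]:
        exo += 0.5
        informative += 1
        report.append(("b5 conserved", "exo (half weight)"))
    else:
        report.append(("b5 absent", "uninformative"))

    if helix_orientation == "reversed":
        exo += 1
        informative += 1
        report.append(("C-terminal helix reversed", "exo"))
    elif helix_orientation == "parallel_to_b1":
        endo += 1
        informative += 1
        report.append(("C-terminal helix parallel to b1", "endo"))
    else:
        report.append(("helix orientation unknown", "uninformative"))

    if informative < 2 or exo == endo:
        return INDETERMINATE, report
    return (EXONUCLEASE if exo > endo else ENDONUCLEASE), report
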