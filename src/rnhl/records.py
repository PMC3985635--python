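"""Sequence records and FASTA input/output.

A :class:`SequenceRecord` is one protein (or excised nuclease-domain)
sequence together with the metadata the downstream stages care about:
an optional family / clade label and the flags used when picking family
representatives (known 3D structure, curated functional annotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SequenceRecord:
    """One protein/domain sequence with optional truth labels and flags."""

    id: str
    seq: str
    family: str | None = None
    clade: str | None = None
    has_structure: bool = False
    curated_annotation: bool = False
    meta: dict = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects."""
    return [
        SequenceRecord(id=r.id, seq=str(r.seq).upper())
        for r in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (one line per sequence)."""
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta-2line")
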