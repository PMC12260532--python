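"""Protein sequence primitives and FASTA I/O.

The evolving unit of the simulator is a plain amino acid sequence carrying
provenance: which individual it descended from and in which generation it
appeared.  Sequences are immutable; every mutation produces a new object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical one-letter amino acid codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class ProteinSequence:
    """One evolving chain with identity and provenance.

    Parameters
    ----------
    id : str
        Opaque unique token for this individual.
    residues : str
        Amino acid sequence over the 20 canonical one-letter codes.
    generation : int
        Generation index at which this individual appeared (founders are 0).
    parent_id : str or None
        Identity of the immediate ancestor, ``None`` for founders.
    """

    id: str
    residues: str
    generation: int = 0
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-canonical residues: {sorted(bad)}"
            )
        if self.generation < 0:
            raise ValueError("generation must be non-negative")

    def __len__(self) -> int:
        return len(self.residues)


def random_residues(length: int, rng: np.random.Generator) -> str:
    """Uniform random amino acid string of the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def read_fasta(path) -> list[ProteinSequence]:
    """Read sequences from a FASTA file (founders generation 0, no parents)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper()))
    if not out:
        raise ValueError(f"no sequences found in {path}")
    return out


def write_fasta(sequences, path, width: int = 60) -> None:
    """Write sequences to FASTA, wrapped at `width` columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=f"generation={s.generation}")
        for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width or None)
        writer.write_file(records)
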