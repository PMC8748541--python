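"""Coding-sequence container and codon-level helpers.

Positions follow two coordinate systems. *Construct* coordinates are 1-based
indices into the expressed open reading frame. *Canonical* coordinates add a
fixed ``numbering_offset`` so that residues of a truncated construct (e.g. a
pro-domain-deleted protease) are reported with the numbering used for the
full-length protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio import SeqIO

_VALID_BASES = frozenset("ACGT")
STOP = "*"


@dataclass(frozen=True)
class CodingSequence:
    """An unambiguous protein-coding DNA sequence.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA header style).
    nucleotides : str
        Uppercase DNA, length divisible by 3, ``ACGT`` only.
    numbering_offset : int
        Added to 1-based construct residue positions to obtain canonical
        residue numbering. A construct missing a 28-residue pro-domain uses
        offset 28.
    """

    id: str
    nucleotides: str
    numbering_offset: int = 0
    _protein: str = field(init=False, repr=False, compare=False, default="")

    def __post_init__(self) -> None:
        nt = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", nt)
        if len(nt) == 0 or len(nt) % 3 != 0:
            raise ValueError(
                f"coding sequence {self.id!r} has length {len(nt)}, "
                "which is not a positive multiple of 3"
            )
        bad = set(nt) - _VALID_BASES
        if bad:
            raise ValueError(f"ambiguous/invalid bases in {self.id!r}: {sorted(bad)}")
        protein = str(Seq(nt).translate())
        if STOP in protein[:-1]:
            raise ValueError(f"reference {self.id!r} contains an internal stop codon")
        object.__setattr__(self, "_protein", protein)

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    @property
    def protein(self) -> str:
        """Translation of the reference (may end in '*')."""
        return self._protein

    def codon(self, construct_pos: int) -> str:
        """Codon at 1-based construct residue position."""
        i = (construct_pos - 1) * 3
        return self.nucleotides[i : i + 3]

    def canonical(self, construct_pos: int) -> int:
        return construct_pos + self.numbering_offset

    @classmethod
    def from_fasta(cls, path, numbering_offset: int = 0) -> "CodingSequence":
        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(id=rec.id, nucleotides=str(rec.seq), numbering_offset=numbering_offset)

    @classmethod
    def all_from_fasta(cls, path, numbering_offset: int = 0) -> list["CodingSequence"]:
        return [
            cls(id=r.id, nucleotides=str(r.seq), numbering_offset=numbering_offset)
            for r in SeqIO.parse(str(path), "fasta")
        ]


def translate_codons(nt: str) -> str:
    """Codon-by-codon translation that never truncates at stop codons."""
    return str(Seq(nt).translate())


def substitution_key(position: int, ref: str, alt: str) -> str:
    """Human-readable substitution label, e.g. ``D175A`` or ``W53*``."""
    return f"{ref}{position}{alt}"
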