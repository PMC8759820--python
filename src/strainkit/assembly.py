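"""Genome assembly containers and FASTA input/output.

An :class:`Assembly` is an ordered collection of named contigs, each an
uppercase DNA string with an optional circularity flag.  It is the substrate
of every locating and counting operation in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case-preserving, N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Contig:
    name: str
    sequence: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    """Named contigs with sequences and circularity flags."""

    contigs: Dict[str, Contig] = field(default_factory=dict)

    def add(self, name: str, sequence: str, circular: bool = False) -> None:
        if name in self.contigs:
            raise ValueError(f"duplicate contig name: {name!r}")
        self.contigs[name] = Contig(name, sequence.upper(), circular)

    def __getitem__(self, name: str) -> Contig:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs.values())

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.contigs)

    def total_length(self) -> int:
        return sum(len(c) for c in self)

    def reverse_complement(self) -> "Assembly":
        out = Assembly()
        for c in self:
            out.add(c.name, revcomp(c.sequence), c.circular)
        return out

    @classmethod
    def from_fasta(cls, path) -> "Assembly":
        """Read a multi-record FASTA.  A record is flagged circular when its
        description contains the token ``circular=true`` (as written by
        :meth:`to_fasta`)."""
        asm = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            circular = "circular=true" in rec.description.lower()
            asm.add(rec.id, str(rec.seq), circular)
        if not asm.contigs:
            raise ValueError(f"no FASTA records in {path}")
        return asm

    @classmethod
    def from_sequences(cls, seqs: Dict[str, str]) -> "Assembly":
        asm = cls()
        for name, seq in seqs.items():
            asm.add(name, seq)
        return asm

    def to_fasta(self, path) -> None:
        """Write 60-column-wrapped FASTA; circular contigs are annotated
        ``circular=true`` in the description."""
        records = [
            SeqRecord(
                Seq(c.sequence),
                id=c.name,
                description="circular=true" if c.circular else "",
            )
            for c in self
        ]
        SeqIO.write(records, str(path), "fasta")


def read_fasta_sequences(path) -> Dict[str, str]:
    """Read FASTA into an ordered ``{id: uppercase sequence}`` mapping."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def iter_pairs(names: Iterable[str]) -> Iterator[Tuple[str, str]]:
    """All unordered pairs, in input order."""
    names = list(names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            yield a, b
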