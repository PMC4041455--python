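"""Nucleotide sequence containers and FASTA I/O.

All coordinates in this package are 0-based, half-open.  Conversion to
1-based conventions happens only at file boundaries (SAM, VCF).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping, Union

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")
_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_RC_TABLE)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMP_TABLE)


@dataclass(frozen=True)
class GenomeSequence:
    """One named chromosome/contig.

    The sequence is normalised to uppercase on construction; characters
    outside {A,C,G,T,N} raise ``ValueError``.
    """

    name: str
    seq: str

    def __post_init__(self) -> None:
        norm = self.seq.upper()
        bad = set(norm) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.name!r} contains invalid characters: {sorted(bad)!r}"
            )
        object.__setattr__(self, "seq", norm)

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


class Genome:
    """An ordered collection of :class:`GenomeSequence` records.

    Behaves as a mapping from sequence name to record.  Multi-sequence
    FASTA files are supported; desk-scale synthetic genomes typically
    hold a single chromosome.
    """

    def __init__(self, sequences: Iterable[GenomeSequence]):
        self._seqs: Dict[str, GenomeSequence] = {}
        for rec in sequences:
            if rec.name in self._seqs:
                raise ValueError(f"duplicate sequence name {rec.name!r}")
            self._seqs[rec.name] = rec

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str]) -> "Genome":
        return cls(GenomeSequence(name, seq) for name, seq in mapping.items())

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "Genome":
        records = SeqIO.parse(str(path), "fasta")
        return cls(GenomeSequence(r.id, str(r.seq)) for r in records)

    def to_fasta(self, path: Union[str, Path], width: int = 70) -> None:
        with open(path, "w") as fh:
            for rec in self._seqs.values():
                fh.write(f">{rec.name}\n")
                for i in range(0, len(rec.seq), width):
                    fh.write(rec.seq[i : i + width] + "\n")

    def __getitem__(self, name: str) -> GenomeSequence:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def items(self):
        return self._seqs.items()

    def names(self):
        return list(self._seqs)

    def sequences(self):
        return list(self._seqs.values())

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def digest(self) -> str:
        """Stable content digest, used to key on-disk mapability caches."""
        h = hashlib.sha256()
        for name, rec in self._seqs.items():
            h.update(name.encode())
            h.update(b"\x00")
            h.update(rec.seq.encode())
            h.update(b"\x00")
        return h.hexdigest()


def as_genome(obj: Union[Genome, GenomeSequence, Mapping[str, str]]) -> Genome:
    """Coerce a single sequence or name->seq mapping into a :class:`Genome`."""
    if isinstance(obj, Genome):
        return obj
    if isinstance(obj, GenomeSequence):
        return Genome([obj])
    return Genome.from_dict(obj)
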