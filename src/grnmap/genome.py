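"""Genome sequence access: FASTA loading, slicing, reverse complement."""

from __future__ import annotations

import gzip
from typing import Dict, Iterator

from Bio import SeqIO

from .intervals import GenomicInterval

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """In-memory genome: chromosome name -> uppercase nucleotide string.

    Suited to the compact genomes this pipeline scans (regulatory elements,
    not whole-genome alignment); sequences are held as plain strings.
    """

    def __init__(self, chroms: Dict[str, str]):
        self._chroms = {name: seq.upper() for name, seq in chroms.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSequence":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as handle:
            records = {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls(records)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def __iter__(self) -> Iterator[str]:
        return iter(self._chroms)

    def chrom_length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def fetch(self, iv: GenomicInterval) -> str:
        """Forward-strand sequence of ``iv``; callers reverse-complement for − scans."""
        if iv.chrom not in self._chroms:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        seq = self._chroms[iv.chrom]
        if iv.end > len(seq):
            raise IndexError(
                f"interval {iv} exceeds {iv.chrom} length {len(seq)}"
            )
        return seq[iv.start : iv.end]

    def base_at(self, chrom: str, pos0: int) -> str:
        return self.fetch(GenomicInterval(chrom, pos0, pos0 + 1))


def fetch_sequence(genome: GenomeSequence, iv: GenomicInterval) -> str:
    return genome.fetch(iv)
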