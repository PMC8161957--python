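"""Genomic coordinate primitives.

All internal coordinates are 0-based, half-open ``[start, end)``. File formats
that use other conventions (GTF: 1-based inclusive; VCF/variant tables:
1-based positions) are converted at the parser boundary, never downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(f"start < end required, got [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def key(self) -> tuple:
        """Location identity ignoring strand (element identity in networks)."""
        return (self.chrom, self.start, self.end)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base on the same chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class GeneModel:
    """A gene with its body span and strand-aware transcription start site."""

    gene_id: str
    symbol: str
    tss: int
    strand: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        expected = self.body.start if self.strand == "+" else self.body.end - 1
        if self.tss != expected:
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with "
                f"{self.strand} strand body {self.body}"
            )


def define_promoter(gene: GeneModel, upstream: int = 2000, downstream: int = 200) -> GenomicInterval:
    """Promoter window around the TSS, oriented by gene strand, clipped at 0.

    On ``+``: ``[tss - upstream, tss + downstream)``.
    On ``-``: ``[tss - downstream + 1, tss + upstream + 1)`` — the mirror image,
    so windows on either strand have equal length for equal (upstream, downstream).
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    if upstream == 0 and downstream == 0:
        raise ValueError("promoter window must have positive extent")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream + 1, gene.tss + upstream + 1
    return GenomicInterval(gene.body.chrom, max(0, start), end, gene.strand)


_NUCS = frozenset("ACGT")


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide substitution at a 1-based position."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    id: str = "."
    pvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref_allele not in _NUCS or self.alt_allele not in _NUCS:
            raise ValueError(
                f"variant {self.id}: alleles must be single nucleotides in ACGT, "
                f"got {self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"variant {self.id}: ref and alt alleles are identical")
        if self.pvalue is not None and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"variant {self.id}: p-value {self.pvalue} outside [0, 1]")

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1
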