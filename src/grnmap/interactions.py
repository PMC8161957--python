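"""Chromatin-interaction input and anchor annotation.

Anchor pairs (e.g. Hi-C loops in BEDPE) are classified against gene promoter
windows: an anchor overlapping a promoter is a promoter element for that gene;
its partner anchor becomes a candidate distal element (enhancer) for the same
gene. Promoter-promoter pairs act as mutual distal regulators. Interactions
touching no promoter are dropped — they cannot be wired to a gene.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .intervals import GeneModel, GenomicInterval, define_promoter, overlaps

log = logging.getLogger(__name__)


class BedpeParseError(ValueError):
    pass


@dataclass(frozen=True)
class ChromatinInteraction:
    """An unordered pair of interacting genomic anchors."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    score: Optional[float] = None
    source_label: Optional[str] = None

    def canonical(self) -> "ChromatinInteraction":
        if self.anchor_b.key() < self.anchor_a.key():
            return ChromatinInteraction(self.anchor_b, self.anchor_a, self.score, self.source_label)
        return self


@dataclass(frozen=True)
class ElementGeneLink:
    """A regulatory element wired to a gene, with its role on that wire."""

    element: GenomicInterval
    role: str  # "enhancer" | "promoter"
    gene_id: str
    via_interaction: Optional[int] = None  # absent for promoter self-links


def read_interactions(path: str) -> List[ChromatinInteraction]:
    """Read BEDPE (>=6 columns, 0-based half-open); dedup after canonical ordering."""
    opener = gzip.open if str(path).endswith(".gz") else open
    seen = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedpeParseError(
                    f"{path}: line {lineno}: BEDPE needs >= 6 tab-separated columns, got {len(fields)}"
                )
            c1, s1, e1, c2, s2, e2 = fields[:6]
            try:
                s1i, e1i, s2i, e2i = int(s1), int(e1), int(s2), int(e2)
            except ValueError as exc:
                raise BedpeParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if s1i >= e1i or s2i >= e2i:
                log.warning("%s: line %d: empty or inverted anchor, record skipped", path, lineno)
                continue
            score = None
            if len(fields) >= 8:
                try:
                    score = float(fields[7])
                except ValueError:
                    score = None
            inter = ChromatinInteraction(
                GenomicInterval(c1, s1i, e1i), GenomicInterval(c2, s2i, e2i), score=score
            ).canonical()
            key = (inter.anchor_a.key(), inter.anchor_b.key())
            seen.setdefault(key, inter)
    return list(seen.values())


def read_bed_intervals(path: str) -> List[GenomicInterval]:
    """Plain BED3+ reader for element/open-chromatin region lists."""
    opener = gzip.open if str(path).endswith(".gz") else open
    out = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedpeParseError(f"{path}: line {lineno}: BED needs >= 3 columns")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


class _PromoterIndex:
    """chrom -> IntervalTree of promoter windows carrying gene ids."""

    def __init__(self, genes: Sequence[GeneModel], upstream: int, downstream: int):
        self.trees: Dict[str, IntervalTree] = {}
        for g in genes:
            win = define_promoter(g, upstream, downstream)
            self.trees.setdefault(win.chrom, IntervalTree()).addi(win.start, win.end, g.gene_id)

    def genes_overlapping(self, iv: GenomicInterval) -> List[str]:
        tree = self.trees.get(iv.chrom)
        if tree is None:
            return []
        return sorted({hit.data for hit in tree.overlap(iv.start, iv.end)})


def annotate_anchors(
    interactions: Sequence[ChromatinInteraction],
    genes: Sequence[GeneModel],
    promoter_upstream: int = 2000,
    promoter_downstream: int = 200,
    candidate_elements: Optional[Iterable[GenomicInterval]] = None,
) -> List[ElementGeneLink]:
    """Classify anchors as promoter/enhancer elements and wire them to genes.

    ``candidate_elements`` optionally restricts which anchors may serve as
    enhancers: an enhancer-role link is kept only if its element overlaps at
    least one interval in the list.
    """
    if not genes:
        raise ValueError("annotate_anchors requires a non-empty gene set")
    index = _PromoterIndex(genes, promoter_upstream, promoter_downstream)
    allowed = list(candidate_elements) if candidate_elements is not None else None

    def enhancer_allowed(iv: GenomicInterval) -> bool:
        if allowed is None:
            return True
        return any(overlaps(iv, a) for a in allowed)

    links: Dict[Tuple[tuple, str, str, Optional[int]], ElementGeneLink] = {}

    def add(element: GenomicInterval, role: str, gene_id: str, via: Optional[int]) -> None:
        key = (element.key(), role, gene_id, via)
        if key not in links:
            links[key] = ElementGeneLink(element, role, gene_id, via)

    for idx, inter in enumerate(interactions):
        a, b = inter.anchor_a, inter.anchor_b
        genes_a = index.genes_overlapping(a)
        genes_b = index.genes_overlapping(b)
        if not genes_a and not genes_b:
            continue
        for g in genes_a:
            add(a, "promoter", g, None)
        for g in genes_b:
            add(b, "promoter", g, None)
        # partner of a promoter anchor is a distal element for that promoter's genes
        if genes_a and enhancer_allowed(b):
            for g in genes_a:
                add(b, "enhancer", g, idx)
        if genes_b and enhancer_allowed(a):
            for g in genes_b:
                add(a, "enhancer", g, idx)
    return list(links.values())


def links_to_rows(links: Iterable[ElementGeneLink]) -> List[dict]:
    rows = [
        {
            "chrom": l.element.chrom,
            "start": l.element.start,
            "end": l.element.end,
            "role": l.role,
            "gene_id": l.gene_id,
            "via_interaction": "" if l.via_interaction is None else l.via_interaction,
        }
        for l in links
    ]
    rows.sort(key=lambda r: (r["gene_id"], r["chrom"], r["start"], r["end"], r["role"]))
    return rows
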