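"""Gene annotation readers (GTF 2.2 and BED12), producing GeneModel records.

Both dialects are converted to internal 0-based half-open coordinates at this
boundary. Duplicate gene ids collapse to the record with the longest body.
"""

from __future__ import annotations

import gzip
import logging
import re
from typing import Dict, List

from .intervals import GeneModel, GenomicInterval

log = logging.getLogger(__name__)

_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')
_GTF_GENE_NAME = re.compile(r'gene_name\s+"([^"]+)"')


class AnnotationParseError(ValueError):
    pass


def _open_text(path: str):
    return gzip.open(path, "rt") if str(path).endswith(".gz") else open(path, "rt")


def _collapse_duplicates(genes: List[GeneModel]) -> List[GeneModel]:
    best: Dict[str, GeneModel] = {}
    for g in genes:
        cur = best.get(g.gene_id)
        if cur is None or len(g.body) > len(cur.body):
            best[g.gene_id] = g
    return list(best.values())


def _make_gene(gene_id: str, symbol: str, chrom: str, start0: int, end0: int, strand: str) -> GeneModel:
    body = GenomicInterval(chrom, start0, end0, strand)
    tss = start0 if strand == "+" else end0 - 1
    return GeneModel(gene_id=gene_id, symbol=symbol, tss=tss, strand=strand, body=body)


def read_gtf(path: str, feature: str = "gene") -> List[GeneModel]:
    """Read gene records from a GTF 2.2 file (1-based inclusive coordinates).

    Records whose feature column differs from ``feature`` are ignored; if the
    file contains no such feature, all features are considered and the widest
    span per gene_id wins (covers transcript-only GTFs).
    """
    genes: List[GeneModel] = []
    fallback: List[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated GTF columns, got {len(fields)}"
                )
            chrom, _source, feat, start, end, _score, strand, _frame, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                log.warning("%s: line %d: unknown strand %r, record skipped", path, lineno, strand)
                continue
            m = _GTF_GENE_ID.search(attrs)
            if m is None:
                raise AnnotationParseError(f"{path}: line {lineno}: missing gene_id attribute")
            gene_id = m.group(1)
            name_m = _GTF_GENE_NAME.search(attrs)
            symbol = name_m.group(1) if name_m else gene_id
            gene = _make_gene(gene_id, symbol, chrom, start_i - 1, end_i, strand)
            (genes if feat == feature else fallback).append(gene)
    return _collapse_duplicates(genes if genes else fallback)


def read_bed12(path: str) -> List[GeneModel]:
    """Read gene records from BED12 (0-based half-open; name column = gene id)."""
    genes: List[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected 12 BED12 columns, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                log.warning("%s: line %d: unknown strand %r, record skipped", path, lineno, strand)
                continue
            try:
                genes.append(_make_gene(name, name, chrom, int(start), int(end), strand))
            except ValueError as exc:
                raise AnnotationParseError(f"{path}: line {lineno}: {exc}") from exc
    return _collapse_duplicates(genes)


def read_gene_annotation(path: str) -> List[GeneModel]:
    """Dispatch on extension: .gtf(.gz) -> GTF, .bed(.gz) -> BED12."""
    stem = str(path)[:-3] if str(path).endswith(".gz") else str(path)
    if stem.endswith((".gtf", ".gff")):
        return read_gtf(path)
    if stem.endswith(".bed"):
        return read_bed12(path)
    raise ValueError(f"cannot infer annotation dialect from {path!r} (expect .gtf or .bed)")
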