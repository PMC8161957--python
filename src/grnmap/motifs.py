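"""TF motif handling: JASPAR PFMs, log-odds PWMs, element scanning, and the
reference TF->element->gene network.

Scoring model
-------------
A position frequency matrix (base counts per column) is turned into a
position weight matrix of log2 odds against a background distribution, with a
pseudocount proportional to the background added per column:

    p[b, j] = (counts[b, j] + pseudocount * background[b]) / (colsum_j + pseudocount)
    logodds[b, j] = log2(p[b, j] / background[b])

A window's score is the sum of its per-position log-odds; ``rel_score``
rescales it to [0, 1] between the matrix's minimum and maximum attainable
scores, which makes one threshold comparable across motif widths. Windows
containing N score -inf and never hit. Both strands are scanned; hits on the
minus strand are reported in forward-strand coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import motifs as bio_motifs

from .genome import reverse_complement
from .intervals import GenomicInterval

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


class JasparParseError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPfm:
    """Position frequency matrix: base counts per motif column (rows A,C,G,T)."""

    tf_name: str
    counts: np.ndarray  # shape (4, w)
    matrix_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4 or c.shape[1] < 1:
            raise ValueError(f"motif {self.matrix_id or self.tf_name}: counts must be 4 x w")
        if (c < 0).any():
            raise ValueError(f"motif {self.matrix_id or self.tf_name}: negative counts")
        if (c.sum(axis=0) <= 0).any():
            raise ValueError(f"motif {self.matrix_id or self.tf_name}: zero column sum")
        object.__setattr__(self, "counts", c)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class MotifPwm:
    """Log2-odds scoring matrix derived from a PFM."""

    tf_name: str
    logodds: np.ndarray  # shape (4, w); -inf allowed
    background: Tuple[float, float, float, float]
    pseudocount: float
    matrix_id: str = ""

    @property
    def width(self) -> int:
        return self.logodds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.logodds.min(axis=0).sum())

    def rel_score(self, score: float) -> float:
        lo, hi = self.min_score, self.max_score
        if not math.isfinite(score):
            return float("-inf")
        if hi == lo:
            return 1.0
        return (score - lo) / (hi - lo)


@dataclass(frozen=True)
class MotifHit:
    tf_name: str
    window: GenomicInterval
    strand: str
    score: float
    rel_score: float


@dataclass(frozen=True)
class ReferenceEdge:
    """Candidate regulatory wire: TF with >=1 binding site on an element linked to a gene."""

    tf_name: str
    element: GenomicInterval
    role: str
    gene_id: str
    supporting_hits: int

    def __post_init__(self) -> None:
        if self.supporting_hits < 1:
            raise ValueError("supporting_hits must be >= 1")


def read_jaspar(path: str) -> List[MotifPfm]:
    """Parse a JASPAR-format PFM text file (``>ID NAME`` + 4 bracketed rows)."""
    try:
        with open(path) as handle:
            records = bio_motifs.parse(handle, "jaspar")
    except Exception as exc:
        raise JasparParseError(f"{path}: not parseable as JASPAR PFM text: {exc}") from exc
    out: List[MotifPfm] = []
    for rec in records:
        name = (rec.name or rec.matrix_id or "").upper()
        counts = np.array([list(rec.counts[b]) for b in BASES], dtype=float)
        try:
            out.append(MotifPfm(tf_name=name, counts=counts, matrix_id=rec.matrix_id or name))
        except ValueError as exc:
            raise JasparParseError(str(exc)) from exc
    if not out:
        raise JasparParseError(f"{path}: no motif records found")
    return out


def pfm_to_pwm(
    pfm: MotifPfm,
    pseudocount: float = 0.8,
    background: Sequence[float] = UNIFORM_BACKGROUND,
) -> MotifPwm:
    bg = np.asarray(background, dtype=float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("background must be a length-4 probability vector")
    colsum = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    with np.errstate(divide="ignore"):
        logodds = np.log2(probs / bg[:, None])  # zero cells -> -inf, never a hit
    return MotifPwm(
        tf_name=pfm.tf_name,
        logodds=logodds,
        background=tuple(bg),
        pseudocount=pseudocount,
        matrix_id=pfm.matrix_id,
    )


def encode_sequence(seq: str) -> np.ndarray:
    """Map ACGT->0..3, anything else (N) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, logodds5: np.ndarray) -> np.ndarray:
    """Scores of every width-w window of ``codes`` (len n -> n-w+1 scores)."""
    w = logodds5.shape[1]
    n = codes.shape[0]
    if n < w:
        return np.empty(0)
    scores = np.zeros(n - w + 1)
    for j in range(w):
        scores += logodds5[codes[j : n - w + 1 + j], j]
    return scores


def _with_n_row(logodds: np.ndarray) -> np.ndarray:
    return np.vstack([logodds, np.full((1, logodds.shape[1]), -np.inf)])


def scan_sequence(
    seq: str,
    pwm: MotifPwm,
    threshold: float = 0.8,
    offset: Optional[GenomicInterval] = None,
) -> List[MotifHit]:
    """All windows on both strands with rel_score >= threshold.

    ``offset`` maps hit windows into genome coordinates (the scanned sequence
    is taken to be the forward strand of ``offset``); without it, coordinates
    are sequence-local on a pseudo-chromosome named "seq".
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if offset is not None and len(offset) != len(seq):
        raise ValueError("offset interval length must equal sequence length")
    chrom = offset.chrom if offset is not None else "seq"
    base = offset.start if offset is not None else 0
    w = pwm.width
    if len(seq) < w:
        return []
    lo5 = _with_n_row(pwm.logodds)
    hits: List[MotifHit] = []
    span = pwm.max_score - pwm.min_score

    def rel(scores: np.ndarray) -> np.ndarray:
        if span == 0:
            return np.where(np.isfinite(scores), 1.0, -np.inf)
        return (scores - pwm.min_score) / span

    fwd = _window_scores(encode_sequence(seq), lo5)
    rc = _window_scores(encode_sequence(reverse_complement(seq)), lo5)
    rel_fwd, rel_rc = rel(fwd), rel(rc)
    n = len(seq)
    for i in np.flatnonzero(rel_fwd >= threshold):
        hits.append(
            MotifHit(pwm.tf_name, GenomicInterval(chrom, base + int(i), base + int(i) + w, "+"),
                     "+", float(fwd[i]), float(rel_fwd[i]))
        )
    for k in np.flatnonzero(rel_rc >= threshold):
        start = n - int(k) - w  # position of the rc window on the forward strand
        hits.append(
            MotifHit(pwm.tf_name, GenomicInterval(chrom, base + start, base + start + w, "-"),
                     "-", float(rc[k]), float(rel_rc[k]))
        )
    hits.sort(key=lambda h: (h.window.start, h.strand))
    return hits


def score_best_window(seq: str, pwm: MotifPwm) -> float:
    """Best rel_score over all windows/strands of ``seq`` (-inf if shorter than motif)."""
    w = pwm.width
    if len(seq) < w:
        return float("-inf")
    lo5 = _with_n_row(pwm.logodds)
    best = max(
        float(_window_scores(encode_sequence(seq), lo5).max()),
        float(_window_scores(encode_sequence(reverse_complement(seq)), lo5).max()),
    )
    return pwm.rel_score(best)


def build_reference_network(
    links: Iterable,
    hits_per_element: Dict[tuple, List[MotifHit]],
) -> List[ReferenceEdge]:
    """Join element->gene links with per-element motif hits.

    ``hits_per_element`` maps ``element.key()`` to the hits found on that
    element; hits of the same TF on one element collapse into one edge with a
    supporting count (pooled across matrices of the same TF name).
    """
    edges: Dict[Tuple[str, tuple, str, str], ReferenceEdge] = {}
    counts: Dict[Tuple[str, tuple, str, str], int] = {}
    meta: Dict[Tuple[str, tuple, str, str], tuple] = {}
    for link in links:
        for hit in hits_per_element.get(link.element.key(), []):
            key = (hit.tf_name, link.element.key(), link.role, link.gene_id)
            counts[key] = counts.get(key, 0) + 1
            meta[key] = (link.element, link.role, link.gene_id)
    for key, n in counts.items():
        element, role, gene_id = meta[key]
        edges[key] = ReferenceEdge(key[0], element, role, gene_id, n)
    out = list(edges.values())
    out.sort(key=lambda e: (e.gene_id, e.tf_name, e.element.key(), e.role))
    return out
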