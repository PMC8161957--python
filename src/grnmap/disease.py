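"""Mapping disease variants onto a cell-type GRN.

GWAS SNPs (a fine-mapped credible set plus any variant below a p-value
threshold) are intersected with the network's enhancers and promoters. For
each variant landing in an element, every motif window covering the variant is
scored on both strands under the reference and the alternate allele; the best
relative score per allele summarizes whether the variant creates or destroys a
binding site. A disruption event on an element implicates a target gene when
the disrupted TF regulates that gene through that element in the GRN
(optionally, any TF with a site on the element — ``tf_specific=False``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .genome import GenomeSequence
from .grn import GrnEdge
from .intervals import GenomicInterval, Variant
from .motifs import MotifPwm, score_best_window

log = logging.getLogger(__name__)


@dataclass
class GwasVariantSet:
    """Variants retained for mapping: credible-set members unconditionally,
    others only with association p strictly below ``pvalue_max``."""

    variants: List[Variant]
    credible_ids: Set[str]
    pvalue_max: float = 5e-5


@dataclass(frozen=True)
class DisruptionEvent:
    variant: Variant
    tf_name: str
    element: GenomicInterval
    role: str
    best_ref_score: float
    best_alt_score: float

    @property
    def delta(self) -> float:
        return self.best_alt_score - self.best_ref_score


@dataclass
class DiseaseGeneCall:
    gene_id: str
    cell_type: str
    elements: List[GenomicInterval]
    variants: List[str]
    tfs: List[str]


def read_variants_tsv(path: str) -> List[Variant]:
    """TSV with columns chrom, pos, id, ref, alt, pvalue (header required)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    out = []
    for row in df.itertuples(index=False):
        pv = getattr(row, "pvalue", None)
        pv = None if pv is None or pd.isna(pv) else float(pv)
        out.append(Variant(chrom=str(row.chrom), pos=int(row.pos), ref_allele=str(row.ref),
                           alt_allele=str(row.alt), id=str(row.id), pvalue=pv))
    return out


def read_variants_vcf(path: str) -> List[Variant]:
    """Sites-only VCF; non-SNV records are skipped; P stored in INFO/PVAL if present."""
    from cyvcf2 import VCF

    out = []
    for rec in VCF(path):
        if len(rec.REF) != 1 or len(rec.ALT) != 1 or len(rec.ALT[0]) != 1:
            log.warning("skipping non-SNV record at %s:%d", rec.CHROM, rec.POS)
            continue
        pv = rec.INFO.get("PVAL")
        out.append(Variant(chrom=rec.CHROM, pos=rec.POS, ref_allele=rec.REF,
                           alt_allele=rec.ALT[0], id=rec.ID or ".",
                           pvalue=None if pv is None else float(pv)))
    return out


def filter_variants(raw: Iterable[Variant], credible_ids: Optional[Iterable[str]] = None,
                    pvalue_max: float = 5e-5) -> GwasVariantSet:
    credible = set(credible_ids or ())
    kept = []
    for v in raw:
        if v.id in credible:
            kept.append(v)
        elif v.pvalue is not None and v.pvalue < pvalue_max:
            kept.append(v)
        elif v.pvalue is None:
            log.warning("variant %s has no p-value and is not in the credible set; excluded", v.id)
    return GwasVariantSet(variants=kept, credible_ids=credible, pvalue_max=pvalue_max)


def overlap_variants_elements(
    var_set: GwasVariantSet, grn: Sequence[GrnEdge]
) -> List[Tuple[Variant, GenomicInterval, str, List[GrnEdge]]]:
    """(variant, element, role, edges-using-element) for every variant inside an element."""
    by_element: Dict[tuple, Tuple[GenomicInterval, str, List[GrnEdge]]] = {}
    for edge in grn:
        for iv, role in edge.elements:
            entry = by_element.setdefault(iv.key() + (role,), (iv, role, []))
            entry[2].append(edge)
    matches = []
    for v in var_set.variants:
        for iv, role, edges in by_element.values():
            if iv.chrom == v.chrom and iv.start <= v.pos0 < iv.end:
                matches.append((v, iv, role, edges))
    return matches


def score_allele_pair(element_seq: str, offset_in_element: int, allele_a: str,
                      allele_b: str, pwm: MotifPwm) -> Tuple[float, float]:
    """Best rel_score over all motif windows covering a position, per allele.

    Exactly antisymmetric under allele swap: the two scores are computed from
    the same window set with only the focal base substituted.
    """
    w = pwm.width
    n = len(element_seq)
    if not 0 <= offset_in_element < n:
        raise ValueError("variant offset outside element")
    lo = max(0, offset_in_element - w + 1)
    hi = min(n, offset_in_element + w)  # the covering region spans < 2w bases
    region = element_seq[lo:hi]
    i = offset_in_element - lo
    seq_a = region[:i] + allele_a + region[i + 1 :]
    seq_b = region[:i] + allele_b + region[i + 1 :]
    return score_best_window(seq_a, pwm), score_best_window(seq_b, pwm)


def score_disruption(
    variant: Variant,
    element: GenomicInterval,
    role: str,
    pwm: MotifPwm,
    genome: GenomeSequence,
    hit_threshold: float = 0.8,
    delta_min: float = 0.10,
) -> Optional[DisruptionEvent]:
    """Score a variant's effect on one motif within one element.

    Returns an event iff the better allele reaches ``hit_threshold`` (a site
    exists under at least one allele) and |alt - ref| >= ``delta_min``.
    """
    if not (element.chrom == variant.chrom and element.start <= variant.pos0 < element.end):
        raise ValueError(f"variant {variant.id} not inside element {element}")
    seq = genome.fetch(element)
    i = variant.pos0 - element.start
    if seq[i] != variant.ref_allele:
        raise ValueError(
            f"variant {variant.id}: genome base {seq[i]!r} at {variant.chrom}:{variant.pos} "
            f"does not match ref allele {variant.ref_allele!r}"
        )
    best_ref, best_alt = score_allele_pair(seq, i, variant.ref_allele, variant.alt_allele, pwm)
    if max(best_ref, best_alt) < hit_threshold:
        return None
    if abs(best_alt - best_ref) < delta_min:
        return None
    return DisruptionEvent(variant, pwm.tf_name, element, role, best_ref, best_alt)


def find_disruption_events(
    var_set: GwasVariantSet,
    grn: Sequence[GrnEdge],
    pwms: Sequence[MotifPwm],
    genome: GenomeSequence,
    hit_threshold: float = 0.8,
    delta_min: float = 0.10,
    losses_only: bool = False,
) -> List[DisruptionEvent]:
    """All (variant, element, TF) disruption events over the GRN's elements."""
    events = []
    seen = set()
    for variant, element, role, _edges in overlap_variants_elements(var_set, grn):
        for pwm in pwms:
            key = (variant.id, element.key(), role, pwm.tf_name)
            if key in seen:
                continue
            seen.add(key)
            ev = score_disruption(variant, element, role, pwm, genome,
                                  hit_threshold=hit_threshold, delta_min=delta_min)
            if ev is None:
                continue
            if losses_only and ev.delta > 0:
                continue
            events.append(ev)
    return events


def call_disease_genes(
    grn: Sequence[GrnEdge],
    events: Sequence[DisruptionEvent],
    cell_type: str,
    tf_specific: bool = True,
) -> List[DiseaseGeneCall]:
    """Group disruption events into per-gene calls through the GRN's wiring.

    ``tf_specific=True`` requires the disrupted motif's TF to be the edge's
    regulator through the affected element; ``False`` implicates a gene when
    any of its elements carries any disrupted site.
    """
    per_gene: Dict[str, Dict[str, set]] = {}
    for ev in events:
        for edge in grn:
            if tf_specific and edge.tf_name != ev.tf_name:
                continue
            if not any(iv.key() == ev.element.key() for iv, _role in edge.elements):
                continue
            slot = per_gene.setdefault(edge.gene_id, {"elements": set(), "variants": set(), "tfs": set()})
            slot["elements"].add(ev.element)
            slot["variants"].add(ev.variant.id)
            slot["tfs"].add(ev.tf_name)
    calls = [
        DiseaseGeneCall(
            gene_id=g,
            cell_type=cell_type,
            elements=sorted(d["elements"]),
            variants=sorted(d["variants"]),
            tfs=sorted(d["tfs"]),
        )
        for g, d in sorted(per_gene.items())
    ]
    return calls


def calls_to_frame(calls: Sequence[DiseaseGeneCall]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "cell_type": c.cell_type,
            "variants": ",".join(c.variants),
            "elements": ",".join(str(iv) for iv in c.elements),
            "tfs": ",".join(c.tfs),
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=["gene_id", "cell_type", "variants", "elements", "tfs"])
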