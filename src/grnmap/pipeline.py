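"""File-level orchestration of the pipeline stages.

Each ``run_*`` function reads the standard input formats, executes one stage
through the library modules, and writes a sorted TSV, so stages can be chained
from the shell or called programmatically. Outputs are deterministic for fixed
seeds and independent of worker count.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from joblib import Parallel, delayed

from .annotation import read_gene_annotation
from .disease import calls_to_frame, call_disease_genes, filter_variants, find_disruption_events, read_variants_tsv, read_variants_vcf
from .expression import ExpressionMatrix, read_expression_mtx, read_expression_tsv
from .genome import GenomeSequence
from .grn import ElasticNetConfig, GrnEdge, grn_to_frame, infer_grn
from .interactions import ElementGeneLink, annotate_anchors, links_to_rows, read_bed_intervals, read_interactions
from .intervals import GenomicInterval
from .motifs import MotifHit, MotifPwm, build_reference_network, pfm_to_pwm, read_jaspar, scan_sequence, ReferenceEdge

log = logging.getLogger(__name__)


def run_interaction(
    bedpe_path: str,
    annotation_path: str,
    out_path: str,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 200,
    candidate_elements_bed: Optional[str] = None,
) -> List[ElementGeneLink]:
    interactions = read_interactions(bedpe_path)
    genes = read_gene_annotation(annotation_path)
    candidates = read_bed_intervals(candidate_elements_bed) if candidate_elements_bed else None
    links = annotate_anchors(interactions, genes, promoter_upstream, promoter_downstream, candidates)
    if not links:
        log.warning("no element-gene links produced from %s", bedpe_path)
    pd.DataFrame(links_to_rows(links)).to_csv(out_path, sep="\t", index=False)
    return links


def read_links_tsv(path: str) -> List[ElementGeneLink]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    links = []
    for row in df.itertuples(index=False):
        via = row.via_interaction
        via = None if pd.isna(via) or via == "" else int(via)
        links.append(ElementGeneLink(GenomicInterval(row.chrom, int(row.start), int(row.end)),
                                     row.role, row.gene_id, via))
    return links


def scan_elements(
    links: Sequence[ElementGeneLink],
    genome: GenomeSequence,
    pwms: Sequence[MotifPwm],
    threshold: float = 0.8,
    n_workers: int = 1,
) -> Dict[tuple, List[MotifHit]]:
    """Scan each distinct element with every motif; output order is sorted and
    therefore independent of the worker count."""
    elements = sorted({l.element for l in links}, key=lambda iv: iv.key())

    def scan_one(iv: GenomicInterval) -> Tuple[tuple, List[MotifHit]]:
        seq = genome.fetch(iv)
        hits: List[MotifHit] = []
        for pwm in pwms:
            hits.extend(scan_sequence(seq, pwm, threshold=threshold, offset=iv))
        hits.sort(key=lambda h: (h.tf_name, h.window.start, h.strand))
        return iv.key(), hits

    if n_workers > 1:
        pairs = Parallel(n_jobs=n_workers)(delayed(scan_one)(iv) for iv in elements)
    else:
        pairs = [scan_one(iv) for iv in elements]
    return dict(pairs)


def run_get_tf(
    links_path: str,
    fasta_path: str,
    jaspar_path: str,
    out_path: str,
    threshold: float = 0.8,
    pseudocount: float = 0.8,
    n_workers: int = 1,
) -> List[ReferenceEdge]:
    links = read_links_tsv(links_path)
    genome = GenomeSequence.from_fasta(fasta_path)
    pwms = [pfm_to_pwm(p, pseudocount=pseudocount) for p in read_jaspar(jaspar_path)]
    hits = scan_elements(links, genome, pwms, threshold=threshold, n_workers=n_workers)
    edges = build_reference_network(links, hits)
    reference_to_frame(edges).to_csv(out_path, sep="\t", index=False)
    return edges


def reference_to_frame(edges: Sequence[ReferenceEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"tf": e.tf_name, "chrom": e.element.chrom, "start": e.element.start,
             "end": e.element.end, "role": e.role, "gene_id": e.gene_id,
             "supporting_hits": e.supporting_hits}
            for e in edges
        ],
        columns=["tf", "chrom", "start", "end", "role", "gene_id", "supporting_hits"],
    )


def read_reference_tsv(path: str) -> List[ReferenceEdge]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        ReferenceEdge(row.tf, GenomicInterval(row.chrom, int(row.start), int(row.end)),
                      row.role, row.gene_id, int(row.supporting_hits))
        for row in df.itertuples(index=False)
    ]


def load_expression(
    expression_path: str,
    cell_types_path: str,
    genes_path: Optional[str] = None,
    barcodes_path: Optional[str] = None,
) -> ExpressionMatrix:
    if str(expression_path).endswith(".mtx"):
        if not (genes_path and barcodes_path):
            raise ValueError("MTX expression requires genes and barcodes sidecars")
        return read_expression_mtx(expression_path, genes_path, barcodes_path, cell_types_path)
    return read_expression_tsv(expression_path, cell_types_path)


def run_get_nt(
    reference_path: str,
    expression_path: str,
    cell_types_path: str,
    cell_type: str,
    out_path: str,
    variant: str = "top_percent",
    open_chromatin_bed: Optional[str] = None,
    genes_path: Optional[str] = None,
    barcodes_path: Optional[str] = None,
    cfg: Optional[ElasticNetConfig] = None,
    mse_max: float = 0.1,
    coef_min: float = 0.01,
    cutoff_percentage: float = 0.10,
) -> List[GrnEdge]:
    reference = read_reference_tsv(reference_path)
    expr = load_expression(expression_path, cell_types_path, genes_path, barcodes_path)
    open_regions = read_bed_intervals(open_chromatin_bed) if open_chromatin_bed else None
    edges, fits = infer_grn(reference, expr, cell_type, cfg=cfg, variant=variant,
                            open_regions=open_regions, mse_max=mse_max, coef_min=coef_min,
                            cutoff_percentage=cutoff_percentage)
    grn_to_frame(edges, fits, variant=variant).to_csv(out_path, sep="\t", index=False)
    return edges


def read_grn_tsv(path: str) -> List[GrnEdge]:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target_gene": str})
    edges = []
    for row in df.itertuples(index=False):
        elems = []
        if isinstance(row.elements, str) and row.elements:
            for token in row.elements.split(";"):
                loc, role = token.rsplit(":", 1)
                chrom, span = loc.rsplit(":", 1)
                start, end = span.split("-")
                elems.append((GenomicInterval(chrom, int(start), int(end)), role))
        edges.append(GrnEdge(row.tf, row.target_gene, float(row.coefficient), tuple(elems)))
    return edges


def run_dis_genes(
    grn_path: str,
    variants_path: str,
    fasta_path: str,
    jaspar_path: str,
    out_path: str,
    cell_type: str,
    credible_ids_path: Optional[str] = None,
    pvalue_max: float = 5e-5,
    hit_threshold: float = 0.8,
    delta_min: float = 0.10,
    pseudocount: float = 0.8,
    tf_specific: bool = True,
):
    grn = read_grn_tsv(grn_path)
    if str(variants_path).endswith(".vcf"):
        raw = read_variants_vcf(variants_path)
    else:
        raw = read_variants_tsv(variants_path)
    credible = None
    if credible_ids_path:
        credible = [l.strip() for l in Path(credible_ids_path).read_text().splitlines() if l.strip()]
    var_set = filter_variants(raw, credible_ids=credible, pvalue_max=pvalue_max)
    genome = GenomeSequence.from_fasta(fasta_path)
    pwms = [pfm_to_pwm(p, pseudocount=pseudocount) for p in read_jaspar(jaspar_path)]
    events = find_disruption_events(var_set, grn, pwms, genome,
                                    hit_threshold=hit_threshold, delta_min=delta_min)
    calls = call_disease_genes(grn, events, cell_type, tf_specific=tf_specific)
    calls_to_frame(calls).to_csv(out_path, sep="\t", index=False)
    return calls
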