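"""Seeded generator of a complete toy multi-omics dataset with known truth.

The generator lays out a compact genome of gene and enhancer slots, plants TF
consensus sites in enhancers wired to target genes, pairs those enhancers with
their targets' promoters as chromatin interactions, simulates linear-Gaussian
single-cell expression driven by the planted TF -> gene effects (two cell
types with disjoint planted wiring), and places motif-breaking SNPs on planted
sites plus neutral SNPs in element-free background. Every emitted file is a
deterministic function of the seed.

The expression model is linear with Gaussian noise because the inference stage
is linear regression: recovery of the planted wiring then has an exact oracle
(the generating coefficients). Count-like matrices (for the preprocessing
path) are produced by exponentiating and rounding the latent values; the
continuous latent matrix is emitted alongside for direct regression use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.io import mmwrite
from scipy.sparse import csr_matrix

from .expression import ExpressionMatrix
from .genome import GenomeSequence, reverse_complement
from .intervals import GeneModel, GenomicInterval, Variant, define_promoter
from .interactions import ChromatinInteraction
from .motifs import BASES, MotifPfm, pfm_to_pwm
from .disease import score_allele_pair

SLOT = 7000  # bp per genome slot; promoter windows never cross slot borders
GENE_OFFSET = 2500
GENE_LENGTH = 1000
NEUTRAL_OFFSET = 6500  # inside a gene slot but outside body, promoter and enhancers


@dataclass
class FixtureSpec:
    """Declares the toy dataset; defaults are the generator's study conditions."""

    n_chrom: int = 2
    n_genes: int = 50
    n_tfs: int = 20
    n_enhancers: int = 40
    n_planted_edges: int = 30
    effect_range: Tuple[float, float] = (1.5, 2.5)
    noise_sd: float = 0.1
    n_cells_per_type: int = 500
    cell_types: Tuple[str, ...] = ("typeA", "typeB")
    n_snps_disrupting: int = 6
    n_snps_neutral: int = 6
    n_decoy_interactions: int = 10
    motif_width: int = 8
    consensus_count: float = 85.0
    offconsensus_count: float = 5.0
    enhancer_length: int = 200
    open_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif_width > self.enhancer_length:
            raise ValueError("motif does not fit in the enhancer")
        if self.n_planted_edges > self.n_enhancers:
            raise ValueError("more planted edges than enhancers")
        if self.n_planted_edges > self.n_genes:
            raise ValueError("generator plants at most one edge per target gene")
        if self.n_snps_disrupting > self.n_planted_edges:
            raise ValueError("more disrupting SNPs than planted sites")

    @property
    def chrom_length(self) -> int:
        total_slots = self.n_tfs + self.n_genes + self.n_enhancers
        per_chrom = -(-total_slots // self.n_chrom)
        return per_chrom * SLOT + 1000


@dataclass
class PlantedEdge:
    tf: str
    gene: str
    enhancer_index: int
    effect: float
    cell_type: str
    site_start: int  # genome coordinate of the embedded consensus
    site_strand: str


@dataclass
class Fixture:
    spec: FixtureSpec
    genome: GenomeSequence
    genes: List[GeneModel]  # TF genes + target genes
    pfms: List[MotifPfm]
    enhancers: List[GenomicInterval]
    interactions: List[ChromatinInteraction]
    open_regions: List[GenomicInterval]
    planted_edges: List[PlantedEdge]
    expression_continuous: ExpressionMatrix
    expression_counts: ExpressionMatrix
    variants: List[Variant]
    manifest: Dict


def _slot_interval(spec: FixtureSpec, slot: int, length: int, at: int) -> Tuple[str, int]:
    per_chrom = -(-(spec.n_tfs + spec.n_genes + spec.n_enhancers) // spec.n_chrom)
    chrom = f"chr{slot // per_chrom + 1}"
    start = (slot % per_chrom) * SLOT + at
    return chrom, start


def _tf_names(spec: FixtureSpec) -> List[str]:
    return [f"TF{i+1:02d}" for i in range(spec.n_tfs)]


def _gene_names(spec: FixtureSpec) -> List[str]:
    return [f"G{i+1:02d}" for i in range(spec.n_genes)]


def generate_fixture(spec: Optional[FixtureSpec] = None) -> Fixture:
    """Build the full dataset in memory. Deterministic in ``spec.seed``."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    tf_names, gene_names = _tf_names(spec), _gene_names(spec)
    all_gene_names = tf_names + gene_names

    # --- gene and enhancer layout -------------------------------------------
    genes: List[GeneModel] = []
    for i, name in enumerate(all_gene_names):
        chrom, start = _slot_interval(spec, i, GENE_LENGTH, GENE_OFFSET)
        strand = "+" if i % 2 == 0 else "-"
        body = GenomicInterval(chrom, start, start + GENE_LENGTH, strand)
        tss = body.start if strand == "+" else body.end - 1
        genes.append(GeneModel(name, name, tss, strand, body))
    gene_by_name = {g.gene_id: g for g in genes}

    enhancers: List[GenomicInterval] = []
    for j in range(spec.n_enhancers):
        chrom, start = _slot_interval(spec, len(all_gene_names) + j, spec.enhancer_length, GENE_OFFSET)
        enhancers.append(GenomicInterval(chrom, start, start + spec.enhancer_length))

    # --- motifs: one sharp consensus per TF ---------------------------------
    consensi: List[str] = []
    while len(consensi) < spec.n_tfs:
        cons = "".join(rng.choice(list(BASES), size=spec.motif_width))
        if cons not in consensi and reverse_complement(cons) not in consensi:
            consensi.append(cons)
    pfms = []
    for name, cons in zip(tf_names, consensi):
        counts = np.full((4, spec.motif_width), spec.offconsensus_count)
        for j, b in enumerate(cons):
            counts[BASES.index(b), j] = spec.consensus_count
        pfms.append(MotifPfm(tf_name=name, counts=counts, matrix_id=f"MX{len(pfms)+1:04d}"))

    # --- planted wiring: one TF per target gene, disjoint across cell types --
    planted_genes = gene_names[: spec.n_planted_edges]
    planted: List[PlantedEdge] = []
    site_at = (spec.enhancer_length - spec.motif_width) // 2
    for k, gname in enumerate(planted_genes):
        tf = tf_names[int(rng.integers(spec.n_tfs))]
        effect = float(rng.uniform(*spec.effect_range)) * (1 if rng.random() < 0.5 else -1)
        cell_type = spec.cell_types[0] if k < spec.n_planted_edges // 2 else spec.cell_types[1]
        enh = enhancers[k]
        strand = "+" if k % 2 == 0 else "-"
        planted.append(PlantedEdge(tf, gname, k, effect, cell_type, enh.start + site_at, strand))

    # --- genome: random background with consensus sites embedded ------------
    chrom_names = sorted({g.body.chrom for g in genes} | {e.chrom for e in enhancers})
    seqs = {
        c: np.array(list("ACGT"))[rng.integers(0, 4, size=spec.chrom_length)]
        for c in chrom_names
    }
    for edge in planted:
        enh = enhancers[edge.enhancer_index]
        cons = consensi[tf_names.index(edge.tf)]
        site = cons if edge.site_strand == "+" else reverse_complement(cons)
        seqs[enh.chrom][edge.site_start : edge.site_start + spec.motif_width] = list(site)
    genome = GenomeSequence({c: "".join(s) for c, s in seqs.items()})

    # --- interactions: planted enhancer <-> target promoter, plus decoys ----
    interactions: List[ChromatinInteraction] = []
    for edge in planted:
        promoter = define_promoter(gene_by_name[edge.gene])
        interactions.append(ChromatinInteraction(enhancers[edge.enhancer_index], promoter))
    noise_genes = [g for g in gene_names if g not in planted_genes]
    decoy_enhancers = enhancers[spec.n_planted_edges :]
    for d in range(spec.n_decoy_interactions):
        if not decoy_enhancers or not noise_genes:
            break
        enh = decoy_enhancers[d % len(decoy_enhancers)]
        promoter = define_promoter(gene_by_name[noise_genes[d % len(noise_genes)]])
        interactions.append(ChromatinInteraction(enh, promoter))

    n_open = int(np.floor(spec.open_fraction * spec.n_planted_edges + 0.5))
    open_regions = [enhancers[e.enhancer_index] for e in planted[:n_open]]

    # --- expression ----------------------------------------------------------
    latent_blocks = []
    cell_ids, cell_labels = [], []
    for ct in spec.cell_types:
        n = spec.n_cells_per_type
        tf_expr = rng.normal(0.0, 1.0, size=(spec.n_tfs, n))
        block = np.empty((len(all_gene_names), n))
        block[: spec.n_tfs] = tf_expr
        for gi, gname in enumerate(gene_names):
            row = spec.n_tfs + gi
            active = [e for e in planted if e.gene == gname and e.cell_type == ct]
            if active:
                signal = sum(e.effect * tf_expr[tf_names.index(e.tf)] for e in active)
                block[row] = signal + rng.normal(0.0, spec.noise_sd, size=n)
            else:
                block[row] = rng.normal(0.0, 1.0, size=n)
        latent_blocks.append(block)
        cell_ids += [f"{ct}_c{i+1:04d}" for i in range(n)]
        cell_labels += [ct] * n
    latent = np.hstack(latent_blocks)
    labels = pd.Series(cell_labels, index=cell_ids)
    # shift each gene row so the continuous matrix is non-negative; an affine
    # per-gene shift leaves the regression (which centers) unchanged
    continuous = latent - latent.min(axis=1, keepdims=True)
    counts = np.rint(np.exp(latent))
    expr_cont = ExpressionMatrix(pd.DataFrame(continuous, index=all_gene_names, columns=cell_ids), labels)
    expr_counts = ExpressionMatrix(pd.DataFrame(counts, index=all_gene_names, columns=cell_ids), labels)

    # --- SNPs ----------------------------------------------------------------
    pwm_by_tf = {p.tf_name: pfm_to_pwm(p) for p in pfms}
    variants: List[Variant] = []
    dis_idx = rng.choice(spec.n_planted_edges, size=spec.n_snps_disrupting, replace=False)
    dis_records = []
    for r, k in enumerate(sorted(int(i) for i in dis_idx)):
        edge = planted[k]
        enh = enhancers[edge.enhancer_index]
        pos0 = edge.site_start + spec.motif_width // 2
        ref = genome.base_at(enh.chrom, pos0)
        elem_seq = genome.fetch(enh)
        # alt allele chosen to maximize the motif-score drop
        pwm = pwm_by_tf[edge.tf]
        alt = min(
            (b for b in BASES if b != ref),
            key=lambda b: score_allele_pair(elem_seq, pos0 - enh.start, ref, b, pwm)[1],
        )
        v = Variant(chrom=enh.chrom, pos=pos0 + 1, ref_allele=ref, alt_allele=alt,
                    id=f"rs_dis{r+1:02d}", pvalue=float((r + 1) * 1e-8))
        variants.append(v)
        dis_records.append({"id": v.id, "tf": edge.tf, "gene": edge.gene,
                            "cell_type": edge.cell_type,
                            "enhancer": {"chrom": enh.chrom, "start": enh.start, "end": enh.end}})
    neutral_slots = rng.choice(len(all_gene_names), size=spec.n_snps_neutral, replace=False)
    for r, slot in enumerate(sorted(int(s) for s in neutral_slots)):
        chrom, pos0 = _slot_interval(spec, slot, 1, NEUTRAL_OFFSET)
        ref = genome.base_at(chrom, pos0)
        alt = next(b for b in BASES if b != ref)
        pv = 1e-6 if r % 2 == 0 else 0.5
        variants.append(Variant(chrom=chrom, pos=pos0 + 1, ref_allele=ref, alt_allele=alt,
                                id=f"rs_neu{r+1:02d}", pvalue=pv))

    manifest = {
        "seed": spec.seed,
        "tf_names": tf_names,
        "gene_names": gene_names,
        "cell_types": list(spec.cell_types),
        "planted_edges": [
            {
                "tf": e.tf, "gene": e.gene, "effect": e.effect, "cell_type": e.cell_type,
                "enhancer": {
                    "chrom": enhancers[e.enhancer_index].chrom,
                    "start": enhancers[e.enhancer_index].start,
                    "end": enhancers[e.enhancer_index].end,
                },
                "site": {"chrom": enhancers[e.enhancer_index].chrom,
                         "start": e.site_start, "strand": e.site_strand},
            }
            for e in planted
        ],
        "disrupting_snps": dis_records,
        "neutral_snp_ids": [v.id for v in variants if v.id.startswith("rs_neu")],
    }
    return Fixture(spec, genome, genes, pfms, enhancers, interactions, open_regions,
                   planted, expr_cont, expr_counts, variants, manifest)


# --- spec-facing thin wrappers ------------------------------------------------

def generate_genome_and_motifs(spec: FixtureSpec):
    fx = generate_fixture(spec)
    return fx.genome, fx.genes, fx.pfms, fx.manifest["planted_edges"]


def generate_interactions_and_chromatin(spec: FixtureSpec):
    fx = generate_fixture(spec)
    return fx.interactions, fx.open_regions


def simulate_expression(spec: FixtureSpec):
    fx = generate_fixture(spec)
    return fx.expression_continuous, fx.expression_counts


def generate_snps(spec: FixtureSpec):
    fx = generate_fixture(spec)
    return fx.variants


# --- file emission ------------------------------------------------------------

def write_fixture(fx: Fixture, outdir: str) -> Dict[str, str]:
    """Write every input file of the pipeline; returns name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}

    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom in fx.genome:
            fh.write(f">{chrom}\n")
            seq = fx.genome.fetch(GenomicInterval(chrom, 0, fx.genome.chrom_length(chrom)))
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["genome"] = str(fasta)

    gtf = out / "genes.gtf"
    with open(gtf, "w") as fh:
        for g in fx.genes:
            fh.write(
                f"{g.body.chrom}\tsim\tgene\t{g.body.start + 1}\t{g.body.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";\n'
            )
    paths["annotation"] = str(gtf)

    jaspar = out / "motifs.jaspar"
    with open(jaspar, "w") as fh:
        for p in fx.pfms:
            fh.write(f">{p.matrix_id} {p.tf_name}\n")
            for bi, b in enumerate(BASES):
                row = " ".join(f"{v:g}" for v in p.counts[bi])
                fh.write(f"{b} [ {row} ]\n")
    paths["motifs"] = str(jaspar)

    bedpe = out / "interactions.bedpe"
    with open(bedpe, "w") as fh:
        for it in fx.interactions:
            a, b = it.anchor_a, it.anchor_b
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")
    paths["interactions"] = str(bedpe)

    bed = out / "open_chromatin.bed"
    with open(bed, "w") as fh:
        for iv in fx.open_regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    paths["open_chromatin"] = str(bed)

    cont = out / "expression_continuous.tsv"
    fx.expression_continuous.values.to_csv(cont, sep="\t")
    paths["expression_continuous"] = str(cont)

    mtx = out / "expression_counts.mtx"
    mmwrite(str(mtx), csr_matrix(fx.expression_counts.values.to_numpy()))
    (out / "genes.txt").write_text("\n".join(fx.expression_counts.gene_ids) + "\n")
    (out / "barcodes.txt").write_text("\n".join(fx.expression_counts.cell_ids) + "\n")
    paths["expression_counts"] = str(mtx)
    paths["expression_genes"] = str(out / "genes.txt")
    paths["expression_barcodes"] = str(out / "barcodes.txt")

    ct = out / "cell_types.tsv"
    fx.expression_counts.cell_types.to_csv(ct, sep="\t", header=False)
    paths["cell_types"] = str(ct)

    var = out / "variants.tsv"
    pd.DataFrame(
        [
            {"chrom": v.chrom, "pos": v.pos, "id": v.id, "ref": v.ref_allele,
             "alt": v.alt_allele, "pvalue": v.pvalue}
            for v in fx.variants
        ]
    ).to_csv(var, sep="\t", index=False)
    paths["variants"] = str(var)

    manifest = out / "manifest.json"
    manifest.write_text(json.dumps(fx.manifest, indent=1))
    paths["manifest"] = str(manifest)
    return paths
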