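# Methods

## Coordinate model

All internal coordinates are 0-based half-open; GTF (1-based inclusive) and
variant positions (1-based) are converted at the parser boundary. Promoter
windows default to 2000 bp upstream / 200 bp downstream of the TSS,
strand-aware (`[tss−u, tss+d)` on +, the mirrored `[tss−d+1, tss+u+1)` on −),
clipped at the chromosome start. The window size is a configurable convention,
not a biological constant; common alternatives (1 kb/1 kb, 5 kb/500 bp) only
change which anchors count as promoters. Duplicate gene ids in an annotation
collapse deterministically to the record with the longest body.

## Anchor annotation

An interaction contributes wires only if at least one anchor overlaps a
promoter window. The non-promoter partner of a promoter anchor becomes an
enhancer candidate for every gene whose promoter the anchor overlaps (fan-out
rather than nearest-TSS assignment: chromatin contacts do not disambiguate
shared promoters). Promoter–promoter pairs produce reciprocal enhancer-role
links — each promoter can act as a distal element for the other gene — plus
the promoter self-links. An optional BED of user-supplied candidate elements
restricts which anchors may serve as enhancers (intersection filter).

## Motif scanning

PWMs are log₂ odds of `(count + pseudocount·background) / (colsum +
pseudocount)` against the background, default pseudocount 0.8 and uniform
background. Scores are summed per window and rescaled to
`rel = (S − S_min)/(S_max − S_min)`; thresholding on `rel` (default 0.80) is
self-normalizing across motif widths, which is why it is used instead of a
p-value calibration (dynamic-programming score distributions are a non-goal).
Windows containing N score −∞ and can never hit. Both strands are scanned;
minus-strand hits are reported in forward coordinates. Hits of one TF on one
element collapse into a single reference edge with a support count, and
matrices sharing a TF name pool into that TF, because the downstream
regression only sees TF identity. The scanner is vectorized; tests hold it
exactly (1e-9) to an independent brute-force per-window scorer.

## Expression preprocessing

Genes detected (nonzero) in fewer than 100 cells are removed, counting across
all cells since the rule is applied before any per-type processing. Cells are
then log-normalized, `ln(1 + 10⁴·x/colsum)` (natural log; the base-10 log
appears only in the per-type rule below). Per cell type, genes with
`log10(S+1) < 1` are removed, where S is the gene's summed expression over the
type's cells — equivalently S < 9. Imputation is out of scope: if a
dropout-corrected matrix is supplied, the same filter applies to it unchanged;
the filters are matrix-agnostic.

## Elastic-net network inference

The per-gene objective is the unnormalized `‖y − Xc‖² + α‖c‖² + β‖c‖₁`.
scikit-learn's `ElasticNet` minimizes `1/(2n)‖y−Xc‖² + a·λ‖c‖₁ +
a(1−λ)/2‖c‖²`, so the conversion is `a = (β+2α)/(2n)`, `λ = β/(β+2α)`
(exact; round-trip tested). At α = β = 0 the solver is plain least squares.

Design choices where the procedure was genuinely open:

- **Standardization.** Predictors and response are standardized to unit
  variance on training statistics; coefficients are reported on that scale.
  A single |c| cutoff (0.01) across thousands of genes is only meaningful if
  coefficients are dimensionless and comparable.
- **Grid.** L1 fraction β/(α+β) ∈ {0.1, 0.5, 0.9} × total penalty α+β
  log-spaced over 10⁻⁴…10¹ (7 values); the winner minimizes *held-out* MSE on
  the 30 % test cells (not cross-validation — model selection and the reported
  MSE use the same split, shared across all genes of a cell type so MSEs are
  comparable between genes).
- **MSE.** Reported as the mean of squared test residuals on the standardized
  scale; the TG filter `MSE > 0.1` and the edge filter `|c| < 0.01` are strict
  inequalities (MSE = 0.1 and |c| = 0.01 survive).
- **Self-regression.** A gene is never its own candidate TF; regressing a TF
  gene on itself is a degenerate perfect fit that would always pass the MSE
  filter.
- **Degenerate inputs.** A constant training response returns all-zero
  coefficients with test MSE = var(y_test); a zero-variance predictor column
  is retained but its standardized values are set to 0, so its coefficient is
  exactly 0.

Network variants: **(I) open_chromatin** keeps edges whose enhancers reach at
least one accessible region (promoter-only edges are kept — accessibility data
rarely covers promoters reliably at subtype level); **(II) top_percent** keeps
the top ⌈0.10·m⌉ TFs per gene by |c| (ties broken lexicographically),
without the accessibility filter.

## Variant disruption scoring

A SNP inside a network element is scored per motif: every window of width w
covering the SNP (at most w per strand), both strands, under each allele; the
per-allele score is the max relative score over those windows. An event
requires the better allele to reach the scan threshold (0.80 — a site must
exist under some allele) and |Δrel| ≥ 0.10. Both losses (Δ < 0) and gains
(Δ > 0) count as interruption by default; a flag restricts to losses. The
computation substitutes only the focal base in a fixed window set, so allele
swap negates Δ exactly (tested on random pairs). By default a call is
TF-specific — the disrupted motif's TF must regulate the gene through that
element in the GRN — because a SNP breaking an irrelevant TF's site says
nothing about the wire; `tf_specific=False` restores the permissive
any-TF-on-the-element behaviour. Only single-nucleotide substitutions are
supported.

## Phenotype classification

The classifier is standard logistic regression (sigmoid link, L2 penalty
C = 1.0 for stability on d > n folds) with inverse-class-frequency weights,
features standardized per fold. Accuracy is balanced accuracy (mean of
per-class recalls), so the chance level is 50 % regardless of class imbalance;
a resampling-based balancing mode is available by flag. Binarizations: Braak
{0–3} vs {4–6}; DCFDX/COGDX {1–3} vs {4, 5}; CERAD requires an explicit
score-to-class mapping because site codings differ; a generic threshold scheme
covers continuous scales.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, with
known ground truth:

- a toy genome of 7 kb slots (gene bodies with strand-aware promoters,
  200 bp enhancers, all non-overlapping by construction);
- 20 sharp 8-mer motifs (85/5 column counts), each planted TF site embedded
  verbatim in the enhancer of its wire, alternating strands;
- planted enhancer ↔ promoter interactions plus decoy interactions to noise
  genes;
- linear-Gaussian expression: TF cells i.i.d. N(0,1); each planted target is
  effect·TF + N(0, 0.1) with |effect| ∈ [1.5, 2.5]; all other genes N(0,1).
  Two cell types with disjoint planted wiring exercise per-type specificity.
  Default sizes: 50 target genes, 30 planted wires, 500 cells per type — one
  planted TF per target, so top-10 % selection can retain it even for genes
  with few candidate TFs;
- a count-like matrix (`rint(exp(z))`) feeds the preprocessing path; the
  continuous latent matrix (shifted per gene to be non-negative, which the
  centering regression cannot see) is emitted for direct regression use and is
  what `run-all` regresses on;
- disrupting SNPs at planted-site centers with the alt allele chosen to
  maximize the motif-score drop (for uniform 85/5 columns the drop is exactly
  1/w ≈ 0.125 of the score range, above the 0.10 event threshold); neutral
  SNPs in element-free background.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: scRNA-seq count noise (dropout, overdispersion, library
size variation), Hi-C contact-distance decay and resolution limits, motif
redundancy between TF families, LD structure among GWAS SNPs, trans effects
and combinatorial/nonlinear regulation. Recovery rates on this fixture are an
upper bound, a correctness check of the machinery rather than a benchmark.

## Problem sizes and determinism

Default analysis sizes (the fixture above, 25-seed baselines, 100×10 scan
comparisons, 200 allele-swap pairs) keep any full run in well under a minute
on one core while leaving no estimator in a small-sample regime. Every
stochastic step — cell splits, CV folds, the generator — takes an explicit
seed; reruns are byte-identical, and element scanning is sorted so output is
independent of the worker count.
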