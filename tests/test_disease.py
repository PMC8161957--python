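import numpy as np
import pytest

from conftest import random_pfm, random_sequence
from grnmap.disease import (
    DisruptionEvent,
    call_disease_genes,
    filter_variants,
    overlap_variants_elements,
    read_variants_tsv,
    read_variants_vcf,
    score_allele_pair,
    score_disruption,
)
from grnmap.genome import GenomeSequence
from grnmap.grn import GrnEdge
from grnmap.intervals import GenomicInterval, Variant
from grnmap.motifs import MotifPfm, pfm_to_pwm


def variant(pos, ref="A", alt="C", id="rs1", pvalue=None, chrom="chr1"):
    return Variant(chrom, pos, ref, alt, id=id, pvalue=pvalue)


class TestFilterVariants:
    def test_pvalue_threshold_is_strict(self):
        kept = filter_variants([variant(10, pvalue=4.9e-5)]).variants
        assert len(kept) == 1
        kept = filter_variants([variant(10, pvalue=5e-5)]).variants
        assert kept == []

    def test_credible_set_membership_overrides_pvalue(self):
        vs = filter_variants([variant(10, id="rsC", pvalue=0.2)], credible_ids={"rsC"})
        assert [v.id for v in vs.variants] == ["rsC"]

    def test_variant_without_pvalue_or_credible_membership_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            vs = filter_variants([variant(10, pvalue=None)])
        assert vs.variants == [] and any("excluded" in r.message for r in caplog.records)


def grn_edge(tf, gene, elements):
    return GrnEdge(tf, gene, 0.5, tuple(elements))


class TestOverlapVariantsElements:
    def grn(self):
        e1 = (GenomicInterval("chr1", 100, 200), "enhancer")
        e2 = (GenomicInterval("chr1", 300, 400), "promoter")
        return [grn_edge("TF1", "G1", [e1, e2]), grn_edge("TF2", "G2", [e1])]

    def test_one_based_position_maps_to_half_open_element(self):
        vs = filter_variants([variant(101, pvalue=1e-8)])
        matches = overlap_variants_elements(vs, self.grn())
        assert len(matches) == 1 and matches[0][1].start == 100

    def test_position_past_element_end_does_not_match(self):
        vs = filter_variants([variant(201, pvalue=1e-8)])
        assert overlap_variants_elements(vs, self.grn()) == []

    def test_matches_equal_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        elements = [
            (GenomicInterval("chr1", int(s), int(s) + 50), "enhancer")
            for s in rng.integers(0, 2000, size=8)
        ]
        grn = [grn_edge(f"TF{i}", f"G{i}", [e]) for i, e in enumerate(elements)]
        variants = [variant(int(p), id=f"rs{k}", pvalue=1e-8)
                    for k, p in enumerate(rng.integers(1, 2100, size=40))]
        vs = filter_variants(variants)
        got = {(v.id, iv.key()) for v, iv, _r, _e in overlap_variants_elements(vs, grn)}
        expected = {
            (v.id, iv.key())
            for v in variants
            for iv, _role in elements
            if iv.start <= v.pos - 1 < iv.end
        }
        assert got == expected

    def test_match_carries_all_edges_using_the_element(self):
        vs = filter_variants([variant(150, pvalue=1e-8)])
        (match,) = overlap_variants_elements(vs, self.grn())
        assert {e.gene_id for e in match[3]} == {"G1", "G2"}


def acgt_pwm():
    counts = np.full((4, 4), 0.0)
    for j, b in enumerate("ACGT"):
        counts["ACGT".index(b), j] = 10.0
    return pfm_to_pwm(MotifPfm("ACGTTF", counts), pseudocount=0.8)


class TestScoreDisruption:
    def genome(self, seq="TTTTTACGTTTTTT"):
        return GenomeSequence({"chr1": seq})

    def element(self, length=14):
        return GenomicInterval("chr1", 0, length)

    def test_loss_of_site_yields_negative_delta(self):
        # ACGT at positions 5-8; variant C>G at motif position 1 (genome pos0 6)
        ev = score_disruption(variant(7, ref="C", alt="G"), self.element(), "enhancer",
                              acgt_pwm(), self.genome(), hit_threshold=0.8, delta_min=0.05)
        assert ev is not None
        assert ev.best_ref_score == pytest.approx(1.0)
        assert ev.best_alt_score < 1.0 and ev.delta < 0

    def test_no_site_under_either_allele_returns_none(self):
        genome = GenomeSequence({"chr1": "TTTTTTTTTTTTTT"})
        ev = score_disruption(variant(7, ref="T", alt="G"), self.element(), "enhancer",
                              acgt_pwm(), genome, hit_threshold=0.8, delta_min=0.0)
        assert ev is None

    def test_small_delta_below_threshold_returns_none(self):
        ev = score_disruption(variant(7, ref="C", alt="G"), self.element(), "enhancer",
                              acgt_pwm(), self.genome(), hit_threshold=0.8, delta_min=0.9)
        assert ev is None

    def test_reference_mismatch_is_an_error_naming_the_variant(self):
        with pytest.raises(ValueError, match="rs1"):
            score_disruption(variant(7, ref="G", alt="A"), self.element(), "enhancer",
                             acgt_pwm(), self.genome())

    def test_best_scores_match_naive_window_enumeration(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        rng = np.random.default_rng(9)
        for _ in range(25):
            seq = random_sequence(rng, 60)
            pwm = pfm_to_pwm(random_pfm(rng, width=6), pseudocount=0.8)
            i = int(rng.integers(0, 60))
            ref = seq[i]
            alt = rng.choice([b for b in "ACGT" if b != ref])

            def naive_best(allele):
                s = seq[:i] + allele + seq[i + 1 :]
                w = pwm.width
                best = float("-inf")
                for start in range(max(0, i - w + 1), min(len(s) - w, i) + 1):
                    window = s[start : start + w]
                    for orient in (window, "".join(comp[b] for b in reversed(window))):
                        score = sum(float(pwm.logodds[base_idx[b], j]) for j, b in enumerate(orient))
                        best = max(best, score)
                return pwm.rel_score(best)

            got = score_allele_pair(seq, i, ref, alt, pwm)
            assert got[0] == pytest.approx(naive_best(ref), abs=1e-9)
            assert got[1] == pytest.approx(naive_best(alt), abs=1e-9)

    def test_allele_swap_negates_delta_exactly(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            seq = random_sequence(rng, 40)
            pwm = pfm_to_pwm(random_pfm(rng, width=5), pseudocount=0.8)
            i = int(rng.integers(0, 40))
            a, b = rng.choice(list("ACGT"), size=2, replace=False)
            fwd = score_allele_pair(seq, i, a, b, pwm)
            rev = score_allele_pair(seq, i, b, a, pwm)
            assert (fwd[1] - fwd[0]) == -(rev[1] - rev[0])


class TestCallDiseaseGenes:
    def elements(self):
        return {
            "E1": GenomicInterval("chr1", 100, 200),
            "E2": GenomicInterval("chr1", 300, 400),
        }

    def event(self, tf, element):
        return DisruptionEvent(variant(150, pvalue=1e-8), tf, element, "enhancer", 0.9, 0.5)

    def test_event_on_edge_element_calls_the_gene(self):
        e = self.elements()
        grn = [grn_edge("A", "G", [(e["E1"], "enhancer")])]
        calls = call_disease_genes(grn, [self.event("A", e["E1"])], "typeA")
        assert [c.gene_id for c in calls] == ["G"] and calls[0].cell_type == "typeA"

    def test_tf_mismatch_blocks_the_call(self):
        e = self.elements()
        grn = [grn_edge("B", "G", [(e["E1"], "enhancer")])]
        assert call_disease_genes(grn, [self.event("A", e["E1"])], "t") == []
        # but the permissive mode implicates the gene through the element alone
        calls = call_disease_genes(grn, [self.event("A", e["E1"])], "t", tf_specific=False)
        assert [c.gene_id for c in calls] == ["G"]

    def test_events_on_two_elements_group_into_one_call(self):
        e = self.elements()
        grn = [
            grn_edge("A", "G", [(e["E1"], "enhancer")]),
            grn_edge("A", "G", [(e["E2"], "enhancer")]),
        ]
        calls = call_disease_genes(grn, [self.event("A", e["E1"]), self.event("A", e["E2"])], "t")
        assert len(calls) == 1 and len(calls[0].elements) == 2

    def test_calls_are_subset_of_grn_target_genes(self, small_fixture):
        # shuffled: events against elements absent from the GRN produce nothing
        e = self.elements()
        grn = [grn_edge("A", "G", [(e["E1"], "enhancer")])]
        off_element = GenomicInterval("chr1", 5000, 5100)
        assert call_disease_genes(grn, [self.event("A", off_element)], "t") == []


class TestVariantReaders:
    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("chrom\tpos\tid\tref\talt\tpvalue\nchr1\t101\trs1\tA\tC\t1e-06\n")
        (v,) = read_variants_tsv(str(p))
        assert (v.chrom, v.pos, v.ref_allele, v.alt_allele, v.pvalue) == ("chr1", 101, "A", "C", 1e-6)

    def test_vcf_snvs_only(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=PVAL,Number=1,Type=Float,Description="p">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t101\trs1\tA\tC\t.\t.\tPVAL=1e-06\n"
            "chr1\t202\trs2\tAT\tA\t.\t.\tPVAL=1e-06\n"
        )
        variants = read_variants_vcf(str(p))
        assert [v.id for v in variants] == ["rs1"]
        assert variants[0].pvalue == pytest.approx(1e-6)
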