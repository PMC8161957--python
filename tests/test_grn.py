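import numpy as np
import pytest

from grnmap.grn import (
    ElasticNetConfig,
    ElasticNetGridRegressor,
    GrnEdge,
    TargetGeneFit,
    assemble_grn,
    candidate_tfs,
    default_grid,
    fit_target_gene,
    paper_to_sklearn,
    select_top_tfs,
    sklearn_to_paper,
    split_cells,
)
from grnmap.intervals import GenomicInterval
from grnmap.motifs import ReferenceEdge


def ref_edge(tf, gene, start=0, end=100, role="enhancer"):
    return ReferenceEdge(tf, GenomicInterval("chr1", start, end), role, gene, 1)


class TestPenaltyConversion:
    @pytest.mark.parametrize("alpha,beta,n", [(0.5, 0.2, 100), (0.0, 1.0, 50), (2.0, 0.0, 7), (1e-4, 1e-3, 350)])
    def test_round_trip_is_exact(self, alpha, beta, n):
        a, l1 = paper_to_sklearn(alpha, beta, n)
        back = sklearn_to_paper(a, l1, n)
        assert back == pytest.approx((alpha, beta), rel=1e-12)

    def test_solver_minimizes_the_stated_objective(self):
        # the converted solver solution must beat nearby perturbations on the
        # unnormalized objective it claims to minimize
        rng = np.random.default_rng(0)
        n, m = 200, 5
        X = rng.normal(size=(n, m))
        y = X @ rng.normal(size=m) + rng.normal(scale=0.5, size=n)
        alpha, beta = 3.0, 2.0
        est = ElasticNetGridRegressor(grid=[(alpha, beta)], split=(np.arange(n), np.arange(n)))
        est.fit(X, y)
        Z = (X - est.x_mean_) / est.x_sd_
        u = (y - est.y_mean_) / est.y_sd_
        base = est.training_objective(est.coef_, Z, u, alpha, beta)
        rng2 = np.random.default_rng(1)
        for _ in range(20):
            perturbed = est.coef_ + rng2.normal(scale=0.01, size=m)
            assert est.training_objective(perturbed, Z, u, alpha, beta) >= base - 1e-8


class TestSplitCells:
    def test_seventy_thirty_split(self):
        train, test = split_cells(10, 0.7, seed=0)
        assert len(train) == 7 and len(test) == 3
        assert sorted(np.concatenate([train, test])) == list(range(10))

    def test_deterministic_for_fixed_seed(self):
        assert (split_cells(100, 0.7, 5)[0] == split_cells(100, 0.7, 5)[0]).all()

    def test_different_seeds_give_different_splits(self):
        collisions = sum(
            (split_cells(100, 0.7, s)[0] == split_cells(100, 0.7, s + 1000)[0]).all()
            for s in range(100)
        )
        assert collisions == 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            split_cells(3, 0.7, 0)
        with pytest.raises(ValueError):
            split_cells(10, 0.001, 0)


class TestFitTargetGene:
    def test_unpenalized_limit_equals_ordinary_least_squares(self):
        rng = np.random.default_rng(2)
        n, m = 100, 4
        X = rng.normal(size=(n, m))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(scale=0.2, size=n)
        split = (np.arange(n), np.arange(n))
        est = ElasticNetGridRegressor(grid=[(0.0, 0.0)], split=split)
        est.fit(X, y)
        Z = (X - est.x_mean_) / est.x_sd_
        u = (y - est.y_mean_) / est.y_sd_
        ols = np.linalg.lstsq(Z, u, rcond=None)[0]
        assert np.allclose(est.coef_, ols, atol=1e-6)

    def test_huge_l1_penalty_shrinks_everything_to_zero(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 5))
        y = X[:, 0] + rng.normal(scale=0.1, size=100)
        est = ElasticNetGridRegressor(grid=[(0.0, 1e6)], seed=0)
        est.fit(X, y)
        assert np.allclose(est.coef_, 0.0)

    def test_planted_two_tf_effects_are_recovered(self):
        rng = np.random.default_rng(4)
        n, m = 500, 20
        X = rng.normal(size=(n, m))
        y = 2.0 * X[:, 0] - 1.5 * X[:, 1] + rng.normal(scale=0.1, size=n)
        fit = fit_target_gene(y, X, [f"TF{i:02d}" for i in range(m)], ElasticNetConfig(seed=0), "G")
        named = dict(zip(fit.tf_names, np.abs(fit.coefficients)))
        assert named["TF00"] > 0.5 and named["TF01"] > 0.3
        assert all(v < 0.05 for tf, v in named.items() if tf not in ("TF00", "TF01"))

    def test_constant_training_response_returns_zero_fit(self):
        X = np.random.default_rng(5).normal(size=(50, 3))
        y = np.full(50, 3.7)
        est = ElasticNetGridRegressor(seed=0)
        est.fit(X, y)
        assert np.allclose(est.coef_, 0.0) and est.test_mse_ == pytest.approx(0.0)

    def test_zero_variance_predictor_gets_zero_coefficient(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 3))
        X[:, 2] = 4.2
        y = X[:, 0] + rng.normal(scale=0.1, size=200)
        est = ElasticNetGridRegressor(grid=[(0.1, 0.1)], seed=0)
        est.fit(X, y)
        assert est.coef_[2] == 0.0

    def test_training_objective_no_worse_than_zero_vector(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            X = rng.normal(size=(80, 6))
            y = rng.normal(size=80)
            alpha, beta = rng.uniform(0, 2, size=2)
            est = ElasticNetGridRegressor(grid=[(alpha, beta)], split=(np.arange(80), np.arange(80)))
            est.fit(X, y)
            Z = (X - est.x_mean_) / np.where(est.x_sd_ > 0, est.x_sd_, 1)
            u = (y - est.y_mean_) / est.y_sd_
            at_fit = est.training_objective(est.coef_, Z, u, alpha, beta)
            at_zero = est.training_objective(np.zeros(6), Z, u, alpha, beta)
            assert at_fit <= at_zero + 1e-9


class TestCandidateTfs:
    def test_dedup_sort_and_expression_intersection(self):
        ref = [ref_edge("TF2", "G"), ref_edge("TF1", "G"), ref_edge("TF1", "G", 200, 300)]
        assert candidate_tfs(ref, "G", {"TF1", "TF2", "TF3"}) == ["TF1", "TF2"]
        assert candidate_tfs(ref, "G", {"TF3"}) == []
        assert candidate_tfs(ref, "absent", {"TF1"}) == []

    def test_target_gene_never_regresses_on_itself(self):
        ref = [ref_edge("TF1", "TF1"), ref_edge("TF2", "TF1")]
        assert candidate_tfs(ref, "TF1", {"TF1", "TF2"}) == ["TF2"]


def make_fit(gene, tfs, coefs, mse):
    return TargetGeneFit(gene, tfs, np.asarray(coefs, dtype=float), 0.1, 0.1, mse)


class TestSelectTopTfs:
    def test_percentage_mode_takes_ceiling(self):
        fit = make_fit("G", [f"T{i:02d}" for i in range(20)], np.linspace(1, 0.01, 20), 0.0)
        assert len(select_top_tfs(fit, cutoff_percentage=0.10)) == 2

    def test_absolute_mode_boundary_is_inclusive(self):
        fit = make_fit("G", ["A", "B"], [0.02, 0.009], 0.0)
        assert select_top_tfs(fit, cutoff_absolute=0.01) == ["A"]
        fit = make_fit("G", ["A", "B"], [0.02, 0.01], 0.0)
        assert select_top_tfs(fit, cutoff_absolute=0.01) == ["A", "B"]

    def test_equal_coefficients_break_ties_lexicographically(self):
        fit = make_fit("G", ["ZZ", "AA", "MM", "BB"], [0.5, 0.5, 0.5, 0.5], 0.0)
        assert select_top_tfs(fit, cutoff_percentage=0.5) == ["AA", "BB"]

    def test_exactly_one_cutoff_required(self):
        fit = make_fit("G", ["A"], [0.5], 0.0)
        with pytest.raises(ValueError):
            select_top_tfs(fit)
        with pytest.raises(ValueError):
            select_top_tfs(fit, cutoff_absolute=0.1, cutoff_percentage=0.1)


class TestAssembleGrn:
    def reference(self):
        return [
            ref_edge("TF1", "G1", 0, 100, "enhancer"),
            ref_edge("TF1", "G1", 500, 600, "promoter"),
            ref_edge("TF2", "G1", 500, 600, "promoter"),
            ref_edge("TF1", "G2", 900, 1000, "enhancer"),
        ]

    def test_mse_threshold_is_strictly_greater_than(self):
        ref = self.reference()
        dropped = make_fit("G1", ["TF1"], [0.8], 0.15)
        kept = make_fit("G1", ["TF1"], [0.8], 0.1)
        assert assemble_grn([dropped], ref) == []
        assert len(assemble_grn([kept], ref)) == 1

    def test_coefficient_threshold_is_strictly_less_than(self):
        ref = self.reference()
        fit = make_fit("G1", ["TF1", "TF2"], [0.009, 0.01], 0.0)
        edges = assemble_grn([fit], ref, cutoff_percentage=1.0)
        assert [(e.tf_name, e.gene_id) for e in edges] == [("TF2", "G1")]

    def test_open_chromatin_variant_versus_top_percent(self):
        ref = self.reference()
        fit_g2 = make_fit("G2", ["TF1"], [0.9], 0.0)
        open_regions = [GenomicInterval("chr1", 5000, 5100)]  # misses G2's enhancer
        assert assemble_grn([fit_g2], ref, variant="open_chromatin", open_regions=open_regions) == []
        kept = assemble_grn([fit_g2], ref, variant="top_percent")
        assert [(e.tf_name, e.gene_id) for e in kept] == [("TF1", "G2")]

    def test_promoter_only_edges_survive_open_chromatin_filter(self):
        ref = self.reference()
        fit = make_fit("G1", ["TF2"], [0.9], 0.0)
        edges = assemble_grn([fit], ref, variant="open_chromatin", open_regions=[])
        assert [(e.tf_name, e.gene_id) for e in edges] == [("TF2", "G1")]

    def test_edges_are_subset_of_reference_pairs(self):
        ref = self.reference()
        fit = make_fit("G1", ["TF1", "TF9"], [0.9, 0.8], 0.0)  # TF9 has no reference wire
        edges = assemble_grn([fit], ref, cutoff_percentage=1.0)
        pairs = {(e.tf_name, e.gene_id) for e in edges}
        assert pairs <= {(r.tf_name, r.gene_id) for r in ref}

    def test_top_percent_caps_edges_per_gene(self):
        tfs = [f"T{i:02d}" for i in range(20)]
        fit = make_fit("G1", tfs, np.linspace(1.0, 0.5, 20), 0.0)
        ref = [ref_edge(tf, "G1") for tf in tfs]
        edges = assemble_grn([fit], ref, variant="top_percent", cutoff_percentage=0.10)
        assert len(edges) <= int(np.ceil(0.10 * 20))

    def test_open_chromatin_requires_regions(self):
        with pytest.raises(ValueError):
            assemble_grn([], self.reference(), variant="open_chromatin")
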