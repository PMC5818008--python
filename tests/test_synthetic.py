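"""Synthetic generator: determinism, propagation oracle, noise structure."""

import numpy as np
import pytest
from scipy import stats

from rootgrn import (GenotypeSpec, GroundTruthNetwork, InvalidArgument,
                     TrueEdge, default_genotypes, make_binding_set,
                     make_ground_truth_network, simulate_genotype_expression,
                     simulate_time_course, time_course_from_expression)
from rootgrn.synthetic import BASELINE, KO_RESIDUAL, _propagate_means


class TestGroundTruthNetwork:
    def test_paper_like_layout_has_39_nodes(self, paper_like_net):
        assert len(paper_like_net.nodes) == 39
        assert set(paper_like_net.regulators) == {"GTL1", "DF1", "RSL4"}

    def test_seeded_determinism(self):
        a = make_ground_truth_network(12, seed=3)
        b = make_ground_truth_network(12, seed=3)
        assert a.edges == b.edges
        c = make_ground_truth_network(12, seed=4)
        assert a.edges != c.edges

    def test_no_targets_gives_only_regulator_edges(self):
        net = make_ground_truth_network(0, include_feedback=True, seed=0)
        assert all(e.target in net.regulators for e in net.edges)
        pairs = net.edge_pairs()
        assert ("RSL4", "GTL1") in pairs and ("GTL1", "RSL4") in pairs

    def test_sign_matches_effect_and_role(self, paper_like_net):
        for e in paper_like_net.edges:
            assert e.sign == (1 if e.effect_size > 0 else -1)
            if e.target not in paper_like_net.regulators:
                expected = -1 if e.regulator in ("GTL1", "DF1") else 1
                assert e.sign == expected
            assert 0.5 <= abs(e.effect_size) <= 2.0

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgument):
            make_ground_truth_network(-1)
        with pytest.raises(InvalidArgument):
            make_ground_truth_network(5, regulators=[])
        with pytest.raises(InvalidArgument):
            make_ground_truth_network(5, regulators=["A", "A", "B"])

    def test_no_self_edges_unless_requested(self):
        net = make_ground_truth_network(6, seed=1)
        assert all(e.regulator != e.target for e in net.edges)
        auto = make_ground_truth_network(6, seed=1, autoregulation=True)
        assert any(e.regulator == e.target == "GTL1" for e in auto.edges)


class TestGenotypeExpression:
    def test_propagation_oracle_one_edge(self, one_edge_net):
        # hand oracle: target mean = 100 * rel(A)^1
        ko = _propagate_means(one_edge_net, GenotypeSpec("ko", {"A": 0.0}))
        assert ko[0] == 0.0                       # A's own row
        assert ko[1] == BASELINE * KO_RESIDUAL    # 100 * 0.1^1 = 10
        oe = _propagate_means(one_edge_net, GenotypeSpec("oe", {"A": 4.0}))
        assert oe[1] == pytest.approx(400.0)
        rep_net = GroundTruthNetwork(["A"], ["T01"],
                                     [TrueEdge("A", "T01", -1.0)])
        ko = _propagate_means(rep_net, GenotypeSpec("ko", {"A": 0.0}))
        assert ko[1] == pytest.approx(BASELINE / KO_RESIDUAL)  # de-repression

    def test_double_knockout_of_repressors_derepresses_targets(
            self, paper_like_net):
        expr = simulate_genotype_expression(paper_like_net, noise_cv=0.0,
                                            seed=0)
        cols = expr.sample_meta.index[
            expr.sample_meta["genotype"] == "gtl1_df1"]
        repressed = [e.target for e in paper_like_net.edges
                     if e.regulator in ("GTL1", "DF1")
                     and e.target not in ("GTL1", "DF1")]
        vals = expr.values.loc[sorted(set(repressed)), cols[0]]
        assert (vals > BASELINE).all()

    def test_zero_noise_replicates_identical(self, small_net):
        expr = simulate_genotype_expression(small_net, n_reps=3,
                                            noise_cv=0.0, seed=2)
        v = expr.values
        assert (v["wt_r1"] == v["wt_r2"]).all()
        assert (v["wt_r1"] == v["wt_r3"]).all()

    def test_overexpression_row_scales_15_fold(self, paper_like_net):
        expr = simulate_genotype_expression(paper_like_net, noise_cv=0.0,
                                            seed=0)
        col = expr.sample_meta.index[
            expr.sample_meta["genotype"] == "GTL1ox"][0]
        assert expr.values.loc["GTL1", col] == pytest.approx(15 * BASELINE)

    def test_knockout_row_is_zero_and_others_positive(self, paper_like_net):
        expr = simulate_genotype_expression(paper_like_net, seed=3)
        col = expr.sample_meta.index[
            expr.sample_meta["genotype"] == "gtl1"][0]
        assert expr.values.loc["GTL1", col] == 0.0
        others = expr.values.loc[expr.values.index != "GTL1", col]
        assert (others > 0).all()

    def test_replicate_noise_cv_scale(self, small_net):
        expr = simulate_genotype_expression(small_net, n_reps=200,
                                            noise_cv=0.2, seed=9)
        wt = expr.sample_meta.index[expr.sample_meta["genotype"] == "wt"]
        # an unregulated regulator row is pure log-normal noise around 100
        row = expr.values.loc["DF1", wt]
        assert row.std() / row.mean() == pytest.approx(0.2, rel=0.25)

    def test_unknown_perturbed_gene_rejected(self, small_net):
        with pytest.raises(InvalidArgument):
            simulate_genotype_expression(
                small_net, [GenotypeSpec("bad", {"NOPE": 0.0})], seed=0)

    def test_determinism(self, small_net):
        a = simulate_genotype_expression(small_net, seed=7)
        b = simulate_genotype_expression(small_net, seed=7)
        np.testing.assert_array_equal(a.values.to_numpy(),
                                      b.values.to_numpy())

    def test_default_design_shape(self, paper_like_net):
        expr = simulate_genotype_expression(paper_like_net, seed=0)
        assert expr.values.shape == (39, 18)  # 6 genotypes x 3 replicates
        assert sorted(set(expr.sample_meta["genotype"])) == sorted(
            g.name for g in default_genotypes())


class TestTimeCourse:
    def test_five_timepoints_four_transitions(self, small_net):
        tc = time_course_from_expression(
            simulate_time_course(small_net, timepoints=5, seed=1))
        assert len(tc.timepoints) == 5
        assert len(tc.timepoints) - 1 == 4

    def test_single_positive_edge_recovered(self, one_edge_net):
        from rootgrn import assign_signs, WeightedEdge
        tc = time_course_from_expression(
            simulate_time_course(one_edge_net, timepoints=5, zones=1, seed=4))
        [signed] = assign_signs([WeightedEdge("A", "T01", 1.0)], tc)
        assert signed.sign == 1
        assert signed.votes_neg == 0

    def test_zone1_identical_whether_one_or_two_zones(self, small_net):
        a = simulate_time_course(small_net, timepoints=9, zones=1, seed=6)
        b = simulate_time_course(small_net, timepoints=9, zones=2, seed=6)
        z1_cols = [c for c in b.sample_ids if c.startswith("z1_")]
        np.testing.assert_array_equal(a.values.to_numpy(),
                                      b.values[z1_cols].to_numpy())

    def test_too_few_timepoints_rejected(self, small_net):
        with pytest.raises(InvalidArgument):
            simulate_time_course(small_net, timepoints=2)

    def test_insufficient_regulator_coverage_rejected(self, small_net):
        # 3 regulators cannot all be exercised in one 5-point zone
        with pytest.raises(InvalidArgument, match="increase timepoints"):
            simulate_time_course(small_net, timepoints=5, zones=1)


class TestBindingSet:
    def test_perfect_binding_equals_truth(self, small_net):
        b = make_binding_set(small_net, tpr=1.0, fpr=0.0, seed=0)
        assert b.pairs == frozenset(small_net.edge_pairs())

    def test_zero_rates_give_empty_set(self, small_net):
        assert len(make_binding_set(small_net, tpr=0.0, fpr=0.0, seed=0)) == 0

    def test_size_within_binomial_bounds(self):
        net = make_ground_truth_network(36, edge_density=0.55,
                                        include_feedback=False, seed=21)
        tpr, fpr = 0.7, 0.1
        n_true = len(net.edges)
        n_cand = 3 * 38  # ordered TF -> other-gene pairs
        n_false = n_cand - n_true
        b = make_binding_set(net, tpr=tpr, fpr=fpr, seed=21)
        lo = (stats.binom.ppf(0.005, n_true, tpr)
              + stats.binom.ppf(0.005, n_false, fpr))
        hi = (stats.binom.ppf(0.995, n_true, tpr)
              + stats.binom.ppf(0.995, n_false, fpr))
        assert lo <= len(b) <= hi

    def test_rate_range_checks(self, small_net):
        with pytest.raises(InvalidArgument):
            make_binding_set(small_net, tpr=1.5)
        with pytest.raises(InvalidArgument):
            make_binding_set(small_net, fpr=-0.1)
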