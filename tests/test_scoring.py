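import math

import numpy as np
import pytest
from scipy import stats

from fflscan.catalog import FFL
from fflscan.expression import CorrResult
from fflscan.scoring import (
    FFLScorer,
    diff_node,
    dysregulated_ffls,
    edge_statistic,
    empirical_pvalue,
    enrichment_test,
    fisher_z,
    score_ffl,
    two_sided_to_z,
)
from fflscan.simulate import SimulationConfig, simulate
from fflscan.catalog import enumerate_ffls, restrict_to_profiled

from conftest import build_study


class TestDiffNode:
    def test_known_values(self):
        assert diff_node(0.01, 2.0) == pytest.approx(4.0)
        assert diff_node(1.0, 5.0) == 0.0
        assert diff_node(0.001, 0.0) == 0.0

    def test_zero_p_floored(self):
        assert diff_node(0.0, 1.0) == pytest.approx(300.0)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            diff_node(1.5, 1.0)
        with pytest.raises(ValueError):
            diff_node(-0.1, 1.0)


class TestTwoSidedToZ:
    def test_boundaries_clamped(self):
        assert two_sided_to_z(0.0) == -8.0
        assert two_sided_to_z(50.0) == 8.0

    def test_quantile_identity(self):
        # Phi(1.6449) ~ 0.95, so the transform lands at Phi^-1(0.90)
        assert two_sided_to_z(1.6449) == pytest.approx(1.2816, abs=2e-4)

    def test_matches_direct_normal_composition(self, rng):
        d = rng.uniform(0.01, 4.0, size=25)
        expected = stats.norm.ppf(2 * stats.norm.cdf(d) - 1)
        np.testing.assert_allclose(two_sided_to_z(d), expected, atol=1e-10)

    def test_strictly_increasing_before_clamp(self):
        grid = np.linspace(0.01, 5, 200)
        vals = two_sided_to_z(grid)
        assert np.all(np.diff(vals) > 0)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            two_sided_to_z(-1.0)


class TestFisherZ:
    def test_known_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * math.log(3), abs=1e-12)

    def test_odd_symmetry(self, rng):
        r = rng.uniform(-0.99, 0.99, size=25)
        np.testing.assert_allclose(fisher_z(-r), -fisher_z(r), atol=1e-12)

    def test_boundary_clamped_finite(self):
        assert math.isfinite(fisher_z(1.0))
        assert math.isfinite(fisher_z(-1.0))


class TestEdgeStatistic:
    def test_identical_groups_zero(self):
        c = CorrResult(r=0.4, p=0.02, n=30)
        assert edge_statistic(c, c) == pytest.approx(0.0)

    def test_antisymmetric_under_swap(self, rng):
        for _ in range(10):
            a = CorrResult(r=rng.uniform(-0.9, 0.9), p=rng.uniform(1e-6, 1), n=30)
            b = CorrResult(r=rng.uniform(-0.9, 0.9), p=rng.uniform(1e-6, 1), n=15)
            assert edge_statistic(a, b) == pytest.approx(-edge_statistic(b, a), abs=1e-12)

    def test_hand_computed_value(self):
        case = CorrResult(r=0.8, p=1e-5, n=106)
        ctrl = CorrResult(r=0.0, p=1.0, n=20)
        expected = (math.atanh(0.8) * 5) / math.sqrt(1.06 / 103 + 1.06 / 17)
        x = edge_statistic(case, ctrl)
        assert x == pytest.approx(expected, abs=1e-10)
        assert x == pytest.approx(20.38, abs=0.01)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            edge_statistic(CorrResult(0, 1, 3), CorrResult(0, 1, 30))


def _mffl():
    return FFL(mirna="m", tf="t", gene="g", ffl_type="miRNA-FFL")


class TestScoreFFL:
    def _edges(self, ffl, val_map=None, default=0.0):
        return {e: (val_map or {}).get(e[2], default) for e in ffl.edges}

    def test_equal_scores(self):
        ffl = _mffl()
        s = score_ffl(ffl, {"m": 2, "t": 2, "g": 2}, self._edges(ffl, default=4.0))
        assert s == pytest.approx(3.0)

    def test_alpha_one_is_node_mean(self):
        ffl = _mffl()
        s = score_ffl(ffl, {"m": 1, "t": 2, "g": 6}, self._edges(ffl, default=99.0), alpha=1.0)
        assert s == pytest.approx(3.0)

    def test_direct_arithmetic(self):
        ffl = _mffl()
        edges = self._edges(ffl, {"mirna_tf": 0.0, "mirna_gene": 0.0, "tf_gene": 6.0})
        s = score_ffl(ffl, {"m": 1, "t": 2, "g": 3}, edges, alpha=0.5)
        assert s == pytest.approx(2.0)

    def test_composite_uses_four_edges(self):
        ffl = FFL(mirna="m", tf="t", gene="g", ffl_type="composite-FFL")
        edges = {e: 4.0 for e in ffl.edges}
        assert len(edges) == 4
        assert score_ffl(ffl, {"m": 0, "t": 0, "g": 0}, edges) == pytest.approx(2.0)

    def test_missing_score_named(self):
        ffl = _mffl()
        with pytest.raises(KeyError, match="'t'"):
            score_ffl(ffl, {"m": 1, "g": 1}, self._edges(ffl))
        with pytest.raises(KeyError, match="missing edge score"):
            score_ffl(ffl, {"m": 1, "t": 1, "g": 1}, {})

    def test_monotone_in_node_diff(self):
        # raising one node's diff never lowers the combined score
        ffl = _mffl()
        edges = self._edges(ffl, default=1.0)
        diffs = np.linspace(0, 10, 50)
        scores = [
            score_ffl(ffl, {"m": two_sided_to_z(d), "t": 0.5, "g": 0.5}, edges)
            for d in diffs
        ]
        assert np.all(np.diff(scores) >= 0)


def _planted_setup(seed=1, **kw):
    cfg = SimulationConfig(seed=seed, **kw)
    study, cat, truth = simulate(cfg)
    ffls = enumerate_ffls(restrict_to_profiled(cat, study))
    return study, ffls, truth


class TestScorerConsistency:
    def test_record_matches_manual_combination(self, small_study):
        scorer = FFLScorer(small_study)
        ffl = FFL(mirna="miR-0", tf="TF-0".replace("-", ""), gene="G0", ffl_type="composite-FFL")
        rec = scorer.record(ffl)
        manual = score_ffl(
            ffl,
            {n.feature: n.score for n in rec.node_scores},
            {e.edge: e.score for e in rec.edge_scores},
            alpha=0.5,
        )
        assert rec.score == pytest.approx(manual, abs=1e-12)

    def test_matrix_edge_scores_match_scalar_path(self):
        study, ffls, _ = _planted_setup(n_case=20, n_control=20, n_candidate_ffls=20)
        scorer = FFLScorer(study)
        pools = scorer._universe(ffls, "candidate")
        nodes, mats = scorer._permutation_tables(pools)
        rng = np.random.default_rng(3)
        for _ in range(20):
            i = rng.integers(len(pools["miRNA"]))
            j = rng.integers(len(pools["TF"]))
            scalar = scorer.edge_score((pools["miRNA"][i], pools["TF"][j], "mirna_tf")).score
            assert mats["mt"][i, j] == pytest.approx(scalar, abs=1e-10)
        for cls in pools:
            for k, f in enumerate(pools[cls]):
                assert nodes[cls][k] == pytest.approx(scorer.node_score(f).score)

    def test_empirical_pvalue_boundaries_and_granularity(self, small_study):
        scorer = FFLScorer(small_study)
        ffl = FFL(mirna="miR-0", tf="TF0", gene="G0", ffl_type="miRNA-FFL")
        assert scorer.empirical_pvalue(ffl, 200, seed=5, real_score=1e9) == 0.0
        assert scorer.empirical_pvalue(ffl, 200, seed=5, real_score=-1e9) == 1.0
        p = scorer.empirical_pvalue(ffl, 200, seed=5)
        assert 0.0 <= p <= 1.0
        assert (p * 200) == pytest.approx(round(p * 200))

    def test_one_shot_wrapper_deterministic(self, small_study):
        ffl = FFL(mirna="miR-1", tf="TF1", gene="G1", ffl_type="miRNA-FFL")
        score = FFLScorer(small_study).score(ffl)
        p1 = empirical_pvalue(score, small_study, ffl, n_random=100, seed=9)
        p2 = empirical_pvalue(score, small_study, ffl, n_random=100, seed=9)
        assert p1 == p2

    def test_alpha_extremes_rank_by_single_component(self):
        study, ffls, _ = _planted_setup(n_case=20, n_control=20, n_candidate_ffls=30)
        sub = ffls[:10]
        node_only = FFLScorer(study, alpha=1.0)
        edge_only = FFLScorer(study, alpha=0.0)
        for ffl in sub:
            rec_n = node_only.record(ffl)
            rec_e = edge_only.record(ffl)
            nm = sum(n.score for n in rec_n.node_scores) / 3
            em = sum(e.score for e in rec_e.edge_scores) / len(rec_e.edge_scores)
            assert rec_n.score == pytest.approx(nm, abs=1e-12)
            assert rec_e.score == pytest.approx(em, abs=1e-12)

    def test_score_invariant_under_component_order(self, small_study):
        scorer = FFLScorer(small_study)
        ffl = FFL(mirna="miR-2", tf="TF2", gene="G2", ffl_type="composite-FFL")
        rec = scorer.record(ffl)
        nodes = {n.feature: n.score for n in rec.node_scores}
        edges = {e.edge: e.score for e in rec.edge_scores}
        shuffled_nodes = dict(reversed(list(nodes.items())))
        shuffled_edges = dict(reversed(list(edges.items())))
        assert score_ffl(ffl, shuffled_nodes, shuffled_edges) == pytest.approx(rec.score)


class TestDysregulatedSelection:
    def _rec(self, p, score, key):
        ffl = FFL(mirna=f"m{key}", tf=f"t{key}", gene=f"g{key}", ffl_type="miRNA-FFL")
        from fflscan.scoring import FFLScoreRecord

        return FFLScoreRecord(
            ffl=ffl, node_scores=[], edge_scores=[], alpha=0.5, score=score,
            n_random=1000, pvalue=p,
        )

    def test_all_insignificant_empty(self):
        recs = [self._rec(0.5, 1.0, i) for i in range(5)]
        assert dysregulated_ffls(recs) == []

    def test_single_hit(self):
        recs = [self._rec(0.5, 1.0, 0), self._rec(0.005, 2.0, 1)]
        assert [r.pvalue for r in dysregulated_ffls(recs)] == [0.005]

    def test_sorting_matches_hand_sort(self, rng):
        ps = list(rng.uniform(0, 0.02, 20).round(4))
        scores = list(rng.normal(size=20).round(4))
        recs = [self._rec(p, s, i) for i, (p, s) in enumerate(zip(ps, scores))]
        got = dysregulated_ffls(recs, p_cut=0.01)
        expected = sorted(
            [r for r in recs if r.pvalue < 0.01],
            key=lambda r: (r.pvalue, -r.score, r.ffl.key),
        )
        assert got == expected

    def test_mixed_n_random_rejected(self):
        a, b = self._rec(0.1, 0, 0), self._rec(0.1, 0, 1)
        b.n_random = 99
        with pytest.raises(ValueError):
            dysregulated_ffls([a, b])


class TestEnrichment:
    def test_no_overlap_is_one(self):
        assert enrichment_test({"a"}, {"a", "b"}, {"c"}) == 1.0

    def test_degenerate_full_selection(self):
        u = {"a", "b", "c"}
        assert enrichment_test(u, u, u) == pytest.approx(1.0)

    def test_matches_exact_mass_summation(self):
        # universe 20, annotated 5, draws 6, observed overlap 4
        universe = {f"u{i}" for i in range(20)}
        annotated = {f"u{i}" for i in range(5)}
        selected = {"u0", "u1", "u2", "u3", "u10", "u11"}
        expected = sum(
            math.comb(5, k) * math.comb(15, 6 - k) / math.comb(20, 6) for k in (4, 5)
        )
        assert enrichment_test(selected, universe, annotated) == pytest.approx(expected, abs=1e-12)

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test({"x"}, {"a"}, set())
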