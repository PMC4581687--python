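import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from dignet import diffint
from dignet.errors import ConstantInputError, ParameterError, SampleSizeError
from tests.conftest import make_expression


class TestPearsonWithPvalue:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = diffint.pearson_with_pvalue(x, x)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_exact_zero_correlation_gives_p_one(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        r, p = diffint.pearson_with_pvalue(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_t_evaluation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 5.0, 4.0])
        # independent evaluation from the definition
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        t = r_direct * math.sqrt((len(x) - 2) / (1 - r_direct**2))
        p_direct = 2 * stats.t.sf(abs(t), df=len(x) - 2)
        r, p = diffint.pearson_with_pvalue(x, y)
        assert r == pytest.approx(r_direct, abs=1e-12)
        assert p == pytest.approx(p_direct, abs=1e-12)

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=(2, 15))
            r, p = diffint.pearson_with_pvalue(x, y)
            r_ref, p_ref = stats.pearsonr(x, y)
            assert r == pytest.approx(r_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_error_contracts(self):
        with pytest.raises(SampleSizeError):
            diffint.pearson_with_pvalue([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ConstantInputError):
            diffint.pearson_with_pvalue([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCoexpressionEdges:
    def test_shared_latent_factor_pair_is_detected(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=30)
        vals = np.vstack(
            [
                0.95 * f + 0.3 * rng.normal(size=30),
                0.95 * f + 0.3 * rng.normal(size=30),
                rng.normal(size=30),
            ]
        )
        m = make_expression(np.hstack([vals, vals]), n_disease=30)
        edges = diffint.coexpression_edges(m, "disease")
        assert ("G0000", "G0001") in edges
        r, p = edges[("G0000", "G0001")]
        assert r >= 0.75 and p <= 0.05

    def test_independent_noise_genes_have_no_edge(self):
        rng = np.random.default_rng(2)
        m = make_expression(rng.normal(size=(10, 60)), n_disease=30)
        assert diffint.coexpression_edges(m, "control") == {}

    def test_r_min_one_keeps_only_collinear_pairs(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=30)
        vals = np.vstack([base, 2 * base + 1, rng.normal(size=30)])
        m = make_expression(np.hstack([vals, vals]), n_disease=30)
        edges = diffint.coexpression_edges(
            m, "disease", diffint.CoexpressionParams(r_min=1.0)
        )
        assert set(edges) == {("G0000", "G0001")}

    def test_too_few_samples_is_an_error(self):
        m = make_expression(np.arange(8.0).reshape(2, 4), n_disease=2)
        with pytest.raises(SampleSizeError):
            diffint.coexpression_edges(m, "disease")

    def test_raising_r_min_never_adds_edges(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=20)
        vals = 0.9 * f + 0.4 * rng.normal(size=(12, 20))
        m = make_expression(np.hstack([vals, vals]), n_disease=20)
        loose = set(diffint.coexpression_edges(m, "disease", diffint.CoexpressionParams(r_min=0.6)))
        tight = set(diffint.coexpression_edges(m, "disease", diffint.CoexpressionParams(r_min=0.8)))
        assert tight <= loose


class TestConditionSpecificPPIN:
    def test_intersection_semantics(self):
        coexpr = {("A", "B"): (0.9, 0.001), ("A", "C"): (0.8, 0.01)}
        ppin = nx.Graph([("A", "B"), ("B", "C")])
        net = diffint.condition_specific_ppin(coexpr, ppin)
        assert set(net.edges) == {("A", "B")}
        assert net.nodes == {"A", "B"}  # isolated genes are not nodes

    def test_identity_and_empty_cases(self):
        coexpr = {("A", "B"): (0.9, 0.001)}
        assert set(diffint.condition_specific_ppin(coexpr, nx.Graph([("A", "B")])).edges) == {("A", "B")}
        assert diffint.condition_specific_ppin(coexpr, nx.Graph([("X", "Y")])).edges == {}


class TestDetectDigs:
    def _net(self, condition, pairs):
        return diffint.ConditionNetwork(condition, {tuple(sorted(p)): (0.9, 0.001) for p in pairs})

    def test_identical_networks_yield_no_digs(self):
        d = self._net("disease", [("A", "B")])
        c = self._net("control", [("A", "B")])
        digs, _ = diffint.detect_digs(d, c)
        assert digs == set()

    def test_hand_enumerated_example(self):
        # disease {A-B, A-C}, control {A-B, A-D}: only A is common with
        # different neighbors; C and D are not common genes; B is unchanged
        d = self._net("disease", [("A", "B"), ("A", "C")])
        c = self._net("control", [("A", "B"), ("A", "D")])
        digs, evidence = diffint.detect_digs(d, c)
        assert digs == {"A"}
        nd, nc = evidence["A"]
        assert nd == {"B", "C"} and nc == {"B", "D"}

    def test_symmetric_in_condition_labels(self):
        d = self._net("disease", [("A", "B"), ("C", "D")])
        c = self._net("control", [("A", "B"), ("A", "C")])
        digs_1, _ = diffint.detect_digs(d, c)
        digs_2, _ = diffint.detect_digs(c, d)
        assert digs_1 == digs_2

    def test_every_dig_has_differing_neighbor_sets(self):
        d = self._net("disease", [("A", "B"), ("A", "C"), ("B", "C")])
        c = self._net("control", [("A", "B"), ("B", "C")])
        digs, evidence = diffint.detect_digs(d, c)
        for g in digs:
            nd, nc = evidence[g]
            assert nd.symmetric_difference(nc)


class TestAggregateDigs:
    def test_union_and_monotonicity(self):
        agg = diffint.aggregate_digs({"p1": {"A", "B"}, "p2": {"B", "C"}})
        assert agg == {"A", "B", "C"}
        assert len(agg) >= 2

    def test_single_profile_identity_and_empty_error(self):
        assert diffint.aggregate_digs({"p1": {"A"}}) == {"A"}
        with pytest.raises(ParameterError):
            diffint.aggregate_digs({})


class TestClusteringAgreement:
    def test_separated_groups_score_one(self):
        scores = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            control = rng.normal(0.0, 1.0, size=(10, 15))
            disease = rng.normal(6.0, 1.0, size=(10, 15))
            m = make_expression(np.hstack([control, disease]), n_disease=15)
            scores.append(diffint.clustering_agreement(m, m.gene_ids))
        assert min(scores) == 1.0

    def test_noise_genes_score_near_chance(self):
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = make_expression(rng.normal(size=(10, 30)), n_disease=15)
            scores.append(diffint.clustering_agreement(m, m.gene_ids))
        assert 0.5 <= np.mean(scores) < 0.8

    def test_duplicated_samples_return_deterministically(self):
        vals = np.tile(np.arange(5.0).reshape(5, 1), (1, 8))
        m = make_expression(vals, n_disease=4)
        s1 = diffint.clustering_agreement(m, m.gene_ids)
        s2 = diffint.clustering_agreement(m, m.gene_ids)
        assert s1 == s2 and 0.5 <= s1 <= 1.0
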