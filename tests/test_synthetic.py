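import numpy as np
import pandas as pd
import pytest

from dignet import preprocessing
from dignet.errors import ParameterError
from dignet.motifs import brute_force_enumerate
from dignet.regnet import build_network, filter_mirna_targets
from dignet.survival import logrank_test, median_split, prognostic_index
from dignet.synthetic_data import (
    SyntheticConfig,
    generate_expression,
    generate_ppin,
    generate_regulatory_layers,
    generate_survival,
)
from tests.conftest import make_expression


def _flat_config(**kw):
    """A config without modules/rewiring, for pure-backbone PPI checks."""
    defaults = dict(n_modules=0, module_size=1, n_rewired=0)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestGeneratePPIN:
    def test_attachment_one_yields_a_tree(self):
        g = generate_ppin(_flat_config(n_genes=10, ppi_attachment=1))
        assert g.number_of_nodes() == 10
        assert g.number_of_edges() == 9

    def test_seeded_determinism(self):
        cfg = SyntheticConfig(seed=42)
        e1 = sorted(generate_ppin(cfg).edges)
        e2 = sorted(generate_ppin(cfg).edges)
        assert e1 == e2

    def test_degree_distribution_is_heavy_tailed(self):
        g = generate_ppin(_flat_config(n_genes=500, seed=5))
        degrees = np.array([d for _, d in g.degree()])
        assert degrees.max() >= 3 * np.median(degrees)
        # log-log degree-rank slope must be negative
        ranked = np.sort(degrees)[::-1].astype(float)
        slope = np.polyfit(np.log10(np.arange(1, len(ranked) + 1)), np.log10(ranked), 1)[0]
        assert slope < 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            SyntheticConfig(n_genes=5)


class TestGenerateExpression:
    def test_no_rewiring_gives_empty_ground_truth(self):
        cfg = SyntheticConfig(n_rewired=0)
        expr, truth = generate_expression(generate_ppin(cfg), cfg)
        assert truth.rewired_genes == set()

    def test_within_module_correlation_exceeds_target(self):
        rs = []
        for seed in range(10):
            cfg = SyntheticConfig(within_module_corr=0.9, seed=seed)
            expr, truth = generate_expression(generate_ppin(cfg), cfg)
            module0 = [g for g, j in truth.module_assignments["control"].items() if j == 0]
            sub = expr.values.loc[sorted(module0), expr.condition_samples("control")]
            corr = np.corrcoef(sub.to_numpy())
            rs.append(corr[np.triu_indices_from(corr, k=1)].mean())
        assert np.mean(rs) > 0.6

    def test_rewired_genes_change_module_between_conditions(self):
        cfg = SyntheticConfig(seed=3)
        _, truth = generate_expression(generate_ppin(cfg), cfg)
        assert len(truth.rewired_genes) == cfg.n_rewired
        for gene in truth.rewired_genes:
            assert (
                truth.module_assignments["control"][gene]
                != truth.module_assignments["disease"][gene]
            )

    def test_seeded_determinism(self):
        cfg = SyntheticConfig(seed=11)
        ppin = generate_ppin(cfg)
        a, _ = generate_expression(ppin, cfg)
        b, _ = generate_expression(ppin, cfg)
        assert a.values.equals(b.values)

    def test_module_capacity_validated(self):
        with pytest.raises(ParameterError):
            SyntheticConfig(n_genes=50, n_modules=10, module_size=10)


class TestGenerateRegulatoryLayers:
    def test_zero_planting_zero_background_gives_empty_tables(self):
        cfg = SyntheticConfig(
            n_planted_per_motif_type=0,
            bg_mirna_gene=0.0,
            bg_tf_gene=0.0,
            bg_mirna_tf=0.0,
            bg_tf_mirna=0.0,
            bg_gene_gene=0.0,
        )
        tables, planted = generate_regulatory_layers({"G0001", "G0002"}, cfg)
        assert planted == []
        for name in ("mirna_gene", "tf_gene", "mirna_tf", "tf_mirna", "gene_gene"):
            assert len(getattr(tables, name)) == 0

    def test_planted_mirna_rows_pass_the_evidence_filter(self):
        cfg = SyntheticConfig(n_planted_per_motif_type=5, seed=2)
        genes = {f"G{i:04d}" for i in range(25)}
        tables, planted = generate_regulatory_layers(genes, cfg)
        planted_edges = {
            (e[0], e[1])
            for m in planted
            for e in m.edges
            if e[2] == "mirna_gene"
        }
        tab = tables.mirna_gene.set_index(["mirna", "gene"])
        for edge in planted_edges:
            row = tab.loc[edge]
            assert row["supporting_experiments"] >= 5
            assert row["pan_cancer"] >= 3
        # and the filter keeps every planted edge
        kept = filter_mirna_targets(tables.mirna_gene)
        kept_edges = set(map(tuple, kept[["mirna", "gene"]].to_numpy()))
        assert planted_edges <= kept_edges

    def test_planted_joints_found_by_exhaustive_scan(self):
        cfg = SyntheticConfig(n_planted_per_motif_type=5, seed=9)
        genes = {f"G{i:04d}" for i in range(30)}
        tables, planted = generate_regulatory_layers(genes, cfg)
        net = build_network(
            genes,
            tables.mirna_gene,
            tables.tf_gene,
            tables.mirna_tf,
            tables.tf_mirna,
            [tuple(r) for r in tables.gene_gene.itertuples(index=False, name=None)],
        )
        found = {m.key() for m in brute_force_enumerate(net, "joint")}
        planted_joints = {m.key() for m in planted if m.motif_type == "joint"}
        assert len(planted_joints) == 5
        assert planted_joints <= found

    def test_too_few_genes_to_plant_is_an_error(self):
        cfg = SyntheticConfig(n_planted_per_motif_type=5)
        with pytest.raises(ParameterError):
            generate_regulatory_layers({"G0001"}, cfg)


class TestGenerateSurvival:
    def test_no_censoring_means_all_events_observed(self):
        rng = np.random.default_rng(0)
        expr = make_expression(rng.normal(size=(3, 40)))
        cfg = SyntheticConfig(censoring_rate=0.0)
        cohort = generate_survival(expr, {"G0000": 0.5}, cfg)
        assert cohort.event.sum() == 40

    def test_censoring_rate_matches_request(self):
        rng = np.random.default_rng(1)
        expr = make_expression(rng.normal(size=(2, 2000)))
        cfg = SyntheticConfig(censoring_rate=0.4, seed=4)
        cohort = generate_survival(expr, {"G0000": 0.3}, cfg)
        assert cohort.event.mean() == pytest.approx(0.6, abs=0.05)

    def test_high_risk_samples_fail_earlier(self):
        diffs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            expr = make_expression(rng.normal(size=(1, 200)))
            cfg = SyntheticConfig(censoring_rate=0.0, seed=seed)
            cohort = generate_survival(expr, {"G0000": 2.0}, cfg)
            x = cohort.covariates["G0000"].to_numpy()
            diffs.append(cohort.time[x > 0].mean() - cohort.time[x <= 0].mean())
        assert np.mean(diffs) < 0  # high expression, shorter observed time

    def test_null_betas_give_uniform_logrank_p(self):
        # split on the covariate itself: independent of survival under the null
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            expr = make_expression(rng.normal(size=(1, 100)))
            cfg = SyntheticConfig(censoring_rate=0.2, seed=seed)
            cohort = generate_survival(expr, {"G0000": 0.0}, cfg)
            pi = prognostic_index(pd.Series({"G0000": 1.0}), cohort)
            hits += logrank_test(median_split(pi), cohort) < 0.05
        assert 0.01 <= hits / n_seeds <= 0.10

    def test_unknown_beta_gene_is_an_error(self):
        expr = make_expression(np.zeros((2, 10)) + np.arange(10))
        with pytest.raises(ParameterError):
            generate_survival(expr, {"NOPE": 1.0}, SyntheticConfig())
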