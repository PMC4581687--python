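"""End-to-end orchestration: expression -> DIGs -> regulatory network ->
motifs -> significance -> survival.

A run is fully determined by its configuration (one global seed; each stage
derives its own stream from it), writes every intermediate artifact into the
run directory, and finishes with ``summary.json`` holding the headline
numbers and ``manifest.json`` recording how to reproduce them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from . import diffint, motifs as motifs_mod, preprocessing, regnet, significance, survival as survival_mod
from .errors import DegenerateInputError, ParameterError
from .preprocessing import ExpressionMatrix
from .synthetic_data import (
    GroundTruth,
    SyntheticConfig,
    generate_expression,
    generate_ppin,
    generate_regulatory_layers,
    generate_survival,
    read_ppin,
    write_ppin,
)

logger = logging.getLogger(__name__)

MOTIF_TYPES = motifs_mod.MOTIF_TYPES


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of ``synthetic`` / ``inputs``."""

    synthetic: SyntheticConfig | None = None
    inputs: dict[str, str] | None = None
    r_min: float = 0.75
    p_max: float = 0.05
    use_abs_corr: bool = False
    require_regulator_edge: bool = True
    exclusive_crosstalk: bool = True
    n_permutations: int = 200
    n_hub_randomizations: int = 1000
    hub_top_k: int = 10
    cachet_quantile: float = 0.01
    biomarker_size: int = 10
    biomarker_beta: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ParameterError("provide exactly one of synthetic config or input paths")
        if self.n_permutations < 1 or self.n_hub_randomizations < 1:
            raise ParameterError("permutation counts must be positive")
        if not 0 < self.cachet_quantile <= 1:
            raise ParameterError("cachet_quantile must be in (0, 1]")
        if self.inputs is not None:
            required = {"expr", "groups", "ppin", "mirna_gene", "tf_gene"}
            missing = required - set(self.inputs)
            if missing:
                raise ParameterError(f"missing input paths: {sorted(missing)}")
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise ParameterError(f"input path for {key!r} does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        synth = payload.pop("synthetic", None)
        if synth is not None:
            synth = SyntheticConfig(**synth)
        return cls(synthetic=synth, **payload)

    def as_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        return out


def demo_config(seed: int = 0, **overrides) -> PipelineConfig:
    """The default synthetic end-to-end scenario."""
    synth = SyntheticConfig(seed=seed)
    return PipelineConfig(synthetic=synth, seed=seed, **overrides)


def compare_gene_sets(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
) -> dict[str, float]:
    """Overlap statistics (|A|, |B|, intersection, Jaccard, hypergeometric p).

    The p-value is the upper tail of drawing |A| genes from a universe of
    ``universe_size`` containing |B| successes and seeing at least the
    observed intersection.
    """
    a, b = set(set_a), set(set_b)
    union = a | b
    if universe_size < len(union):
        raise ParameterError("universe smaller than the union of the sets")
    m = len(a & b)
    p = significance.hypergeom_upper_tail(m, len(a), len(b), universe_size) if a and b else 1.0
    jaccard = m / len(union) if union else 0.0
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_overlap": m,
        "jaccard": jaccard,
        "hypergeom_p": float(p),
    }


def _stage_seed(config: PipelineConfig, offset: int) -> int:
    # fixed offsets so any stage can be re-run in isolation
    return int(np.random.SeedSequence([config.seed, offset]).generate_state(1)[0] % 2**31)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every stage and write artifacts + summary into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {}
    truth: GroundTruth | None = None

    # ------------------------------------------------------------ stage: data
    if config.synthetic is not None:
        scfg = dataclasses.replace(config.synthetic, seed=config.seed)
        ppin = generate_ppin(scfg)
        expr, truth = generate_expression(ppin, scfg)
        write_ppin(ppin, outdir / "ppin.tsv")
        expr.to_tsv(outdir / "expression.tsv", outdir / "groups.tsv")
    else:
        scfg = None
        expr = ExpressionMatrix.from_tsv(config.inputs["expr"], config.inputs["groups"])
        ppin = read_ppin(config.inputs["ppin"])

    # --------------------------------------------------- stage: preprocessing
    pre = preprocessing.preprocess(expr)
    pre.to_tsv(outdir / "expression.preprocessed.tsv", outdir / "groups.tsv")

    # --------------------------------------------------------- stage: diffint
    params = diffint.CoexpressionParams(config.r_min, config.p_max, config.use_abs_corr)
    digs, evidence, disease_net, control_net = diffint.call_digs_for_profile(pre, ppin, params)
    result = diffint.DIGResult({"profile_1": digs}, {"profile_1": evidence})
    result.to_dataframe().to_csv(outdir / "digs.tsv", sep="\t", index=False)
    disease_net.to_dataframe().to_csv(outdir / "network.disease.tsv", sep="\t", index=False)
    control_net.to_dataframe().to_csv(outdir / "network.control.tsv", sep="\t", index=False)
    summary["n_digs"] = len(digs)
    if truth is not None and truth.rewired_genes:
        planted = truth.rewired_genes
        negatives = set(pre.gene_ids) - planted
        summary["dig_sensitivity"] = len(digs & planted) / len(planted)
        summary["dig_fpr"] = len(digs - planted) / len(negatives)
    if digs:
        try:
            summary["clustering_agreement"] = diffint.clustering_agreement(pre, digs)
        except DegenerateInputError:
            summary["clustering_agreement"] = None

    # ---------------------------------------------------------- stage: regnet
    if config.synthetic is not None:
        layers, planted_motifs = generate_regulatory_layers(truth.rewired_genes, scfg)
        truth.planted_motifs = planted_motifs
        layers.write_tsv(outdir)
        gene_pairs = [tuple(r) for r in layers.gene_gene.itertuples(index=False, name=None)]
        mirna_tf_tab, tf_mirna_tab = layers.mirna_tf, layers.tf_mirna
        mirna_gene_tab, tf_gene_tab = layers.mirna_gene, layers.tf_gene
    else:
        mirna_gene_tab = pd.read_csv(config.inputs["mirna_gene"], sep="\t")
        tf_gene_tab = pd.read_csv(config.inputs["tf_gene"], sep="\t")
        mirna_tf_tab = (
            pd.read_csv(config.inputs["mirna_tf"], sep="\t")
            if "mirna_tf" in config.inputs
            else None
        )
        tf_mirna_tab = (
            pd.read_csv(config.inputs["tf_mirna"], sep="\t")
            if "tf_mirna" in config.inputs
            else None
        )
        # gene-gene layer: disease-condition co-expression restricted to PPI
        gene_pairs = [pair for pair in disease_net.edges if pair[0] in digs and pair[1] in digs]
    filtered = regnet.filter_mirna_targets(mirna_gene_tab)
    net = regnet.build_network(
        digs, filtered, tf_gene_tab, mirna_tf_tab, tf_mirna_tab, gene_pairs
    )
    net.to_tsv(outdir / "regnetwork.tsv")
    summary["network"] = {
        "n_mirna": len(net.mirnas),
        "n_tf": len(net.tfs),
        "n_gene": len(net.genes),
        "n_edges": net.n_edges,
    }
    try:
        slope, r2 = regnet.degree_distribution_fit(net)
        summary["degree_fit"] = {"slope": slope, "r_squared": r2}
    except (ParameterError, DegenerateInputError):
        summary["degree_fit"] = None

    # ---------------------------------------------------------- stage: motifs
    flags = {
        "triplet": {"require_regulator_edge": config.require_regulator_edge},
        "crosstalk": {"exclusive": config.exclusive_crosstalk},
        "joint": {},
    }
    instances: dict[str, list] = {}
    summary["motifs"] = {}
    hub_rows, cachet_frames, catalog_frames = [], [], []
    for mtype in MOTIF_TYPES:
        found = motifs_mod.find_motifs(net, mtype, **flags[mtype])
        instances[mtype] = found
        entry: dict[str, Any] = {"n_instances": len(found)}
        if truth is not None:
            planted_keys = {m.key() for m in truth.planted_motifs if m.motif_type == mtype}
            found_keys = {m.key() for m in found}
            entry["n_planted"] = len(planted_keys)
            entry["planted_recovered"] = len(planted_keys & found_keys)
        if found:
            catalog_frames.append(motifs_mod.motif_catalog(found))
            subnet = motifs_mod.build_subnet(found)
            entry["subnet_nodes"] = len(subnet.nodes)
            for node_type in ("miRNA", "TF", "gene"):
                for node, deg in motifs_mod.rank_hubs(subnet, node_type, config.hub_top_k):
                    hub_rows.append(
                        {"motif_type": mtype, "node_type": node_type, "node": node, "degree": deg}
                    )
            cachets = motifs_mod.extract_cachets(found, config.cachet_quantile)
            entry["n_cachets"] = len(cachets.ranked)
            cf = cachets.to_dataframe()
            cf.insert(0, "motif_type", mtype)
            cachet_frames.append(cf)
        summary["motifs"][mtype] = entry
    if catalog_frames:
        pd.concat(catalog_frames, ignore_index=True).to_csv(
            outdir / "motif_catalog.tsv", sep="\t", index=False
        )
    pd.DataFrame(hub_rows, columns=["motif_type", "node_type", "node", "degree"]).to_csv(
        outdir / "hubs.tsv", sep="\t", index=False
    )
    if cachet_frames:
        pd.concat(cachet_frames, ignore_index=True).to_csv(
            outdir / "cachets.tsv", sep="\t", index=False
        )

    # ---------------------------------------------------- stage: significance
    summary["significance"] = {}
    for i, mtype in enumerate(MOTIF_TYPES):
        sig = significance.motif_enrichment(
            net,
            mtype,
            n_permutations=config.n_permutations,
            seed=_stage_seed(config, 10 + i),
            **flags[mtype],
        )
        summary["significance"][mtype] = sig.as_dict()
    with open(outdir / "motif_significance.json", "w") as fh:
        json.dump(summary["significance"], fh, indent=2, sort_keys=True)

    hub_mirnas = sorted(
        {r["node"] for r in hub_rows if r["node_type"] == "miRNA"}
    )
    if hub_mirnas and digs:
        targets = {
            m: set(filtered.loc[filtered["mirna"] == m, "gene"])
            for m in hub_mirnas
        }
        universe = sorted(expr.values.index)
        hub_results = significance.hub_randomization_test(
            targets,
            digs,
            universe,
            n_iter=config.n_hub_randomizations,
            seed=_stage_seed(config, 20),
        )
        pd.DataFrame([dataclasses.asdict(h) for h in hub_results]).to_csv(
            outdir / "hub_tests.tsv", sep="\t", index=False
        )
        summary["hub_tests"] = {
            "n_hubs": len(hub_results),
            "n_fdr_significant": sum(h.fdr_significant for h in hub_results),
        }

    # -------------------------------------------------------- stage: survival
    joint_hub_genes = [
        r["node"] for r in hub_rows if r["motif_type"] == "joint" and r["node_type"] == "gene"
    ]
    if config.synthetic is not None:
        beta_genes = sorted(
            {g for m in truth.planted_motifs if m.motif_type == "joint" for g in m.genes}
        )
        truth.true_betas = {g: config.biomarker_beta for g in beta_genes}
        truth.to_json(outdir / "ground_truth.json")
        if truth.true_betas:
            cohort = generate_survival(expr, truth.true_betas, scfg)
            biomarker = joint_hub_genes[: config.biomarker_size] or beta_genes
            eval_cohort = survival_mod.SurvivalCohort(
                cohort.sample_ids,
                cohort.time,
                cohort.event,
                expr.values.loc[biomarker].T.copy(),
            )
            eval_cohort.to_tsv(outdir / "survival_cohort.tsv")
            pi_result = survival_mod.evaluate_biomarker(eval_cohort)
            summary["survival"] = pi_result.as_dict()
            summary["survival"]["biomarker_genes"] = biomarker
    elif config.inputs is not None and "survival" in config.inputs:
        cohort = survival_mod.SurvivalCohort.from_tsv(config.inputs["survival"])
        biomarker = [g for g in joint_hub_genes[: config.biomarker_size] if g in cohort.genes]
        if biomarker:
            eval_cohort = survival_mod.SurvivalCohort(
                cohort.sample_ids,
                cohort.time,
                cohort.event,
                cohort.covariates[biomarker].copy(),
            )
            pi_result = survival_mod.evaluate_biomarker(eval_cohort)
            summary["survival"] = pi_result.as_dict()
            summary["survival"]["biomarker_genes"] = biomarker

    # -------------------------------------------------------------- reporting
    manifest = {
        "config": config.as_dict(),
        "stage_seeds": {
            "enrichment": [_stage_seed(config, 10 + i) for i in range(len(MOTIF_TYPES))],
            "hub_randomization": _stage_seed(config, 20),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return outdir
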