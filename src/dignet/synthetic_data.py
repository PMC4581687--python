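"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the four data classes the analysis consumes:

* a scale-free protein-protein interaction network (preferential
  attachment, plus deterministic within-module wiring so that co-expression
  and interaction overlap);
* two-condition expression with latent-factor co-expression modules, where a
  chosen set of *rewired* genes swaps module membership between control and
  disease — the minimal mechanism that changes a gene's interaction partners
  while keeping its variance;
* miRNA/TF regulatory layers with planted triplet, crosstalk and joint
  motifs plus uniform background edges carrying evidence attributes, so the
  target filter sees both passing and failing rows;
* survival times from an exponential proportional-hazards model whose
  per-sample rate is exp(sum beta_g x_g), with independent censoring.

Everything is a pure function of :class:`SyntheticConfig` (including its
seed), so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .motifs import MotifInstance
from .preprocessing import ExpressionMatrix


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic scenario.

    Defaults describe a compact two-condition microarray-like study: 500
    genes, 30 samples per group, ten co-expression modules of ten genes,
    twenty rewired genes, and regulatory layers planted with four instances
    of each motif class.
    """

    n_genes: int = 500
    n_samples_per_group: int = 30
    n_modules: int = 10
    module_size: int = 10
    n_rewired: int = 20
    within_module_corr: float = 0.85
    noise_sd: float = 0.5
    ppi_attachment: int = 3
    n_mirna: int = 30
    n_tf: int = 20
    n_planted_per_motif_type: int = 4
    censoring_rate: float = 0.2
    baseline_hazard: float = 0.02  # events per month at PI = 0
    bg_mirna_gene: float = 0.02
    bg_tf_gene: float = 0.02
    bg_mirna_tf: float = 0.01
    bg_tf_mirna: float = 0.01
    bg_gene_gene: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ParameterError("n_genes must be >= 10")
        if min(self.n_samples_per_group, self.ppi_attachment, self.n_mirna, self.n_tf) < 1:
            raise ParameterError("sample, attachment and regulator counts must be positive")
        if self.n_modules < 0 or self.module_size < 1:
            raise ParameterError("invalid module geometry")
        if self.n_modules * self.module_size > self.n_genes:
            raise ParameterError("module capacity exceeds n_genes")
        if self.n_rewired < 0 or self.n_rewired > self.n_genes:
            raise ParameterError("n_rewired must be in [0, n_genes]")
        if not 0 < self.within_module_corr < 1:
            raise ParameterError("within_module_corr must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ParameterError("censoring_rate must be in [0, 1)")
        if self.n_planted_per_motif_type < 0:
            raise ParameterError("n_planted_per_motif_type must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure: what a perfect analysis should recover."""

    rewired_genes: set[str] = field(default_factory=set)
    planted_motifs: list[MotifInstance] = field(default_factory=list)
    true_betas: dict[str, float] = field(default_factory=dict)
    module_assignments: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rewired_genes": sorted(self.rewired_genes),
            "planted_motifs": [
                {
                    "motif_type": m.motif_type,
                    "mirna": m.mirna,
                    "tf": m.tf,
                    "genes": list(m.genes),
                    "edges": [list(e) for e in m.edges],
                }
                for m in self.planted_motifs
            ],
            "true_betas": dict(sorted(self.true_betas.items())),
            "module_assignments": {
                cond: dict(sorted(assign.items()))
                for cond, assign in sorted(self.module_assignments.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        motifs = [
            MotifInstance(
                d["motif_type"],
                d["mirna"],
                d["tf"],
                tuple(d["genes"]),
                tuple(tuple(e) for e in d["edges"]),
            )
            for d in payload["planted_motifs"]
        ]
        return cls(
            set(payload["rewired_genes"]),
            motifs,
            payload["true_betas"],
            {c: dict(a) for c, a in payload["module_assignments"].items()},
        )


# --------------------------------------------------------------------- layout


def gene_ids(config: SyntheticConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(config.n_genes)]


@dataclass
class _ModulePlan:
    """Deterministic module/rewiring layout shared by the PPI and expression
    generators.

    Within each module, members play fixed roles: slots 0-1 are *home
    anchors* (control-condition PPI partners of the module's own rewired
    genes), slots 2-3 are *guest anchors* (disease-condition partners of
    rewired genes arriving from another module), the last two slots are a
    *stable pair* wired to each other in the PPIN so the co-expression /
    interaction overlap is non-empty in both conditions, and the middle
    slots host the rewired genes themselves.
    """

    modules: list[list[str]]
    control_assignment: dict[str, int]
    disease_assignment: dict[str, int]
    rewired: list[tuple[str, int, int]]  # (gene, home module, disease module)

    @property
    def rewired_genes(self) -> set[str]:
        return {g for g, _, _ in self.rewired}


def _module_plan(config: SyntheticConfig) -> _ModulePlan:
    genes = gene_ids(config)
    modules = [
        genes[j * config.module_size : (j + 1) * config.module_size]
        for j in range(config.n_modules)
    ]
    control = {g: j for j, mod in enumerate(modules) for g in mod}
    disease = dict(control)
    rewired: list[tuple[str, int, int]] = []
    if config.n_rewired:
        if config.n_modules < 2:
            raise ParameterError("rewiring needs at least 2 modules")
        per_module = math.ceil(config.n_rewired / config.n_modules)
        if config.module_size < 6 + per_module:
            raise ParameterError(
                "module_size too small for the requested rewired genes "
                f"(need >= {6 + per_module})"
            )
        for i in range(config.n_rewired):
            home = i % config.n_modules
            slot = 4 + i // config.n_modules
            gene = modules[home][slot]
            dest = (home + 1) % config.n_modules
            disease[gene] = dest
            rewired.append((gene, home, dest))
    return _ModulePlan(modules, control, disease, rewired)


def _home_anchors(plan: _ModulePlan, module: int) -> list[str]:
    return plan.modules[module][0:2]


def _guest_anchors(plan: _ModulePlan, module: int) -> list[str]:
    return plan.modules[module][2:4]


def _stable_pair(plan: _ModulePlan, module: int) -> list[str]:
    return plan.modules[module][-2:]


# ----------------------------------------------------------------------- PPIN


def generate_ppin(config: SyntheticConfig) -> nx.Graph:
    """Scale-free PPIN by preferential attachment, plus planted module wiring.

    The Barabasi-Albert backbone supplies the heavy-tailed degree
    distribution; on top of it each module gets its stable-pair edge and
    every rewired gene gets anchor edges into both its control-condition and
    disease-condition modules, so planted rewiring is observable downstream.
    """
    g = nx.barabasi_albert_graph(config.n_genes, config.ppi_attachment, seed=int(config.seed))
    names = gene_ids(config)
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    if config.n_modules:
        plan = _module_plan(config)
        for j in range(config.n_modules):
            a, b = _stable_pair(plan, j)
            g.add_edge(a, b)
        for gene, home, dest in plan.rewired:
            for anchor in _home_anchors(plan, home):
                g.add_edge(gene, anchor)
            for anchor in _guest_anchors(plan, dest):
                g.add_edge(gene, anchor)
    return g


def write_ppin(g: nx.Graph, path: str | Path) -> None:
    pd.DataFrame(sorted(tuple(sorted(e)) for e in g.edges), columns=["gene1", "gene2"]).to_csv(
        path, sep="\t", index=False
    )


def read_ppin(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    g.add_edges_from(df.itertuples(index=False, name=None))
    return g


# ----------------------------------------------------------------- expression


def generate_expression(
    ppin: nx.Graph, config: SyntheticConfig
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Two-condition expression with latent-factor modules and planted rewiring.

    Module members load on a shared standard-normal factor with weight
    sqrt(w), w = ``within_module_corr``; the idiosyncratic residual is scaled
    by ``noise_sd``, so realized within-module correlation is
    w / (w + noise_sd^2 (1 - w)) >= w whenever noise_sd <= 1.  A rewired
    gene keeps its variance but loads on its disease-condition module's
    factor in the disease group.
    """
    plan = _module_plan(config)
    missing = [g for mod in plan.modules for g in mod if g not in ppin]
    if missing:
        raise ParameterError(f"ppin lacks planned module genes, e.g. {missing[:3]}")
    rng = np.random.default_rng([int(config.seed), 1])
    genes = gene_ids(config)
    n = config.n_samples_per_group
    w = config.within_module_corr
    lam = math.sqrt(w)
    resid = config.noise_sd * math.sqrt(1.0 - w)
    columns: list[str] = []
    blocks: list[np.ndarray] = []
    for condition, prefix, assignment in (
        ("control", "C", plan.control_assignment),
        ("disease", "D", plan.disease_assignment),
    ):
        factors = rng.normal(size=(max(config.n_modules, 1), n))
        block = rng.normal(size=(config.n_genes, n))
        for gi, gene in enumerate(genes):
            j = assignment.get(gene)
            if j is not None:
                block[gi] = lam * factors[j] + resid * block[gi]
        blocks.append(block)
        columns.extend(f"{prefix}{i:03d}" for i in range(n))
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=columns)
    groups = pd.Series(
        ["control"] * n + ["disease"] * n, index=columns, name="group"
    )
    truth = GroundTruth(
        rewired_genes=plan.rewired_genes,
        module_assignments={
            "control": dict(plan.control_assignment),
            "disease": dict(plan.disease_assignment),
        },
    )
    return ExpressionMatrix(values, groups), truth


# ----------------------------------------------------------- regulatory layers


@dataclass
class RegulatoryTables:
    """The regulatory edge tables plus gene-gene (co-expressed and
    interacting) pairs the network builder consumes."""

    mirna_gene: pd.DataFrame
    tf_gene: pd.DataFrame
    mirna_tf: pd.DataFrame
    tf_mirna: pd.DataFrame
    gene_gene: pd.DataFrame

    def write_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        for name in ("mirna_gene", "tf_gene", "mirna_tf", "tf_mirna", "gene_gene"):
            getattr(self, name).to_csv(directory / f"{name}.tsv", sep="\t", index=False)


def mirna_ids(config: SyntheticConfig) -> list[str]:
    return [f"hsa-miR-{i:03d}" for i in range(config.n_mirna)]


def tf_ids(config: SyntheticConfig) -> list[str]:
    return [f"TF{i:03d}" for i in range(config.n_tf)]


def generate_regulatory_layers(
    dig_candidates: Iterable[str], config: SyntheticConfig
) -> tuple[RegulatoryTables, list[MotifInstance]]:
    """Regulatory layers over a candidate gene set, with planted motifs.

    Exactly ``n_planted_per_motif_type`` instances of each class are
    embedded on disjoint gene pools (triplets reuse the joint pool's genes
    but with fresh regulator pairs).  Background edges are sampled uniformly
    at the configured densities; a background edge that would complete a
    planted crosstalk into the full joint pattern is rejected, so planted
    crosstalks stay crosstalks.  Planted miRNA->gene rows always satisfy the
    evidence thresholds (>= 5 experiments, >= 3 pan-cancer); background rows
    draw evidence uniformly from 1-10 and 0-5.
    """
    genes = sorted(set(dig_candidates))
    if not genes:
        raise ParameterError("dig_candidates must be non-empty")
    n_p = config.n_planted_per_motif_type
    if n_p and len(genes) < 4 * n_p:
        raise ParameterError(
            f"need >= {4 * n_p} candidate genes to plant {n_p} motifs per type"
        )
    rng = np.random.default_rng([int(config.seed), 2])
    mirnas = mirna_ids(config)
    tfs = tf_ids(config)

    mg: dict[tuple[str, str], tuple[int, int]] = {}  # edge -> (experiments, pan_cancer)
    tg: set[tuple[str, str]] = set()
    mt: set[tuple[str, str]] = set()
    tm: set[tuple[str, str]] = set()
    gg: set[tuple[str, str]] = set()
    planted: list[MotifInstance] = []
    protected_mg: set[tuple[str, str]] = set()
    protected_tg: set[tuple[str, str]] = set()

    def plant_mg(edge: tuple[str, str]) -> None:
        mg[edge] = (int(rng.integers(5, 13)), int(rng.integers(3, 7)))

    joint_pool = genes[: 2 * n_p]
    cross_pool = genes[2 * n_p : 4 * n_p]
    for i in range(n_p):
        m, t = mirnas[i % config.n_mirna], tfs[i % config.n_tf]
        g1, g2 = sorted((joint_pool[2 * i], joint_pool[2 * i + 1]))
        for g in (g1, g2):
            plant_mg((m, g))
            tg.add((t, g))
        gg.add((g1, g2))
        planted.append(
            MotifInstance(
                "joint",
                m,
                t,
                (g1, g2),
                (
                    (m, g1, "mirna_gene"),
                    (m, g2, "mirna_gene"),
                    (t, g1, "tf_gene"),
                    (t, g2, "tf_gene"),
                    (g1, g2, "gene_gene"),
                ),
            )
        )
    for i in range(n_p):
        m = mirnas[(i + n_p) % config.n_mirna]
        t = tfs[(i + n_p) % config.n_tf]
        g_t, g_m = cross_pool[2 * i], cross_pool[2 * i + 1]
        tg.add((t, g_t))
        plant_mg((m, g_m))
        gg.add(tuple(sorted((g_t, g_m))))
        protected_tg.add((t, g_m))  # completions that must stay absent
        protected_mg.add((m, g_t))
        planted.append(
            MotifInstance(
                "crosstalk",
                m,
                t,
                (g_t, g_m),
                (
                    (t, g_t, "tf_gene"),
                    (m, g_m, "mirna_gene"),
                    (min(g_t, g_m), max(g_t, g_m), "gene_gene"),
                ),
            )
        )
    for i in range(n_p):
        g = joint_pool[i % len(joint_pool)]
        m = mirnas[(i + 2 * n_p) % config.n_mirna]
        t = tfs[(i + 2 * n_p) % config.n_tf]
        plant_mg((m, g))
        tg.add((t, g))
        mt.add((m, t))
        planted.append(
            MotifInstance(
                "triplet",
                m,
                t,
                (g,),
                ((m, g, "mirna_gene"), (t, g, "tf_gene"), (m, t, "mirna_tf")),
            )
        )

    # background layers; rejection keeps planted crosstalks intact
    for m in mirnas:
        for g in genes:
            if rng.random() < config.bg_mirna_gene and (m, g) not in mg:
                if (m, g) in protected_mg:
                    continue
                mg[(m, g)] = (int(rng.integers(1, 11)), int(rng.integers(0, 6)))
    for t in tfs:
        for g in genes:
            if rng.random() < config.bg_tf_gene and (t, g) not in tg:
                if (t, g) in protected_tg:
                    continue
                tg.add((t, g))
    for m in mirnas:
        for t in tfs:
            if rng.random() < config.bg_mirna_tf:
                mt.add((m, t))
    for t in tfs:
        for m in mirnas:
            if rng.random() < config.bg_tf_mirna:
                tm.add((t, m))
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if rng.random() < config.bg_gene_gene:
                gg.add((a, b))

    tables = RegulatoryTables(
        mirna_gene=pd.DataFrame(
            [
                {"mirna": m, "gene": g, "supporting_experiments": e, "pan_cancer": pc}
                for (m, g), (e, pc) in sorted(mg.items())
            ],
            columns=["mirna", "gene", "supporting_experiments", "pan_cancer"],
        ),
        tf_gene=pd.DataFrame(sorted(tg), columns=["tf", "gene"]),
        mirna_tf=pd.DataFrame(sorted(mt), columns=["mirna", "tf"]),
        tf_mirna=pd.DataFrame(sorted(tm), columns=["tf", "mirna"]),
        gene_gene=pd.DataFrame(sorted(gg), columns=["gene1", "gene2"]),
    )
    return tables, planted


# ------------------------------------------------------------------- survival


from .survival import SurvivalCohort  # noqa: E402  (leaf import, no cycle)


def generate_survival(
    expr: ExpressionMatrix,
    true_betas: Mapping[str, float],
    config: SyntheticConfig,
) -> SurvivalCohort:
    """Exponential proportional-hazards survival for the matrix's samples.

    Event rate per sample is ``baseline_hazard * exp(PI)`` with
    PI = sum beta_g x_g.  Censoring is independent with per-sample rate
    chosen so each sample is censored with probability ``censoring_rate``
    exactly.
    """
    betas = pd.Series(dict(true_betas), dtype=float).sort_index()
    missing = [g for g in betas.index if g not in expr.values.index]
    if missing:
        raise ParameterError(f"true_betas name genes absent from expression: {missing[:5]}")
    if len(betas) == 0:
        raise ParameterError("true_betas must name at least one gene")
    rng = np.random.default_rng([int(config.seed), 3])
    X = expr.values.loc[list(betas.index)].to_numpy(dtype=float).T  # samples x genes
    pi = X @ betas.to_numpy()
    rate = config.baseline_hazard * np.exp(pi)
    t_event = rng.exponential(scale=1.0 / rate)
    p = config.censoring_rate
    if p > 0:
        censor_rate = rate * p / (1.0 - p)
        t_censor = rng.exponential(scale=1.0 / censor_rate)
        event = (t_event <= t_censor).astype(int)
        time = np.minimum(t_event, t_censor)
    else:
        event = np.ones(len(t_event), dtype=int)
        time = t_event
    covariates = pd.DataFrame(X, index=expr.sample_ids, columns=list(betas.index))
    return SurvivalCohort(expr.sample_ids, time, event, covariates)


# ------------------------------------------------------------- random networks


def random_typed_network(
    n_mirna: int,
    n_tf: int,
    n_genes: int,
    p_mirna_gene: float = 0.1,
    p_tf_gene: float = 0.1,
    p_mirna_tf: float = 0.05,
    p_tf_mirna: float = 0.02,
    p_gene_gene: float = 0.05,
    seed: int | None = None,
):
    """An unplanted Erdos-Renyi-style typed network, mainly a null model for
    calibration studies and enumeration cross-checks."""
    from .regnet import RegNetwork

    rng = np.random.default_rng(seed)
    mirnas = [f"hsa-miR-{i:03d}" for i in range(n_mirna)]
    tfs = [f"TF{i:03d}" for i in range(n_tf)]
    genes = [f"G{i:04d}" for i in range(n_genes)]
    net = RegNetwork(mirnas=set(mirnas), tfs=set(tfs), genes=set(genes))
    net.mirna_gene = {
        (m, g) for m in mirnas for g in genes if rng.random() < p_mirna_gene
    }
    net.tf_gene = {(t, g) for t in tfs for g in genes if rng.random() < p_tf_gene}
    net.mirna_tf = {(m, t) for m in mirnas for t in tfs if rng.random() < p_mirna_tf}
    net.tf_mirna = {(t, m) for t in tfs for m in mirnas if rng.random() < p_tf_mirna}
    net.gene_gene = {
        (a, b)
        for i, a in enumerate(genes)
        for b in genes[i + 1 :]
        if rng.random() < p_gene_gene
    }
    net.validate()
    return net
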