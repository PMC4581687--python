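"""Differential-interaction gene (DIG) calling.

A condition-specific network is the intersection of a condition's strong
co-expression pairs (Pearson r >= r_min, two-sided p <= p_max) with a global
protein-protein interaction network.  A gene is a DIG when it appears in both
condition networks but with different interaction partners — the signature of
interaction rewiring between disease and control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import t as t_dist

from .errors import ConstantInputError, DegenerateInputError, ParameterError, SampleSizeError
from .preprocessing import ExpressionMatrix

Pair = tuple[str, str]


@dataclass
class CoexpressionParams:
    """Thresholds for calling a co-expressed gene pair."""

    r_min: float = 0.75
    p_max: float = 0.05
    use_abs: bool = False  # threshold |r| instead of r

    def __post_init__(self) -> None:
        if not 0 < self.r_min <= 1:
            raise ParameterError("r_min must be in (0, 1]")
        if not 0 < self.p_max <= 1:
            raise ParameterError("p_max must be in (0, 1]")


@dataclass
class ConditionNetwork:
    """Co-expression edges of one condition restricted to the global PPIN."""

    condition: str
    edges: dict[Pair, tuple[float, float]]  # sorted pair -> (r, p)
    _adj: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        adj: dict[str, set[str]] = {}
        for a, b in self.edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        self._adj = adj

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    def neighbors(self, gene: str) -> set[str]:
        return set(self._adj.get(gene, set()))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"gene1": a, "gene2": b, "r": r, "p": p}
            for (a, b), (r, p) in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["gene1", "gene2", "r", "p"])


def pearson_with_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided p-value from t = r*sqrt((n-2)/(1-r^2)).

    The statistic has n-2 degrees of freedom, n being the number of paired
    observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise SampleSizeError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(t_dist.sf(abs(t), df=n - 2))
    return r, min(p, 1.0)


def coexpression_edges(
    m: ExpressionMatrix, condition: str, params: CoexpressionParams | None = None
) -> dict[Pair, tuple[float, float]]:
    """All gene pairs passing the correlation thresholds within one condition.

    Computed on the matrix as delivered by preprocessing (i.e. on per-sample
    ranks when the standard pipeline is used).  Constant genes are silently
    non-edges.
    """
    params = params or CoexpressionParams()
    samples = m.condition_samples(condition)
    n = len(samples)
    if n < 3:
        raise SampleSizeError(f"condition {condition!r} has {n} samples; need >= 3")
    X = m.values[samples].to_numpy(dtype=float)
    sd = X.std(axis=1)
    ok = sd > 0
    genes = np.asarray(m.gene_ids)[ok]
    X = X[ok]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
        np.clip(corr, -1.0, 1.0, out=corr)
        score = np.abs(corr) if params.use_abs else corr
        denom = 1.0 - corr**2
        tstat = np.where(denom > 0, corr * np.sqrt((n - 2) / np.where(denom > 0, denom, 1.0)), np.inf)
    pvals = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
    pvals = np.where(np.abs(corr) >= 1.0, 0.0, pvals)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = (score[iu, ju] >= params.r_min) & (pvals[iu, ju] <= params.p_max)
    edges: dict[Pair, tuple[float, float]] = {}
    for i, j in zip(iu[keep], ju[keep]):
        a, b = sorted((genes[i], genes[j]))
        edges[(a, b)] = (float(corr[i, j]), float(pvals[i, j]))
    return edges


def condition_specific_ppin(
    coexpr: Mapping[Pair, tuple[float, float]],
    global_ppin: nx.Graph,
    condition: str = "disease",
) -> ConditionNetwork:
    """Intersect co-expression pairs with the global PPIN edge set."""
    ppin_edges = {tuple(sorted(e)) for e in global_ppin.edges}
    edges = {pair: rp for pair, rp in coexpr.items() if tuple(sorted(pair)) in ppin_edges}
    return ConditionNetwork(condition, edges)


@dataclass
class DIGResult:
    """Per-profile DIG sets plus neighbor-set evidence for each called gene."""

    per_profile: dict[str, set[str]]
    evidence: dict[str, dict[str, tuple[frozenset, frozenset]]]  # profile -> gene -> (dis, ctl)

    @property
    def aggregate(self) -> set[str]:
        out: set[str] = set()
        for s in self.per_profile.values():
            out |= s
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for gene in sorted(self.aggregate):
            profiles = sorted(p for p, s in self.per_profile.items() if gene in s)
            dis, ctl = self.evidence[profiles[0]][gene]
            rows.append(
                {
                    "gene": gene,
                    "profiles": ",".join(profiles),
                    "disease_neighbors": ",".join(sorted(dis)),
                    "control_neighbors": ",".join(sorted(ctl)),
                }
            )
        return pd.DataFrame(
            rows, columns=["gene", "profiles", "disease_neighbors", "control_neighbors"]
        )


def detect_digs(
    disease: ConditionNetwork, control: ConditionNetwork
) -> tuple[set[str], dict[str, tuple[frozenset, frozenset]]]:
    """Genes present in both condition networks whose neighbor sets differ.

    Genes exclusive to one condition network are not DIGs: the contract
    requires commonality first.  The call is symmetric in the two conditions.
    """
    common = disease.nodes & control.nodes
    digs: set[str] = set()
    evidence: dict[str, tuple[frozenset, frozenset]] = {}
    for gene in common:
        nd = frozenset(disease.neighbors(gene))
        nc = frozenset(control.neighbors(gene))
        if nd != nc:
            digs.add(gene)
            evidence[gene] = (nd, nc)
    return digs, evidence


def aggregate_digs(per_profile: Mapping[str, Iterable[str]]) -> set[str]:
    """Union of per-profile DIG sets (a comprehensive, not consensus, call)."""
    if not per_profile:
        raise ParameterError("aggregate_digs requires at least one profile")
    out: set[str] = set()
    for genes in per_profile.values():
        out |= set(genes)
    return out


def call_digs_for_profile(
    m: ExpressionMatrix,
    global_ppin: nx.Graph,
    params: CoexpressionParams | None = None,
) -> tuple[set[str], dict, ConditionNetwork, ConditionNetwork]:
    """Convenience: condition networks and DIG call for one expression profile."""
    params = params or CoexpressionParams()
    nets = {}
    for condition in ("disease", "control"):
        co = coexpression_edges(m, condition, params)
        nets[condition] = condition_specific_ppin(co, global_ppin, condition)
    digs, evidence = detect_digs(nets["disease"], nets["control"])
    return digs, evidence, nets["disease"], nets["control"]


def clustering_agreement(m: ExpressionMatrix, gene_set: Iterable[str]) -> float:
    """How well a gene set separates the two sample groups.

    Average-linkage hierarchical clustering of samples on the gene subset is
    cut into two clusters; the score is the best label agreement over the two
    possible cluster-to-group assignments, so it lives in [0.5, 1] for
    balanced groups.
    """
    genes = [g for g in gene_set if g in m.values.index]
    if not genes:
        raise ParameterError("gene_set shares no genes with the matrix")
    labels = m.groups.to_numpy()
    for condition in ("disease", "control"):
        if (labels == condition).sum() < 2:
            raise DegenerateInputError(f"group {condition!r} has fewer than 2 samples")
    X = m.values.loc[genes].to_numpy(dtype=float).T  # samples x genes
    Z = linkage(X, method="average", metric="euclidean")
    clusters = fcluster(Z, t=2, criterion="maxclust")
    truth = (labels == "disease").astype(int)
    pred = (clusters == clusters[0]).astype(int)
    agree = float(np.mean(pred == truth))
    return max(agree, 1.0 - agree)
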