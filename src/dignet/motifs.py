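"""Enumeration of miRNA-TF co-regulatory motifs and their subnets.

Three motif classes over the synergistic regulatory network:

* ``triplet`` — a three-node feed-forward loop: a miRNA and a TF co-regulate
  one gene, and a regulatory edge links the two regulators (either
  direction).
* ``crosstalk`` — four nodes: two co-expressed, interacting genes, with the
  TF regulating one and the miRNA the other (and, by default, *not* the full
  four-edge pattern, which is classified as joint).
* ``joint`` — four nodes: both regulators regulate both of the co-expressed,
  interacting genes simultaneously.

Crosstalk and joint are mutually exclusive classifications by default, joint
taking precedence on the full four-edge pattern; a flag relaxes this.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParameterError
from .regnet import RegNetwork

MOTIF_TYPES = ("triplet", "crosstalk", "joint")

Edge = tuple[str, str, str]  # (source, target, edge_type)


@dataclass(frozen=True)
class MotifInstance:
    """One motif occurrence.

    ``genes`` holds one gene for a triplet, the unordered (sorted) pair for a
    joint, and the ordered pair ``(tf_target, mirna_target)`` for a crosstalk
    — the order *is* the role map.  ``edges`` records the member edges but
    does not participate in identity.
    """

    motif_type: str
    mirna: str
    tf: str
    genes: tuple[str, ...]
    edges: tuple[Edge, ...] = field(default=(), compare=False)

    def key(self) -> tuple:
        return (self.motif_type, self.mirna, self.tf, self.genes)

    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.mirna, self.tf) + self.genes


def _regulator_indexes(net: RegNetwork):
    m_targets: dict[str, set[str]] = defaultdict(set)
    t_targets: dict[str, set[str]] = defaultdict(set)
    m_of_gene: dict[str, set[str]] = defaultdict(set)
    t_of_gene: dict[str, set[str]] = defaultdict(set)
    for m, g in net.mirna_gene:
        m_targets[m].add(g)
        m_of_gene[g].add(m)
    for t, g in net.tf_gene:
        t_targets[t].add(g)
        t_of_gene[g].add(t)
    return m_targets, t_targets, m_of_gene, t_of_gene


def _regulator_pair_edges(net: RegNetwork, m: str, t: str) -> tuple[Edge, ...]:
    out = []
    if (m, t) in net.mirna_tf:
        out.append((m, t, "mirna_tf"))
    if (t, m) in net.tf_mirna:
        out.append((t, m, "tf_mirna"))
    return tuple(out)


def find_triplets(net: RegNetwork, require_regulator_edge: bool = True) -> list[MotifInstance]:
    """All feed-forward (miRNA, TF, gene) triples.

    With ``require_regulator_edge=False`` the looser co-targeting-only
    definition is used (no miRNA-TF edge needed).
    """
    m_targets, t_targets, _, _ = _regulator_indexes(net)
    if require_regulator_edge:
        pairs = {(m, t) for m, t in net.mirna_tf} | {(m, t) for t, m in net.tf_mirna}
    else:
        pairs = {(m, t) for m in m_targets for t in t_targets}
    out = []
    for m, t in sorted(pairs):
        common = (m_targets.get(m, set()) & t_targets.get(t, set())) - {t}
        reg_edges = _regulator_pair_edges(net, m, t)
        for g in sorted(common):
            edges = ((m, g, "mirna_gene"), (t, g, "tf_gene")) + reg_edges
            out.append(MotifInstance("triplet", m, t, (g,), edges))
    return out


def find_joint(net: RegNetwork) -> list[MotifInstance]:
    """All (miRNA, TF, {g1, g2}) with both regulators targeting both genes."""
    _, _, m_of_gene, t_of_gene = _regulator_indexes(net)
    out = []
    for g1, g2 in sorted(net.gene_gene):
        ms = m_of_gene[g1] & m_of_gene[g2]
        ts = (t_of_gene[g1] & t_of_gene[g2]) - {g1, g2}
        for m in sorted(ms):
            for t in sorted(ts):
                edges = (
                    (m, g1, "mirna_gene"),
                    (m, g2, "mirna_gene"),
                    (t, g1, "tf_gene"),
                    (t, g2, "tf_gene"),
                    (g1, g2, "gene_gene"),
                )
                out.append(MotifInstance("joint", m, t, (g1, g2), edges))
    return out


def find_crosstalk(net: RegNetwork, exclusive: bool = True) -> list[MotifInstance]:
    """All (miRNA, TF, g_tf, g_mirna) with split regulation of a gene pair.

    ``genes`` is ordered (TF-regulated gene, miRNA-regulated gene).  With
    ``exclusive=True`` (default) quadruples that carry the full joint pattern
    are excluded, making crosstalk and joint disjoint classes.
    """
    _, _, m_of_gene, t_of_gene = _regulator_indexes(net)
    out = []
    for pair in sorted(net.gene_gene):
        for g_t, g_m in (pair, pair[::-1]):
            for t in sorted(t_of_gene[g_t] - {g_t, g_m}):
                for m in sorted(m_of_gene[g_m]):
                    if exclusive and t in t_of_gene[g_m] and m in m_of_gene[g_t]:
                        continue  # full 4-edge pattern: classified joint
                    edges = (
                        (t, g_t, "tf_gene"),
                        (m, g_m, "mirna_gene"),
                        (min(g_t, g_m), max(g_t, g_m), "gene_gene"),
                    )
                    out.append(MotifInstance("crosstalk", m, t, (g_t, g_m), edges))
    return out


def find_motifs(net: RegNetwork, motif_type: str, **flags) -> list[MotifInstance]:
    if motif_type == "triplet":
        return find_triplets(net, **{k: v for k, v in flags.items() if k == "require_regulator_edge"})
    if motif_type == "crosstalk":
        return find_crosstalk(net, **{k: v for k, v in flags.items() if k == "exclusive"})
    if motif_type == "joint":
        return find_joint(net)
    raise ParameterError(f"unknown motif type {motif_type!r}")


def count_motifs(net: RegNetwork, motif_type: str, **flags) -> int:
    return len(find_motifs(net, motif_type, **flags))


def brute_force_enumerate(
    net: RegNetwork,
    motif_type: str,
    require_regulator_edge: bool = True,
    exclusive: bool = True,
) -> list[MotifInstance]:
    """Literal scan over all node triples/quadruples; the test oracle.

    Quadratic-to-cubic in network size; intended for small networks only.
    """
    mirnas = sorted(net.mirnas)
    tfs = sorted(net.tfs)
    genes = sorted(net.genes)
    out = []
    if motif_type == "triplet":
        for m in mirnas:
            for t in tfs:
                has_reg = (m, t) in net.mirna_tf or (t, m) in net.tf_mirna
                if require_regulator_edge and not has_reg:
                    continue
                for g in genes:
                    if g == t:
                        continue
                    if (m, g) in net.mirna_gene and (t, g) in net.tf_gene:
                        edges = ((m, g, "mirna_gene"), (t, g, "tf_gene")) + _regulator_pair_edges(net, m, t)
                        out.append(MotifInstance("triplet", m, t, (g,), edges))
        return out
    if motif_type == "joint":
        for m in mirnas:
            for t in tfs:
                for g1, g2 in combinations(genes, 2):
                    if t in (g1, g2):
                        continue
                    if (
                        tuple(sorted((g1, g2))) in net.gene_gene
                        and (m, g1) in net.mirna_gene
                        and (m, g2) in net.mirna_gene
                        and (t, g1) in net.tf_gene
                        and (t, g2) in net.tf_gene
                    ):
                        pair = tuple(sorted((g1, g2)))
                        edges = (
                            (m, pair[0], "mirna_gene"),
                            (m, pair[1], "mirna_gene"),
                            (t, pair[0], "tf_gene"),
                            (t, pair[1], "tf_gene"),
                            (pair[0], pair[1], "gene_gene"),
                        )
                        out.append(MotifInstance("joint", m, t, pair, edges))
        return out
    if motif_type == "crosstalk":
        for m in mirnas:
            for t in tfs:
                for g_t in genes:
                    for g_m in genes:
                        if g_t == g_m or t in (g_t, g_m):
                            continue
                        if tuple(sorted((g_t, g_m))) not in net.gene_gene:
                            continue
                        if (t, g_t) not in net.tf_gene or (m, g_m) not in net.mirna_gene:
                            continue
                        if exclusive and (t, g_m) in net.tf_gene and (m, g_t) in net.mirna_gene:
                            continue
                        edges = (
                            (t, g_t, "tf_gene"),
                            (m, g_m, "mirna_gene"),
                            (min(g_t, g_m), max(g_t, g_m), "gene_gene"),
                        )
                        out.append(MotifInstance("crosstalk", m, t, (g_t, g_m), edges))
        return out
    raise ParameterError(f"unknown motif type {motif_type!r}")


@dataclass
class Subnet:
    """Union graph of all instances of one motif type."""

    motif_type: str
    mirnas: set[str] = field(default_factory=set)
    tfs: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)
    edges: set[Edge] = field(default_factory=set)

    @property
    def nodes(self) -> set[str]:
        return self.mirnas | self.tfs | self.genes

    def total_degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {n: 0 for n in self.nodes}
        for a, b, _ in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"source": a, "target": b, "edge_type": e} for a, b, e in sorted(self.edges)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "edge_type"])


def build_subnet(instances: Sequence[MotifInstance]) -> Subnet:
    """Collapse motif instances of one type into their union subnet."""
    types = {inst.motif_type for inst in instances}
    if len(types) > 1:
        raise ParameterError(f"mixed motif types in subnet: {sorted(types)}")
    motif_type = next(iter(types)) if types else "empty"
    sub = Subnet(motif_type)
    for inst in instances:
        sub.mirnas.add(inst.mirna)
        sub.tfs.add(inst.tf)
        sub.genes.update(inst.genes)
        sub.edges.update(inst.edges)
    return sub


def rank_hubs(subnet: Subnet, node_type: str, top_k: int = 10) -> list[tuple[str, int]]:
    """Nodes of one type sorted by total degree within the subnet.

    Ties break lexicographically by node id.  Returns (node, degree) pairs.
    """
    pools = {"miRNA": subnet.mirnas, "TF": subnet.tfs, "gene": subnet.genes}
    if node_type not in pools:
        raise ParameterError(f"node_type must be one of {sorted(pools)}")
    deg = subnet.total_degrees()
    ranked = sorted(pools[node_type], key=lambda n: (-deg[n], n))
    return [(n, deg[n]) for n in ranked[:top_k]]


@dataclass
class CachetSet:
    """Top miRNA-TF pairs by number of distinct co-regulated genes."""

    motif_type: str
    ranked: list[tuple[str, str, int]]  # (mirna, tf, n_coregulated_genes)
    cutoff_rank: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranked, columns=["mirna", "tf", "n_coregulated_genes"])


def extract_cachets(instances: Sequence[MotifInstance], quantile: float = 0.01) -> CachetSet:
    """The top ``quantile`` of miRNA-TF pairs by distinct regulated genes.

    The cutoff is ceil(quantile * n_pairs); ties at the cutoff count are all
    kept.
    """
    if not instances:
        raise ParameterError("extract_cachets requires at least one instance")
    types = {inst.motif_type for inst in instances}
    if len(types) > 1:
        raise ParameterError("extract_cachets requires a single motif type")
    gene_sets: dict[tuple[str, str], set[str]] = defaultdict(set)
    for inst in instances:
        gene_sets[(inst.mirna, inst.tf)].update(inst.genes)
    counts = sorted(
        ((m, t, len(gs)) for (m, t), gs in gene_sets.items()),
        key=lambda row: (-row[2], row[0], row[1]),
    )
    cutoff = max(1, math.ceil(quantile * len(counts)))
    threshold = counts[cutoff - 1][2]
    kept = [row for row in counts if row[2] >= threshold]
    return CachetSet(next(iter(types)), kept, cutoff)


def motif_catalog(instances: Iterable[MotifInstance]) -> pd.DataFrame:
    rows = []
    for inst in sorted(instances, key=lambda i: i.key()):
        rows.append(
            {
                "motif_type": inst.motif_type,
                "mirna": inst.mirna,
                "tf": inst.tf,
                "gene1": inst.genes[0],
                "gene2": inst.genes[1] if len(inst.genes) > 1 else "",
                "role": "tf_target,mirna_target" if inst.motif_type == "crosstalk" else "",
            }
        )
    return pd.DataFrame(rows, columns=["motif_type", "mirna", "tf", "gene1", "gene2", "role"])
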