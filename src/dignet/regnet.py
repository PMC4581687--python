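"""The miRNA-TF synergistic regulatory network over DIGs.

The network is heterogeneous: miRNA, TF and gene nodes; four directed
regulatory edge classes (miRNA->gene, TF->gene, miRNA->TF, TF->miRNA) and one
undirected gene-gene class restricted to gene pairs that are both
co-expressed and physically interacting.  A TF whose coding gene is itself a
DIG is a single node carrying both roles; self-regulation is excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError, SchemaError

DIRECTED_EDGE_TYPES = ("mirna_gene", "tf_gene", "mirna_tf", "tf_mirna")
EDGE_TYPES = DIRECTED_EDGE_TYPES + ("gene_gene",)

MIRNA_GENE_COLUMNS = ["mirna", "gene", "supporting_experiments", "pan_cancer"]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table missing columns {missing}")


@dataclass
class RegNetwork:
    """Typed node sets plus one edge set per edge class.

    Directed edges are (source, target) tuples; gene_gene edges are stored as
    lexicographically sorted tuples.
    """

    mirnas: set[str] = field(default_factory=set)
    tfs: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)
    mirna_gene: set[tuple[str, str]] = field(default_factory=set)
    tf_gene: set[tuple[str, str]] = field(default_factory=set)
    mirna_tf: set[tuple[str, str]] = field(default_factory=set)
    tf_mirna: set[tuple[str, str]] = field(default_factory=set)
    gene_gene: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.gene_gene = {tuple(sorted(e)) for e in self.gene_gene}
        self.validate()

    def validate(self) -> None:
        for m, g in self.mirna_gene:
            if m not in self.mirnas or g not in self.genes:
                raise SchemaError(f"mirna_gene edge {m}->{g} touches unknown node")
        for t, g in self.tf_gene:
            if t not in self.tfs or g not in self.genes:
                raise SchemaError(f"tf_gene edge {t}->{g} touches unknown node")
            if t == g:
                raise SchemaError(f"self-regulation {t}->{g} not allowed")
        for m, t in self.mirna_tf:
            if m not in self.mirnas or t not in self.tfs:
                raise SchemaError(f"mirna_tf edge {m}->{t} touches unknown node")
        for t, m in self.tf_mirna:
            if t not in self.tfs or m not in self.mirnas:
                raise SchemaError(f"tf_mirna edge {t}->{m} touches unknown node")
        for a, b in self.gene_gene:
            if a not in self.genes or b not in self.genes:
                raise SchemaError(f"gene_gene edge {a}-{b} touches unknown node")
            if a == b:
                raise SchemaError(f"gene_gene self-loop on {a}")

    # ---------------------------------------------------------------- helpers
    def edge_sets(self) -> dict[str, set[tuple[str, str]]]:
        return {
            "mirna_gene": self.mirna_gene,
            "tf_gene": self.tf_gene,
            "mirna_tf": self.mirna_tf,
            "tf_mirna": self.tf_mirna,
            "gene_gene": self.gene_gene,
        }

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.edge_sets().values())

    @property
    def nodes(self) -> set[str]:
        return self.mirnas | self.tfs | self.genes

    def copy(self) -> "RegNetwork":
        return RegNetwork(
            set(self.mirnas),
            set(self.tfs),
            set(self.genes),
            set(self.mirna_gene),
            set(self.tf_gene),
            set(self.mirna_tf),
            set(self.tf_mirna),
            set(self.gene_gene),
        )

    def total_degrees(self) -> dict[str, int]:
        """Total degree (in + out + undirected) per node, over all classes."""
        deg: Counter[str] = Counter()
        for etype, edges in self.edge_sets().items():
            for a, b in edges:
                deg[a] += 1
                deg[b] += 1
        for node in self.nodes:
            deg.setdefault(node, 0)
        return dict(deg)

    def typed_degree_signature(self) -> dict[str, Counter]:
        """Per-class degree multisets, the invariant preserved by rewiring."""
        sig: dict[str, Counter] = {}
        for etype, edges in self.edge_sets().items():
            if etype == "gene_gene":
                c: Counter = Counter()
                for a, b in edges:
                    c[a] += 1
                    c[b] += 1
                sig[f"{etype}:und"] = c
            else:
                out_c: Counter = Counter()
                in_c: Counter = Counter()
                for a, b in edges:
                    out_c[a] += 1
                    in_c[b] += 1
                sig[f"{etype}:out"] = out_c
                sig[f"{etype}:in"] = in_c
        return sig

    # -------------------------------------------------------------------- I/O
    def to_dataframe(self) -> pd.DataFrame:
        node_type = {}
        for n in self.mirnas:
            node_type[n] = "miRNA"
        for n in self.tfs:
            node_type.setdefault(n, "TF")
        for n in self.genes:
            node_type.setdefault(n, "gene")
        rows = []
        for etype in EDGE_TYPES:
            for a, b in sorted(self.edge_sets()[etype]):
                rows.append(
                    {
                        "source": a,
                        "source_type": node_type[a],
                        "target": b,
                        "target_type": node_type[b],
                        "edge_type": etype,
                    }
                )
        return pd.DataFrame(
            rows, columns=["source", "source_type", "target", "target_type", "edge_type"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegNetwork":
        df = pd.read_csv(path, sep="\t")
        _require_columns(df, ["source", "target", "edge_type"], "network")
        net = cls()
        for row in df.itertuples(index=False):
            etype = row.edge_type
            if etype not in EDGE_TYPES:
                raise SchemaError(f"unknown edge type {etype!r}")
            src_t = etype.split("_")[0]
            tgt_t = etype.split("_")[1]
            for node, kind in ((row.source, src_t), (row.target, tgt_t)):
                if kind == "mirna":
                    net.mirnas.add(node)
                elif kind == "tf":
                    net.tfs.add(node)
                else:
                    net.genes.add(node)
            if etype == "gene_gene":
                net.gene_gene.add(tuple(sorted((row.source, row.target))))
            else:
                getattr(net, etype).add((row.source, row.target))
        net.validate()
        return net


def filter_mirna_targets(
    table: pd.DataFrame, min_experiments: int = 5, min_pancancer: int = 3
) -> pd.DataFrame:
    """Keep miRNA->gene rows with enough CLIP-seq support and pan-cancer
    anti-correlation evidence (both thresholds inclusive)."""
    _require_columns(table, MIRNA_GENE_COLUMNS, "mirna_gene")
    keep = (table["supporting_experiments"] >= min_experiments) & (
        table["pan_cancer"] >= min_pancancer
    )
    return table.loc[keep].reset_index(drop=True)


def merge_tf_targets(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Deduplicated union of TF->gene tables from multiple databases."""
    if not tables:
        raise ParameterError("merge_tf_targets needs at least one table")
    for t in tables:
        _require_columns(t, ["tf", "gene"], "tf_gene")
    merged = pd.concat([t[["tf", "gene"]] for t in tables], ignore_index=True)
    return merged.drop_duplicates().reset_index(drop=True)


def build_network(
    digs: Iterable[str],
    mirna_gene: pd.DataFrame,
    tf_gene: pd.DataFrame,
    mirna_tf: pd.DataFrame | None = None,
    tf_mirna: pd.DataFrame | None = None,
    coexpr_interact_pairs: Iterable[tuple[str, str]] = (),
) -> RegNetwork:
    """Assemble the synergistic regulatory network restricted to a DIG set.

    Regulatory edges are kept only when their gene target is a DIG; miRNA and
    TF nodes are kept regardless (they carry the regulator layer).  Gene-gene
    edges are the supplied co-expressed-and-interacting DIG pairs.
    """
    digs = set(digs)
    _require_columns(mirna_gene, ["mirna", "gene"], "mirna_gene")
    _require_columns(tf_gene, ["tf", "gene"], "tf_gene")
    net = RegNetwork.__new__(RegNetwork)  # fill sets, validate at the end
    net.mirnas, net.tfs, net.genes = set(), set(), set()
    net.mirna_gene, net.tf_gene = set(), set()
    net.mirna_tf, net.tf_mirna, net.gene_gene = set(), set(), set()

    for row in mirna_gene.itertuples(index=False):
        if row.gene in digs:
            net.mirna_gene.add((row.mirna, row.gene))
            net.mirnas.add(row.mirna)
            net.genes.add(row.gene)
    for row in tf_gene.itertuples(index=False):
        if row.gene in digs and row.tf != row.gene:
            net.tf_gene.add((row.tf, row.gene))
            net.tfs.add(row.tf)
            net.genes.add(row.gene)
    if mirna_tf is not None:
        _require_columns(mirna_tf, ["mirna", "tf"], "mirna_tf")
        for row in mirna_tf.itertuples(index=False):
            net.mirna_tf.add((row.mirna, row.tf))
            net.mirnas.add(row.mirna)
            net.tfs.add(row.tf)
    if tf_mirna is not None:
        _require_columns(tf_mirna, ["tf", "mirna"], "tf_mirna")
        for row in tf_mirna.itertuples(index=False):
            net.tf_mirna.add((row.tf, row.mirna))
            net.tfs.add(row.tf)
            net.mirnas.add(row.mirna)
    for a, b in coexpr_interact_pairs:
        if a in digs and b in digs and a != b:
            net.gene_gene.add(tuple(sorted((a, b))))
            net.genes.add(a)
            net.genes.add(b)
    net.validate()
    return net


def degree_distribution_fit(obj) -> tuple[float, float]:
    """Least-squares fit of log10(frequency) on log10(degree).

    Accepts anything exposing ``total_degrees()`` (RegNetwork, Subnet) or a
    networkx graph.  Degrees are binned at raw integer resolution; zero
    degrees are excluded.  Returns (slope, r_squared); a heavy-tailed network
    yields a clearly negative slope.
    """
    if hasattr(obj, "total_degrees"):
        degrees = list(obj.total_degrees().values())
    else:  # networkx graph
        degrees = [d for _, d in obj.degree()]
    if len(degrees) < 10:
        raise ParameterError("need at least 10 nodes for a degree fit")
    degrees = [d for d in degrees if d > 0]
    counts = Counter(degrees)
    if len(counts) < 2:
        raise DegenerateInputError("all nodes share one degree; fit is degenerate")
    ks = np.array(sorted(counts))
    freq = np.array([counts[k] for k in ks], dtype=float)
    x = np.log10(ks)
    y = np.log10(freq)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return float(slope), float(r2)
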