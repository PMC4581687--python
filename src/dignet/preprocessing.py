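"""Expression preprocessing: probe collapsing, imputation, standardization, ranks.

The pipeline order is collapse -> impute -> standardize -> rank.  The final
per-sample rank replacement makes every sample's marginal distribution
identical, which is what removes profile-level batch effects before
co-expression is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import MappingError, ParameterError

GROUP_LABELS = ("disease", "control")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a binary group label per sample.

    ``values`` rows are genes, columns are samples.  ``groups`` maps each
    sample id to ``"disease"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ParameterError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ParameterError("duplicate sample ids in expression matrix")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ParameterError(f"samples without group label: {sorted(missing)[:5]}")
        self.groups = self.groups.loc[self.values.columns]
        bad = set(self.groups.unique()) - set(GROUP_LABELS)
        if bad:
            raise ParameterError(f"unknown group labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.groups.index[self.groups == condition])

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], self.groups.copy())

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, values_path: str | Path, groups_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene")
        self.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, values_path: str | Path, groups_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
        return cls(values, groups)


def collapse_probes(
    probe_values: pd.DataFrame,
    probe_map: Mapping[str, Iterable[str]],
    groups: pd.Series,
) -> ExpressionMatrix:
    """Collapse a probe x sample matrix to genes.

    Probes mapping to more than one gene are discarded; when several probes
    map to the same gene their values are averaged.
    """
    unmapped = [p for p in probe_values.index if p not in probe_map]
    if unmapped:
        raise MappingError(f"probes without map entry: {unmapped[:5]}")
    rows: dict[str, list[str]] = {}
    for probe in probe_values.index:
        targets = set(probe_map[probe])
        if not targets:
            raise MappingError(f"probe {probe!r} maps to no gene")
        if len(targets) > 1:
            continue  # ambiguous probe: contributes to neither gene
        rows.setdefault(next(iter(targets)), []).append(probe)
    if not rows:
        raise MappingError("no probe maps unambiguously to a gene")
    gene_ids = sorted(rows)
    collapsed = pd.DataFrame(
        {g: probe_values.loc[rows[g]].mean(axis=0) for g in gene_ids}
    ).T
    collapsed.index.name = "gene"
    return ExpressionMatrix(collapsed, groups)


def impute_missing(
    m: ExpressionMatrix, k: int = 10, max_missing: float = 0.05
) -> ExpressionMatrix:
    """Fill missing cells with the mean of the k nearest genes at that sample.

    Nearness is Euclidean distance over the samples where the incomplete gene
    is observed.  Genes missing more than ``max_missing`` of their samples are
    dropped with a warning.
    """
    values = m.values.copy()
    frac = values.isna().mean(axis=1)
    dropped = list(values.index[frac > max_missing])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} gene(s) above the missing-value cap "
            f"{max_missing:g}: {dropped[:5]}",
            stacklevel=2,
        )
        values = values.drop(index=dropped)
    incomplete = values.index[values.isna().any(axis=1)]
    if len(incomplete) == 0:
        return ExpressionMatrix(values, m.groups.copy())
    complete = values.index[values.notna().all(axis=1)]
    if k >= len(complete):
        raise ParameterError(
            f"k={k} but only {len(complete)} complete genes available"
        )
    comp = values.loc[complete].to_numpy()
    for gene in incomplete:
        row = values.loc[gene].to_numpy(dtype=float)
        obs = ~np.isnan(row)
        dist = np.sqrt(((comp[:, obs] - row[obs]) ** 2).sum(axis=1))
        nearest = np.argsort(dist, kind="stable")[:k]
        fill = comp[nearest][:, ~obs].mean(axis=0)
        row[~obs] = fill
        values.loc[gene] = row
    return ExpressionMatrix(values, m.groups.copy())


def standardize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene across samples (mean 0, sd 1); drop constant genes."""
    if m.values.isna().any().any():
        raise ParameterError("standardize requires a complete matrix")
    sd = m.values.std(axis=1, ddof=0)
    constant = list(m.values.index[sd == 0])
    values = m.values
    if constant:
        warnings.warn(
            f"dropping {len(constant)} zero-variance gene(s): {constant[:5]}",
            stacklevel=2,
        )
        values = values.drop(index=constant)
        sd = sd.drop(index=constant)
    z = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, m.groups.copy())


def rank_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each sample's values by within-sample ranks (ties averaged).

    After this transform every sample shares the same marginal distribution
    (1..G in the tie-free case), which neutralises profile-level batch shifts.
    """
    if m.values.isna().any().any():
        raise ParameterError("rank_transform requires a complete matrix")
    ranked = rankdata(m.values.to_numpy(), method="average", axis=0)
    values = pd.DataFrame(ranked, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.groups.copy())


def preprocess(
    m: ExpressionMatrix, k: int = 10, max_missing: float = 0.05
) -> ExpressionMatrix:
    """Run impute -> standardize -> rank on a gene-level matrix."""
    return rank_transform(standardize(impute_missing(m, k=k, max_missing=max_missing)))
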