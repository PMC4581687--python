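"""Null models and significance tests for motifs and hub regulators.

Motif enrichment compares the observed motif count with counts in an
ensemble of degree-preserving random networks: double-edge swaps are
performed *within* each edge-type class, so a miRNA->gene edge can never
turn into a TF->gene edge and every node keeps its per-class in-, out- and
undirected degree.  P = N_high / n_permutations (strictly more motifs) and
Z = (N_real - N_mean) / SD.

Hub regulators are tested two ways: an exact hypergeometric upper tail for
the overlap of their targets with the disease gene set, and an empirical
randomization test that redraws the disease gene set from the gene universe,
with Benjamini-Hochberg control across hubs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .motifs import count_motifs
from .regnet import RegNetwork

logger = logging.getLogger(__name__)


def _swap_directed(edges: set, n_attempts: int, rng: np.random.Generator) -> set:
    pool = sorted(edges)
    n = len(pool)
    if n < 2:
        return set(pool)
    current = set(pool)
    for _ in range(n_attempts):
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        a, b = pool[i]
        c, d = pool[j]
        if a == d or c == b or b == d:
            continue  # self-loop or no-op swap
        e1, e2 = (a, d), (c, b)
        if e1 in current or e2 in current:
            continue
        current.discard((a, b))
        current.discard((c, d))
        current.add(e1)
        current.add(e2)
        pool[i], pool[j] = e1, e2
    return current


def _swap_undirected(edges: set, n_attempts: int, rng: np.random.Generator) -> set:
    pool = sorted(edges)
    n = len(pool)
    if n < 2:
        return set(pool)
    current = set(pool)
    for _ in range(n_attempts):
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        a, b = pool[i]
        c, d = pool[j]
        if len({a, b, c, d}) < 4:
            continue
        if rng.integers(0, 2):
            e1 = tuple(sorted((a, c)))
            e2 = tuple(sorted((b, d)))
        else:
            e1 = tuple(sorted((a, d)))
            e2 = tuple(sorted((b, c)))
        if e1 in current or e2 in current:
            continue
        current.discard(pool[i])
        current.discard(pool[j])
        current.add(e1)
        current.add(e2)
        pool[i], pool[j] = e1, e2
    return current


def degree_preserving_rewire(
    net: RegNetwork,
    n_swaps: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RegNetwork:
    """Randomize the network while conserving per-class degree sequences.

    ``n_swaps`` is the number of attempted double-edge swaps per edge-type
    class (default 10x the class edge count).  Classes with fewer than two
    edges are left unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = net.copy()
    for etype, edges in net.edge_sets().items():
        if len(edges) < 2:
            if edges:
                logger.debug("class %s has <2 edges; left unchanged", etype)
            continue
        attempts = n_swaps if n_swaps is not None else 10 * len(edges)
        if etype == "gene_gene":
            new_edges = _swap_undirected(edges, attempts, rng)
        else:
            new_edges = _swap_directed(edges, attempts, rng)
        setattr(out, etype, new_edges)
    out.validate()
    return out


@dataclass
class MotifSignificance:
    """Permutation-null summary for one motif type."""

    motif_type: str
    n_real: int
    n_mean: float
    sd: float
    n_high: int
    p_value: float
    z_value: float
    n_permutations: int

    def as_dict(self) -> dict:
        return {
            "motif_type": self.motif_type,
            "n_real": self.n_real,
            "n_mean": self.n_mean,
            "sd": self.sd,
            "n_high": self.n_high,
            "p_value": self.p_value,
            "z_value": self.z_value,
            "n_permutations": self.n_permutations,
        }


def motif_enrichment(
    net: RegNetwork,
    motif_type: str,
    n_permutations: int = 1000,
    seed: int | None = None,
    n_swaps: int | None = None,
    **motif_flags,
) -> MotifSignificance:
    """Motif count in the real network against degree-preserving rewires.

    ``p = N_high / n_permutations`` with N_high the number of random networks
    holding *strictly more* motifs than the real one;
    ``z = (N_real - N_mean) / SD``.  A degenerate SD of 0 yields z = 0 when
    the real count equals the null mean, else signed infinity.
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    n_real = count_motifs(net, motif_type, **motif_flags)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_permutations)
    counts = np.empty(n_permutations, dtype=float)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        random_net = degree_preserving_rewire(net, n_swaps=n_swaps, rng=rng)
        counts[i] = count_motifs(random_net, motif_type, **motif_flags)
    n_mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if n_permutations > 1 else 0.0
    n_high = int((counts > n_real).sum())
    p = n_high / n_permutations
    if sd > 0:
        z = (n_real - n_mean) / sd
    else:
        z = 0.0 if n_real == n_mean else math.copysign(math.inf, n_real - n_mean)
    return MotifSignificance(motif_type, n_real, n_mean, sd, n_high, p, float(z), n_permutations)


def hypergeom_upper_tail(m, n, M, N):
    """P(X >= m) for X ~ Hypergeometric(population N, successes M, draws n).

    The chance that a regulator with n targets genome-wide hits at least m of
    the M disease-related genes by chance.  Accepts scalars or broadcastable
    arrays; returns a float for all-scalar input.
    """
    m_a, n_a, M_a, N_a = np.broadcast_arrays(
        np.asarray(m), np.asarray(n), np.asarray(M), np.asarray(N)
    )
    if np.any(m_a < 0) or np.any(n_a > N_a) or np.any(M_a > N_a):
        raise ParameterError("require 0 <= m, n <= N, M <= N")
    if np.any(m_a > np.minimum(n_a, M_a)):
        raise ParameterError("m cannot exceed min(n, M)")
    p = hypergeom.sf(m_a - 1, N_a, M_a, n_a)
    if np.isscalar(m) and np.isscalar(n) and np.isscalar(M) and np.isscalar(N):
        return float(p)
    return p


@dataclass
class HubTestResult:
    node: str
    n_targets: int
    n_in_dig: int
    hypergeom_p: float
    randomization_p: float
    fdr_significant: bool


def hub_randomization_test(
    target_sets: Mapping[str, Iterable[str]],
    dig_genes: Iterable[str],
    universe: Sequence[str],
    n_iter: int = 1000,
    fdr: float = 0.01,
    seed: int | None = None,
) -> list[HubTestResult]:
    """Empirical + hypergeometric enrichment of hub targets in the DIG set.

    For each hub, the randomization p-value is the fraction of iterations in
    which a freshly drawn random gene set (same size as the DIG set) contains
    at least as many of the hub's targets as the real DIG set does.
    Benjamini-Hochberg is applied across hubs on the randomization p-values.
    """
    if not target_sets:
        return []
    universe = sorted(set(universe))
    dig_genes = set(dig_genes) & set(universe)
    if len(dig_genes) >= len(universe):
        raise ParameterError("DIG set must be strictly smaller than the universe")
    idx = {g: i for i, g in enumerate(universe)}
    hubs = sorted(target_sets)
    target_idx = {
        h: np.array(sorted(idx[g] for g in set(target_sets[h]) if g in idx), dtype=int)
        for h in hubs
    }
    real = {h: int(sum(universe[i] in dig_genes for i in target_idx[h])) for h in hubs}
    rng = np.random.default_rng(seed)
    exceed = {h: 0 for h in hubs}
    size = len(dig_genes)
    member = np.zeros(len(universe), dtype=bool)
    for _ in range(n_iter):
        member[:] = False
        member[rng.choice(len(universe), size=size, replace=False)] = True
        for h in hubs:
            if int(member[target_idx[h]].sum()) >= real[h]:
                exceed[h] += 1
    sim_p = {h: exceed[h] / n_iter for h in hubs}
    hyper_p = {
        h: hypergeom_upper_tail(real[h], len(target_idx[h]), size, len(universe))
        for h in hubs
    }
    reject, _, _, _ = multipletests([sim_p[h] for h in hubs], alpha=fdr, method="fdr_bh")
    return [
        HubTestResult(h, len(target_idx[h]), real[h], float(hyper_p[h]), sim_p[h], bool(r))
        for h, r in zip(hubs, reject)
    ]
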