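"""Treg-specific coregulatory network: expression filter, RMS normalization,
correlation edges, and the within-group connectivity permutation test.

The network is built from Treg samples only.  Genes whose maximum expression
never exceeds that of lineage-negative control genes (B-cell / macrophage
markers, which a pure T-cell sort should not express) are treated as technical
noise and removed.  Remaining rows are scaled to unit root-mean-square and all
pairwise Pearson correlations are tested; an edge is kept when its two-sided
t-based p-value clears the threshold.  Network quality is assessed by whether
a functionally coherent gene group has more within-group links than random
gene groups of the same size.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import ExpressionMatrix
from .signatures import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "CoregNetwork",
    "ConnectivityResult",
    "filter_expressed",
    "rms_normalize",
    "pcc_edges",
    "within_group_connectivity",
    "connectivity_null_test",
]


@dataclass
class CoregNetwork:
    """Undirected gene graph; each edge carries Pearson r and its p-value."""

    graph: nx.Graph
    m_samples: int

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-edges are not allowed")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": min(u, v), "gene_b": max(u, v), "r": d["r"], "p": d["p"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p"])
        return df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


@dataclass
class ConnectivityResult:
    group_name: str
    observed: int
    n_draws: int
    p_value: float
    method: str = "sample"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("empirical p must be in (0, 1]")


def filter_expressed(
    mat: ExpressionMatrix, negative_markers: GeneSet, rule: str = "max"
) -> ExpressionMatrix:
    """Remove genes below the expression floor set by lineage-negative genes.

    The floor is the max (default) or mean over negative markers of each
    marker's maximum expression across samples; genes whose own maximum does
    not exceed the floor are removed, as are the negative markers themselves.
    """
    present = [g for g in sorted(negative_markers.gene_ids) if g in mat.values.index]
    absent = sorted(negative_markers.gene_ids - set(present))
    if absent:
        logger.info("filter_expressed: %d negative marker(s) not in matrix: %s", len(absent), absent[:5])
    if not present:
        raise ValueError("no negative marker found in the expression matrix")
    marker_maxima = mat.values.loc[present].max(axis=1)
    floor = float(marker_maxima.max() if rule == "max" else marker_maxima.mean())
    keep = (mat.values.max(axis=1) > floor) & ~mat.values.index.isin(present)
    if not keep.any():
        warnings.warn("filter_expressed: all genes fall below the noise floor", stacklevel=2)
    return ExpressionMatrix(mat.values.loc[keep], mat.sample_meta.copy(), scale=mat.scale)


def rms_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene's row to unit root-mean-square across samples.

    All-zero rows cannot be scaled and are dropped with a warning.  Pearson
    correlations are invariant to this per-row scaling; it fixes the scale of
    the values fed to the correlation stage.
    """
    vals = mat.values.to_numpy(float)
    rms = np.sqrt(np.mean(vals**2, axis=1))
    degenerate = rms == 0
    if degenerate.any():
        warnings.warn(
            f"rms_normalize: dropping {int(degenerate.sum())} all-zero gene row(s)",
            stacklevel=2,
        )
    out = mat.values.loc[~degenerate].div(rms[~degenerate], axis=0)
    return ExpressionMatrix(out, mat.sample_meta.copy(), scale=mat.scale)


def pcc_edges(mat: ExpressionMatrix, p_threshold: float = 0.01) -> CoregNetwork:
    """All-pairs Pearson correlation network with t-based edge significance.

    For m samples the statistic is ``t = r * sqrt((m-2) / (1-r^2))`` with
    m-2 degrees of freedom (|r| = 1 caps at p = 0).  Constant gene rows have
    undefined correlations; they are excluded from the network and flagged.
    An unordered pair becomes an edge iff its two-sided p < ``p_threshold``.
    """
    m = mat.values.shape[1]
    if m < 3:
        raise ValueError("pcc_edges requires at least 3 samples (df = m-2 >= 1)")
    vals = mat.values.to_numpy(float)
    sd = vals.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "pcc_edges: %d constant gene row(s) excluded: %s",
            int(constant.sum()),
            list(mat.values.index[constant][:5]),
        )
    genes = mat.values.index[~constant]
    x = vals[~constant]
    corr = np.corrcoef(x)
    np.fill_diagonal(corr, 0.0)
    r = np.clip(corr, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - r**2
        t = np.where(denom > 0, r * np.sqrt((m - 2) / np.where(denom > 0, denom, 1.0)), np.inf)
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df=m - 2))
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = p[iu, ju] < p_threshold
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    graph.add_edges_from(
        (genes[i], genes[j], {"r": float(r[i, j]), "p": float(p[i, j])})
        for i, j in zip(iu[keep], ju[keep])
    )
    return CoregNetwork(graph, m_samples=m)


def within_group_connectivity(net: CoregNetwork, group: GeneSet) -> int:
    """Number of network edges with both endpoints inside the gene group."""
    in_net = group.gene_ids & set(net.graph.nodes)
    dropped = len(group) - len(in_net)
    if dropped:
        logger.info("within_group_connectivity: %d group gene(s) not in network", dropped)
    if len(in_net) < 2:
        raise ValueError("fewer than 2 group genes present in the network")
    return int(net.graph.subgraph(in_net).number_of_edges())


def _connectivity_counts(net: CoregNetwork, node_sets: np.ndarray, n_nodes: int) -> np.ndarray:
    """Within-set edge counts for each row of sampled node indices."""
    idx = {g: i for i, g in enumerate(net.graph.nodes)}
    ea = np.array([idx[u] for u, _ in net.graph.edges], dtype=np.int64)
    eb = np.array([idx[v] for _, v in net.graph.edges], dtype=np.int64)
    counts = np.empty(node_sets.shape[0], dtype=np.int64)
    member = np.zeros(n_nodes, dtype=bool)
    for row in range(node_sets.shape[0]):
        member[node_sets[row]] = True
        counts[row] = np.count_nonzero(member[ea] & member[eb])
        member[node_sets[row]] = False
    return counts


def connectivity_null_test(
    net: CoregNetwork,
    group: GeneSet,
    n_draws: int = 100_000,
    seed: int | None = None,
    method: str = "auto",
) -> ConnectivityResult:
    """Permutation significance of within-group connectivity.

    The null model draws random node groups of the same in-network size
    uniformly without replacement and recounts within-group links.  The
    sampled p uses an add-one correction, ``(1 + #{draws >= observed}) /
    (1 + n_draws)``, so it is never exactly zero.  With ``method='auto'`` the
    null is enumerated exhaustively whenever C(n, k) <= 1e5 (then
    ``p = #{subsets >= observed} / C(n, k)``).
    """
    nodes = list(net.graph.nodes)
    if len(group.gene_ids) > len(nodes):
        raise ValueError("group larger than the network")
    in_net = sorted(group.gene_ids & set(nodes))
    k = len(in_net)
    if k < 2:
        raise ValueError("fewer than 2 group genes present in the network")
    observed = within_group_connectivity(net, group)
    n = len(nodes)
    if method not in ("auto", "sample", "exhaustive"):
        raise ValueError(f"unknown method {method!r}")
    exhaustive = method == "exhaustive" or (method == "auto" and math.comb(n, k) <= 100_000)
    if exhaustive:
        total = math.comb(n, k)
        combos = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), k)),
            dtype=np.int64,
        ).reshape(total, k)
        counts = _connectivity_counts(net, combos, n)
        p = float(np.count_nonzero(counts >= observed) / total)
        return ConnectivityResult(group.name, observed, total, max(p, 1.0 / total), "exhaustive")
    rng = np.random.default_rng(seed)
    draws = np.empty((n_draws, k), dtype=np.int64)
    for i in range(n_draws):
        draws[i] = rng.choice(n, size=k, replace=False)
    counts = _connectivity_counts(net, draws, n)
    p = float((1 + np.count_nonzero(counts >= observed)) / (1 + n_draws))
    return ConnectivityResult(group.name, observed, n_draws, p, "sample")
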