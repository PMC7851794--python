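"""Context-associated centrality (CAC).

A gene's functional importance for a cellular context is scored by how
over-represented its network neighbors are among context signature genes: a
one-sided hypergeometric (Fisher exact) test of the overlap between the
gene's neighbor set and the in-universe signature, with the universe taken as
all network nodes except the focal gene.  Per-gene p-values are BH-adjusted
across the network and the CAC score is ``-log10(q)``.  Unlike degree
centrality, a low-degree gene whose few neighbors are all signature genes can
outrank a high-degree gene with an unremarkable neighborhood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coregnet import CoregNetwork
from .signatures import GeneSet

__all__ = ["CACRecord", "neighbor_enrichment", "cac_table", "top_fraction_membership"]

_Q_FLOOR = 1e-300  # keeps -log10(q) finite when the tail underflows


@dataclass
class CACRecord:
    """Neighbor-enrichment result for one gene."""

    gene_id: str
    n_neighbors: int
    n_signature_in_universe: int
    overlap: int
    universe_size: int
    p_value: float
    q_value: float = float("nan")
    cac_score: float = float("nan")
    rank: int = -1
    top_decile: bool = False
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.overlap > min(self.n_neighbors, self.n_signature_in_universe):
            raise ValueError("overlap exceeds neighbor or signature size")


def neighbor_enrichment(net: CoregNetwork, signature: GeneSet, gene: str) -> CACRecord:
    """One-sided hypergeometric enrichment of a gene's neighbors in a signature.

    The universe is the network's node set minus the focal gene; the
    signature is intersected with that universe before testing.  A degree-0
    gene cannot be enriched: p = 1, flagged.
    """
    if gene not in net.graph:
        raise KeyError(f"gene {gene!r} not in network")
    universe = set(net.graph.nodes) - {gene}
    sig = signature.gene_ids & universe
    neighbors = set(net.graph.neighbors(gene))
    k = len(neighbors & sig)
    n, big_k, big_n = len(neighbors), len(sig), len(universe)
    if n == 0:
        return CACRecord(gene, 0, big_k, 0, big_n, 1.0, flagged=True)
    p = float(min(stats.hypergeom.sf(k - 1, big_n, big_k, n), 1.0))
    return CACRecord(gene, n, big_k, k, big_n, p)


def cac_table(net: CoregNetwork, signature: GeneSet) -> pd.DataFrame:
    """CAC for every network node, ranked.

    Per-node hypergeometric enrichment p-values (see
    :func:`neighbor_enrichment`) are BH-adjusted across all nodes;
    ``cac_score = -log10(q)``.  Ranking is by ascending p with ties broken by
    descending overlap then gene id, so ranks are unique and reproducible;
    ``top_decile`` flags rank <= ceil(0.1 * N).
    """
    nodes = sorted(net.graph.nodes)
    n_univ = len(nodes) - 1
    sig_all = signature.gene_ids & set(nodes)
    degree = np.array([net.graph.degree(g) for g in nodes])
    in_sig = np.array([g in sig_all for g in nodes])
    overlap = np.array(
        [len(set(net.graph.neighbors(g)) & sig_all) for g in nodes]
    )
    big_k = len(sig_all) - in_sig.astype(int)  # signature genes in each gene's universe
    p = stats.hypergeom.sf(overlap - 1, n_univ, big_k, degree)
    p = np.minimum(np.where(degree == 0, 1.0, p), 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    score = -np.log10(np.maximum(q, _Q_FLOOR))
    df = pd.DataFrame(
        {
            "gene": nodes,
            "degree": degree,
            "n_signature_in_universe": big_k,
            "overlap": overlap,
            "universe_size": n_univ,
            "p_value": p,
            "q_value": q,
            "cac_score": score,
            "flagged": degree == 0,
        }
    )
    order = df.sort_values(
        ["p_value", "overlap", "gene"], ascending=[True, False, True], kind="mergesort"
    ).index
    df.loc[order, "rank"] = np.arange(1, len(df) + 1)
    df["rank"] = df["rank"].astype(int)
    df["top_decile"] = df["rank"] <= math.ceil(0.1 * len(df))
    return df.set_index("gene").sort_values("rank")


def top_fraction_membership(
    table: pd.DataFrame, genes: GeneSet, fraction: float = 0.1
) -> dict[str, bool]:
    """Whether each gene ranks within the top ``fraction`` of the CAC table.

    Genes absent from the table are omitted from the result (absent, not
    False); callers can detect them as missing keys.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    cutoff = math.ceil(fraction * len(table))
    return {
        g: bool(table.loc[g, "rank"] <= cutoff) for g in sorted(genes.gene_ids) if g in table.index
    }
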