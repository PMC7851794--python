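"""Gene-set algebra for the marker screen.

The marker screen is pure set arithmetic over differential-expression results:
candidate surface markers of tumor-infiltrating Tregs are the genes present in
every one of the per-contrast DEG sets (ten sets for the bulk mouse screen:
five contrasts times two DE engines), the chronic-infection-specific signature
is a set difference, and cross-species conservation is the image of the mouse
candidate set under a one-to-one ortholog map intersected with the human DEG
sets.  Every derived set carries a provenance trail so the full derivation of
the final marker list can be reconstructed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "OrthologMap",
    "intersect_sets",
    "subtract_sets",
    "rbh_orthologs",
    "map_set",
    "conserved_markers",
    "overlap_significance",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers with a provenance trail.

    Parameters
    ----------
    name
        Human-readable set name (GMT first column).
    gene_ids
        The member identifiers (stored as a frozenset; duplicates collapse).
    provenance
        Tuple of strings describing how the set was derived (contrast names,
        filters, set operations).  Required to be non-empty for derived sets;
        primary inputs may use a single entry such as ``("input",)``.
    """

    name: str
    gene_ids: frozenset[str]
    provenance: tuple[str, ...] = ("input",)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))
        if not self.provenance:
            raise ValueError(f"gene set {self.name!r} has empty provenance")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_ids


@dataclass(frozen=True)
class OrthologMap:
    """One-to-one mouse<->human gene pairing.

    ``pairs`` maps mouse id -> human id; each id may appear in at most one
    pair (enforced), so the reverse map is well defined.
    """

    pairs: dict[str, str] = field(default_factory=dict)
    method: str = "provided"

    def __post_init__(self) -> None:
        humans = list(self.pairs.values())
        if len(set(self.pairs)) != len(humans) or len(set(humans)) != len(humans):
            raise ValueError("ortholog map is not one-to-one")

    @property
    def reverse(self) -> dict[str, str]:
        return {h: m for m, h in self.pairs.items()}

    def __len__(self) -> int:
        return len(self.pairs)


def intersect_sets(sets: list[GeneSet], name: str = "intersection") -> GeneSet:
    """Genes present in every input set.

    Requires at least two sets; the result's provenance records all inputs.
    """
    if len(sets) < 2:
        raise ValueError("intersection requires at least two gene sets")
    ids = frozenset.intersection(*(s.gene_ids for s in sets))
    prov = ("intersect",) + tuple(s.name for s in sets)
    return GeneSet(name, ids, prov)


def subtract_sets(minuend: GeneSet, subtrahend: GeneSet, name: str | None = None) -> GeneSet:
    """Set difference ``minuend - subtrahend`` with provenance."""
    ids = minuend.gene_ids - subtrahend.gene_ids
    return GeneSet(
        name or f"{minuend.name}-minus-{subtrahend.name}",
        ids,
        ("subtract", minuend.name, subtrahend.name),
    )


def rbh_orthologs(scores: pd.DataFrame) -> OrthologMap:
    """Reciprocal-best-hit ortholog calls from a pairwise similarity table.

    ``scores`` must have columns ``mouse_id``, ``human_id``, ``score``.  A pair
    (m, h) is kept iff h is m's unique best-scoring human partner and m is h's
    unique best-scoring mouse partner.  A tie at either best score drops the
    candidate pair (logged) rather than resolving it arbitrarily.
    """
    required = {"mouse_id", "human_id", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"similarity table needs columns {sorted(required)}")

    def unique_best(df: pd.DataFrame, key: str, other: str) -> dict[str, str]:
        best: dict[str, str] = {}
        for ident, grp in df.groupby(key, sort=True):
            top = grp["score"].max()
            hits = grp.loc[grp["score"] == top, other]
            if hits.nunique() == 1:
                best[ident] = hits.iloc[0]
            else:
                logger.info("RBH: tie at best score for %s=%s; dropped", key, ident)
        return best

    m_best = unique_best(scores, "mouse_id", "human_id")
    h_best = unique_best(scores, "human_id", "mouse_id")
    pairs = {m: h for m, h in m_best.items() if h_best.get(h) == m}
    return OrthologMap(pairs, method="rbh")


def map_set(gene_set: GeneSet, ortholog_map: OrthologMap, reverse: bool = False) -> GeneSet:
    """Image of a gene set under the ortholog map; unmapped ids are dropped.

    With ``reverse=True`` maps human ids back to mouse ids.
    """
    table = ortholog_map.reverse if reverse else ortholog_map.pairs
    mapped = {table[g] for g in gene_set.gene_ids if g in table}
    dropped = len(gene_set) - len(mapped)
    if dropped:
        logger.info("map_set: %d of %d ids had no ortholog and were dropped", dropped, len(gene_set))
    direction = "human->mouse" if reverse else "mouse->human"
    return GeneSet(
        f"{gene_set.name}-{'mouse' if reverse else 'human'}",
        frozenset(mapped),
        gene_set.provenance + (f"ortholog-map[{direction}]",),
    )


def conserved_markers(
    mouse_candidates: GeneSet,
    human_deg_sets: list[GeneSet],
    ortholog_map: OrthologMap,
    name: str = "conserved-markers",
) -> GeneSet:
    """Human orthologs of mouse candidates found in *all* human DEG sets.

    This is the cross-species filter of the screen: a mouse candidate survives
    only if its human ortholog is differentially expressed in the tumor-Treg
    population against every comparison population.
    """
    human_image = map_set(mouse_candidates, ortholog_map)
    kept = intersect_sets([human_image, *human_deg_sets], name=name)
    return GeneSet(name, kept.gene_ids, ("conserved",) + kept.provenance[1:])


def overlap_significance(set_a: GeneSet, set_b: GeneSet, universe: GeneSet) -> tuple[int, float]:
    """Overlap count and one-sided hypergeometric enrichment p-value.

    Tests over-representation of the observed overlap ``k = |A ∩ B|`` given a
    finite universe of size N: ``p = P(X >= k)`` for X hypergeometric with
    |A| draws from a universe containing |B| successes.  Both sets must be
    subsets of the universe.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    if not set_a.gene_ids <= universe.gene_ids or not set_b.gene_ids <= universe.gene_ids:
        raise ValueError("both sets must be subsets of the universe")
    k = len(set_a.gene_ids & set_b.gene_ids)
    n_universe = len(universe)
    p = float(stats.hypergeom.sf(k - 1, n_universe, len(set_b), len(set_a)))
    return k, min(p, 1.0)
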