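"""Context-associated centrality: enrichment oracles and ranking behavior."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from tregmark.cac import cac_table, neighbor_enrichment, top_fraction_membership
from tregmark.coregnet import CoregNetwork
from tregmark.signatures import GeneSet

from conftest import make_network


def bh_stepup(pvals):
    """Independent BH oracle: the step-up definition applied literally."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        q[i] = running
    return q


def star_network(n_extra=7):
    """Focal gene f with 3 neighbors inside an 11-node graph (universe 10)."""
    edges = [("f", "n1"), ("f", "n2"), ("f", "n3")]
    extra = [f"x{i}" for i in range(n_extra)]
    return make_network(edges, nodes=extra)


class TestNeighborEnrichment:
    def test_hypergeometric_fixture(self):
        net = star_network()
        sig = GeneSet("sig", frozenset({"n1", "n2", "x0"}))
        rec = neighbor_enrichment(net, sig, "f")
        assert (rec.universe_size, rec.n_neighbors, rec.overlap) == (10, 3, 2)
        assert np.isclose(rec.p_value, 22 / 120, atol=1e-12)

    def test_empty_signature_gives_p_one(self):
        rec = neighbor_enrichment(star_network(), GeneSet("sig", frozenset()), "f")
        assert rec.p_value == 1.0

    def test_signature_equal_universe_forces_overlap(self):
        net = make_network([("f", "a"), ("f", "b")])
        sig = GeneSet("sig", frozenset({"a", "b", "f"}))
        rec = neighbor_enrichment(net, sig, "f")
        assert rec.p_value == 1.0

    def test_degree_zero_flagged(self):
        net = make_network([("a", "b")], nodes=["z"])
        rec = neighbor_enrichment(net, GeneSet("sig", frozenset({"a"})), "z")
        assert rec.p_value == 1.0 and rec.flagged

    def test_absent_gene_rejected(self):
        with pytest.raises(KeyError):
            neighbor_enrichment(star_network(), GeneSet("s", frozenset()), "nope")

    @pytest.mark.parametrize("n_nodes,n_neighbors,n_sig", [(8, 3, 4), (12, 5, 3)])
    def test_matches_fisher_exact_and_enumeration(self, n_nodes, n_neighbors, n_sig):
        rng = np.random.default_rng(7)
        others = [f"v{i}" for i in range(n_nodes - 1)]
        neigh = others[:n_neighbors]
        net = make_network([("f", v) for v in neigh], nodes=others)
        sig_ids = set(rng.choice(others, size=n_sig, replace=False))
        rec = neighbor_enrichment(net, GeneSet("s", frozenset(sig_ids)), "f")
        k = len(set(neigh) & sig_ids)
        table = [
            [k, n_neighbors - k],
            [n_sig - k, (n_nodes - 1) - n_neighbors - (n_sig - k)],
        ]
        _, p_fisher = stats.fisher_exact(table, alternative="greater")
        assert np.isclose(rec.p_value, p_fisher, atol=1e-12)
        count = sum(
            1
            for subset in itertools.combinations(others, n_neighbors)
            if len(set(subset) & sig_ids) >= k
        )
        assert np.isclose(rec.p_value, count / math.comb(n_nodes - 1, n_neighbors), atol=1e-12)


class TestCACTable:
    def test_q_values_match_bh_oracle_and_toy_vector(self):
        # printed toy: BH of (0.01, 0.02, 0.03) is (0.03, 0.03, 0.03)
        assert np.allclose(bh_stepup([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(40, 0.15, seed=4)
        net = CoregNetwork(nx.relabel_nodes(g, {i: f"g{i}" for i in g}), m_samples=9)
        sig = GeneSet("s", frozenset(rng.choice([f"g{i}" for i in range(40)], 8, replace=False)))
        table = cac_table(net, sig)
        assert np.allclose(table["q_value"], bh_stepup(table["p_value"]), atol=1e-12)
        assert np.allclose(table["cac_score"], -np.log10(table["q_value"]), atol=1e-12)

    def test_empty_signature_zeroes_scores(self):
        table = cac_table(star_network(), GeneSet("s", frozenset()))
        assert (table["p_value"] == 1.0).all()
        assert (table["cac_score"] == 0.0).all()

    def test_ranks_unique_and_order_invariant(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")]
        net1 = make_network(edges)
        net2 = make_network(list(reversed(edges)))
        sig = GeneSet("s", frozenset({"b", "d"}))
        t1, t2 = cac_table(net1, sig), cac_table(net2, sig)
        assert sorted(t1["rank"]) == list(range(1, len(t1) + 1))
        assert t1.equals(t2)

    def test_degree_alone_does_not_drive_cac(self):
        # null signature: high-degree nodes must not outscore low-degree ones
        rng = np.random.default_rng(6)
        g = nx.barabasi_albert_graph(300, 3, seed=2)  # heavy-tailed degrees
        net = CoregNetwork(nx.relabel_nodes(g, {i: f"g{i}" for i in g}), m_samples=9)
        scores = []
        for rep in range(20):
            sig = GeneSet(
                "s", frozenset(rng.choice([f"g{i}" for i in range(300)], 30, replace=False))
            )
            table = cac_table(net, sig)
            deg_median = table["degree"].median()
            hi = table.loc[table["degree"] > deg_median, "cac_score"].mean()
            lo = table.loc[table["degree"] <= deg_median, "cac_score"].mean()
            scores.append(hi - lo)
        assert abs(np.mean(scores)) < 0.05

    def test_planted_hub_outranks_nonhub_median(self, small_config):
        import dataclasses

        from tregmark.coregnet import filter_expressed, pcc_edges, rms_normalize
        from tregmark.diffexp import ExpressionMatrix, normalize_counts
        from tregmark.synth import simulate_bulk

        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cfg = dataclasses.replace(small_config, seed=seed)
            mat, truth = simulate_bulk(cfg)
            log = normalize_counts(mat)
            cols = log.samples_of(["TBM-TI-Treg", "TBM-SP-Treg", "NM-SP-Treg"])
            treg = ExpressionMatrix(log.values[cols], log.sample_meta.loc[cols], "log-intensity")
            net = pcc_edges(
                rms_normalize(
                    filter_expressed(treg, GeneSet("neg", truth.negative_marker_ids))
                ),
                0.01,
            )
            table = cac_table(net, GeneSet("sig", truth.signature_ids))
            hubs = [h for h in truth.hub_ids if h in table.index]
            nonhub_median = table.loc[~table.index.isin(hubs), "rank"].median()
            wins += all(table.loc[h, "rank"] <= nonhub_median for h in hubs)
        assert wins >= 0.95 * n_seeds - 1


class TestTopFraction:
    def test_membership_flags(self):
        net = make_network([(f"g{i}", f"g{i+1}") for i in range(9)])
        table = cac_table(net, GeneSet("s", frozenset({"g0", "g1"})))
        best = table.index[table["rank"] == 1][0]
        worst = table.index[table["rank"] == len(table)][0]
        flags = top_fraction_membership(table, GeneSet("q", frozenset({best, worst})), 0.1)
        assert flags[best] is True and flags[worst] is False

    def test_fraction_one_includes_all(self):
        net = make_network([("a", "b"), ("b", "c")])
        table = cac_table(net, GeneSet("s", frozenset({"a"})))
        flags = top_fraction_membership(table, GeneSet("q", frozenset("abc")), 1.0)
        assert all(flags.values())

    def test_missing_gene_omitted_not_false(self):
        net = make_network([("a", "b")])
        table = cac_table(net, GeneSet("s", frozenset({"a"})))
        flags = top_fraction_membership(table, GeneSet("q", frozenset({"a", "zz"})), 1.0)
        assert "zz" not in flags
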