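"""Directional pairing, triplet combinatorics, network algebra and hubs."""

import numpy as np
import pandas as pd
import pytest

from cernapipe import cerna

from oracles import brute_force_bfs, brute_force_degrees


def pair_table(rows):
    return pd.DataFrame(rows, columns=["mirna", "transcript", "n_sites", "best_class", "best_score"])


def make_pair(mirna, mdir, transcript, kind, sites=1, comparison="c1"):
    return cerna.DirectionalPair(
        mirna=mirna,
        mirna_direction=mdir,
        transcript=transcript,
        kind=kind,
        transcript_direction={"up": "down", "down": "up"}[mdir],
        n_sites=sites,
        comparison=comparison,
    )


class TestFilterDirectionalPairs:
    def test_opposite_directions_with_sites_are_retained(self):
        pairs = cerna.filter_directional_pairs(
            {"mir1": "up"},
            {"g1": ("mRNA", "down")},
            pair_table([("mir1", "g1", 2, "8mer", 10.0)]),
        )
        assert len(pairs) == 1 and pairs[0].n_sites == 2

    def test_same_direction_pairs_are_dropped(self):
        pairs = cerna.filter_directional_pairs(
            {"mir1": "up"},
            {"g1": ("mRNA", "up")},
            pair_table([("mir1", "g1", 2, "8mer", 10.0)]),
        )
        assert pairs == []

    def test_non_de_transcripts_are_dropped(self):
        pairs = cerna.filter_directional_pairs(
            {"mir1": "up"}, {}, pair_table([("mir1", "g1", 2, "8mer", 10.0)])
        )
        assert pairs == []

    def test_direction_outside_up_down_is_an_error(self):
        with pytest.raises(ValueError, match="direction"):
            cerna.filter_directional_pairs(
                {"mir1": "none"}, {}, pair_table([])
            )

    def test_pair_invariants_enforced_on_construction(self):
        with pytest.raises(ValueError):
            make_pair("m", "up", "t", "mRNA", sites=0)
        with pytest.raises(ValueError):
            cerna.DirectionalPair("m", "up", "t", "mRNA", "up", 1)


class TestAssembleTriplets:
    def test_minimal_shared_mirna_gives_one_triplet(self):
        trip = cerna.assemble_triplets(
            [make_pair("m", "up", "lnc1", "lncRNA")],
            [make_pair("m", "up", "g1", "mRNA")],
        )
        assert [t.key() for t in trip] == [("lnc1", "m", "g1")]

    def test_partner_counts_multiply(self):
        lncs = [make_pair("m", "down", f"lnc{i}", "lncRNA") for i in range(3)]
        genes = [make_pair("m", "down", f"g{i}", "mRNA") for i in range(4)]
        trip = cerna.assemble_triplets(lncs, genes)
        assert len(trip) == 12
        # brute-force cross product
        want = {
            (l.transcript, "m", g.transcript) for l in lncs for g in genes
        }
        assert {t.key() for t in trip} == want

    def test_no_shared_mirna_gives_nothing(self):
        trip = cerna.assemble_triplets(
            [make_pair("m1", "up", "lnc1", "lncRNA")],
            [make_pair("m2", "up", "g1", "mRNA")],
        )
        assert trip == []

    def test_every_triplet_is_opposite_directional(self):
        rng = np.random.default_rng(0)
        direction_of = {f"m{i}": ("up" if i % 2 else "down") for i in range(5)}
        lncs, genes = [], []
        for i in range(20):
            mir = f"m{int(rng.integers(5))}"
            lncs.append(make_pair(mir, direction_of[mir], f"lnc{i}", "lncRNA"))
            mir = f"m{int(rng.integers(5))}"
            genes.append(make_pair(mir, direction_of[mir], f"g{i}", "mRNA"))
        for t in cerna.assemble_triplets(lncs, genes):
            assert t.partner_direction == {"up": "down", "down": "up"}[t.mirna_direction]

    def test_conflicting_mirna_directions_between_lists_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            cerna.assemble_triplets(
                [make_pair("m", "up", "lnc1", "lncRNA")],
                [make_pair("m", "down", "g1", "mRNA")],
            )


def star_triplets(n_leaves=5):
    lncs = [make_pair("m", "up", f"lnc{i}", "lncRNA") for i in range(n_leaves)]
    genes = [make_pair("m", "up", "g0", "mRNA")]
    return cerna.assemble_triplets(lncs, genes)


class TestBuildNetwork:
    def test_single_triplet_shape(self):
        net = cerna.build_network(
            [cerna.CernaTriplet("lnc1", "m", "g1", 2, 3, "up", "down")]
        )
        assert net.n_nodes == 3 and net.n_edges == 2
        deg = dict(zip(net.degree_table()["node"], net.degree_table()["degree"]))
        assert deg == {"m": 2, "lnc1": 1, "g1": 1}

    def test_shared_arm_is_one_edge(self):
        trips = [
            cerna.CernaTriplet("lnc1", "m", "g1", 1, 1, "up", "down"),
            cerna.CernaTriplet("lnc1", "m", "g2", 1, 1, "up", "down"),
            cerna.CernaTriplet("lnc2", "m", "g1", 1, 1, "up", "down"),
        ]
        net = cerna.build_network(trips)
        assert net.n_edges == 4  # lnc1-m, lnc2-m, m-g1, m-g2

    def test_conflicting_regulation_is_an_error(self):
        trips = [
            cerna.CernaTriplet("lnc1", "m", "g1", 1, 1, "up", "down"),
            cerna.CernaTriplet("lnc1", "m", "g1", 1, 1, "down", "up"),
        ]
        with pytest.raises(ValueError, match="regulation"):
            cerna.build_network(trips)

    def test_union_of_conflicting_comparisons_marks_regulation_none(self):
        a = cerna.build_network([cerna.CernaTriplet("lnc1", "m", "g1", 1, 1, "up", "down", "c1")])
        b = cerna.build_network([cerna.CernaTriplet("lnc1", "m", "g2", 1, 1, "down", "up", "c2")])
        union = cerna.union_networks([a, b])
        assert union.graph.nodes["m"]["regulation"] == "none"
        assert union.graph.nodes["lnc1"]["regulation"] == "none"
        assert union.graph.nodes["g1"]["regulation"] == "down"

    def test_degree_table_matches_incidence_counting(self):
        rng = np.random.default_rng(4)
        trips = [
            cerna.CernaTriplet(
                f"lnc{int(rng.integers(8))}",
                f"m{int(rng.integers(5))}",
                f"g{int(rng.integers(12))}",
                1,
                1,
                "up",
                "down",
            )
            for _ in range(60)
        ]
        net = cerna.build_network(trips)
        edges = [(u, v) for u, v in net.graph.edges]
        want = brute_force_degrees(edges)
        got = dict(zip(net.degree_table()["node"], net.degree_table()["degree"]))
        assert got == want
        assert sum(got.values()) == 2 * net.n_edges

    def test_layered_bipartite_structure_is_enforced(self):
        import networkx as nx

        g = nx.Graph()
        g.add_node("lnc1", kind="lncRNA", regulation="up")
        g.add_node("g1", kind="mRNA", regulation="down")
        g.add_edge("lnc1", "g1")
        with pytest.raises(ValueError, match="illegal"):
            cerna.CernaNetwork(g)


class TestRankHubs:
    def test_star_center_ranks_first(self):
        net = cerna.build_network(star_triplets(5))
        assert cerna.rank_hubs(net, k=1) == ["m"]

    def test_degree_ties_break_lexicographically(self):
        net = cerna.build_network(
            [cerna.CernaTriplet("lnc1", "m", "g1", 1, 1, "up", "down")]
        )
        assert cerna.rank_hubs(net, k=3) == ["m", "g1", "lnc1"]

    def test_matches_full_sort_on_random_networks(self):
        rng = np.random.default_rng(5)
        trips = [
            cerna.CernaTriplet(
                f"lnc{int(rng.integers(10))}",
                f"m{int(rng.integers(6))}",
                f"g{int(rng.integers(15))}",
                1,
                1,
                "down",
                "up",
            )
            for _ in range(80)
        ]
        net = cerna.build_network(trips)
        deg = brute_force_degrees([(u, v) for u, v in net.graph.edges])
        want = sorted(deg, key=lambda n: (-deg[n], n))
        assert cerna.rank_hubs(net, k=10) == want[:10]
        assert cerna.rank_hubs(net, k=10_000) == want  # k > |nodes| returns all

    def test_k_below_one_is_an_error(self):
        with pytest.raises(ValueError):
            cerna.rank_hubs(cerna.build_network(star_triplets()), k=0)


class TestExtractSubnet:
    def test_radius_one_around_a_mirna_returns_its_partners(self):
        net = cerna.build_network(star_triplets(4))
        sub = cerna.extract_subnet(net, ["m"], radius=1)
        assert set(sub.graph.nodes) == {"m", "g0", "lnc0", "lnc1", "lnc2", "lnc3"}

    def test_radius_zero_is_the_induced_seed_subgraph(self):
        net = cerna.build_network(star_triplets(3))
        sub = cerna.extract_subnet(net, ["m", "g0"], radius=0)
        assert set(sub.graph.nodes) == {"m", "g0"}
        assert sub.n_edges == 1  # the m-g0 edge is induced

    def test_membership_matches_bfs_oracle(self):
        rng = np.random.default_rng(6)
        trips = [
            cerna.CernaTriplet(
                f"lnc{int(rng.integers(10))}",
                f"m{int(rng.integers(6))}",
                f"g{int(rng.integers(15))}",
                1,
                1,
                "up",
                "down",
            )
            for _ in range(60)
        ]
        net = cerna.build_network(trips)
        edges = [(u, v) for u, v in net.graph.edges]
        for radius in (0, 1, 2, 3):
            sub = cerna.extract_subnet(net, ["m0"], radius=radius)
            assert set(sub.graph.nodes) == brute_force_bfs(edges, {"m0"}, radius)

    def test_unknown_seed_is_an_error(self):
        net = cerna.build_network(star_triplets())
        with pytest.raises(ValueError, match="ghost"):
            cerna.extract_subnet(net, ["ghost"])
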