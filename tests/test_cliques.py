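"""Top-K network construction and the four-rule clique separation."""

import numpy as np
import pandas as pd
import pytest

from coexcliques import (
    CliqueSet,
    build_rank_db,
    build_topk_network,
    connection_stats,
    eval_clique_rankings,
    name_cliques,
    scramble_cliques,
    separate_cliques,
)
from coexcliques.cliques import CoexprNetwork, _sorted_edges
from coexcliques.synthetic import SyntheticSpec, make_expression

from conftest import db_from_rankings

import networkx as nx


def db_from_corr(names, corr):
    """Rank database straight from a symmetric correlation matrix."""
    corr = np.asarray(corr, dtype=float)
    np.fill_diagonal(corr, np.nan)
    rankings = {}
    for i, g in enumerate(names):
        scored = sorted(
            ((-corr[i, j], names[j]) for j in range(len(names)) if j != i)
        )
        rankings[g] = [h for _, h in scored]
    return db_from_rankings(rankings, corr=corr)


def network_from_edges(edge_strengths, genes=None):
    """Hand-built network: explicit undirected edges with strengths."""
    graph = nx.Graph()
    if genes:
        graph.add_nodes_from(genes)
    top = {}
    for (u, v), s in edge_strengths.items():
        graph.add_edge(u, v, strength=s, multiplicity=1)
        top.setdefault(u, []).append(v)
        top.setdefault(v, []).append(u)
    return CoexprNetwork(top={g: tuple(v) for g, v in top.items()}, graph=graph, k=0)


class TestBuildTopkNetwork:
    def setup_method(self):
        self.names = ["A", "B", "C", "D"]
        r = np.array(
            [
                [np.nan, 0.9, 0.8, 0.1],
                [0.9, np.nan, 0.7, 0.2],
                [0.8, 0.7, np.nan, 0.3],
                [0.1, 0.2, 0.3, np.nan],
            ]
        )
        self.db = db_from_corr(self.names, r)

    def test_top1_network_matches_hand_derivation(self):
        net = build_topk_network(self.db, k=1)
        assert net.top == {"A": ("B",), "B": ("A",), "C": ("A",), "D": ("C",)}
        edges = {tuple(sorted(e)): d for *e, d in net.graph.edges(data=True)}
        assert set(edges) == {("A", "B"), ("A", "C"), ("C", "D")}
        assert edges[("A", "B")]["multiplicity"] == 2
        assert edges[("A", "C")]["multiplicity"] == 1
        assert edges[("A", "B")]["strength"] == pytest.approx(0.9)

    def test_full_k_gives_complete_graph(self):
        net = build_topk_network(self.db, k=3)
        assert net.n_unique == 6
        assert all(len(v) == 3 for v in net.top.values())

    def test_out_degree_is_always_k(self):
        for k in (1, 2, 3):
            net = build_topk_network(self.db, k=k)
            assert {len(v) for v in net.top.values()} == {k}
            assert net.n_unique <= net.n_directed <= 2 * net.n_unique

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            build_topk_network(self.db, k=4)

    def test_connection_stats_arithmetic(self):
        stats = connection_stats(4, 4, 3)
        assert stats["possible_connections"] == 6
        assert stats["average_edge_count"] == pytest.approx(4 / 3)


class TestSeparateCliques:
    def test_hand_traced_four_rule_example(self):
        """Hand trace at T=2: rules 1/1/3/1/1/3/4/2 in edge order."""
        strengths = {
            ("A", "B"): 0.9, ("C", "D"): 0.85, ("A", "C"): 0.8,
            ("E", "F"): 0.75, ("G", "H"): 0.7, ("E", "G"): 0.65,
            ("A", "E"): 0.6, ("A", "I"): 0.55,
        }
        net = network_from_edges(strengths)
        cs = separate_cliques(net, t=2)
        assert sorted(map(set, cs.values()), key=len) == [
            {"E", "F", "G", "H"},
            {"A", "B", "C", "D", "I"},
        ]

    def test_single_edge_network(self):
        net = network_from_edges({("X", "Y"): 0.5})
        cs = separate_cliques(net, t=5)
        assert list(map(set, cs.values())) == [{"X", "Y"}]

    def test_partition_is_disjoint_and_exhaustive(self):
        spec = SyntheticSpec(module_sizes=(8, 8, 8), n_background_genes=16,
                             n_samples=30, seed=3)
        mat, _ = make_expression(spec)
        net = build_topk_network(build_rank_db(mat), k=6)
        cs = separate_cliques(net, t=5)
        genes = [g for c in cs.values() for g in c]
        assert len(genes) == len(set(genes)) == mat.shape[0]

    @pytest.mark.parametrize("seed", range(6))
    def test_minimum_clique_size_guarantee(self, seed):
        """K >= T+1 forces every final clique above the protection size."""
        rng = np.random.default_rng(seed)
        mat = pd.DataFrame(
            rng.normal(size=(80, 15)), index=[f"g{i:02d}" for i in range(80)]
        )
        net = build_topk_network(build_rank_db(mat), k=10)
        cs = separate_cliques(net, t=5)
        assert min(cs.sizes.values()) >= 6

    def test_determinism_under_gene_reordering(self):
        spec = SyntheticSpec(module_sizes=(10, 10), n_background_genes=10,
                             n_samples=25, seed=9)
        mat, _ = make_expression(spec)
        shuffled = mat.sample(frac=1.0, random_state=4)
        make = lambda m: name_cliques(
            separate_cliques(build_topk_network(build_rank_db(m), k=6), t=5),
            build_topk_network(build_rank_db(m), k=6),
        )
        assert make(mat) == make(shuffled)


class TestNameCliques:
    def test_two_best_connected_genes(self):
        strengths = {
            ("A", "B"): 0.9, ("C", "D"): 0.8, ("A", "C"): 0.7, ("A", "I"): 0.6,
        }
        net = network_from_edges(strengths)
        cs = CliqueSet({"c1": frozenset("ABCDI")})
        named = name_cliques(cs, net)
        # degrees: A=3, C=2, B=D=I=1
        assert list(named) == ["A-C"]

    def test_lexicographic_ties(self):
        net = network_from_edges({("X", "Y"): 0.5})
        assert list(name_cliques(CliqueSet({"c": frozenset("XY")}), net)) == ["X-Y"]
        cycle = network_from_edges(
            {("P", "Q"): 0.9, ("Q", "R"): 0.8, ("P", "R"): 0.7}
        )
        assert list(name_cliques(CliqueSet({"c": frozenset("PQR")}), cycle)) == ["P-Q"]


class TestEvalCliqueRankings:
    def test_hand_enumerated_example(self):
        db = db_from_rankings(
            {"A": list("BCD"), "B": list("ACD"), "C": list("ABD"), "D": list("CAB")}
        )
        cs = CliqueSet({"c1": frozenset("AB"), "c2": frozenset("CD")})
        out = eval_clique_rankings(cs, db)
        intra, inter = out["c1"]
        assert intra == pytest.approx(1.0)
        assert inter == pytest.approx(2.5)  # ranks 2,3 (A->C,D) and 2,3 (B->C,D)

    def test_single_clique_has_no_inter_value(self):
        db = db_from_rankings({"A": ["B"], "B": ["A"]})
        out = eval_clique_rankings(CliqueSet({"c": frozenset("AB")}), db)
        assert out["c"][1] is None

    def test_random_rankings_have_no_intra_inter_gap(self):
        """With exchangeable rankings both means are ~(N)/2 in expectation."""
        rng = np.random.default_rng(5)
        n = 40
        genes = [f"g{i:02d}" for i in range(n)]
        gaps = []
        for _ in range(30):
            rankings = {
                g: [genes[j] for j in rng.permutation([i for i in range(n) if genes[i] != g])]
                for g in genes
            }
            db = db_from_rankings(rankings)
            cs = CliqueSet(
                {"a": frozenset(genes[:20]), "b": frozenset(genes[20:])}
            )
            out = eval_clique_rankings(cs, db)
            gaps.append(out["a"][0] - out["a"][1])
        assert abs(np.mean(gaps)) < 1.0  # centred on zero, mean rank is n/2


class TestScrambleCliques:
    def test_sizes_and_universe_preserved(self, two_cliques):
        sc = scramble_cliques(two_cliques, seed=1)
        assert sorted(sc.sizes.values()) == sorted(two_cliques.sizes.values())
        assert sc.genes == two_cliques.genes

    def test_different_seeds_differ(self):
        cs = CliqueSet(
            {"a": frozenset(f"g{i}" for i in range(10)),
             "b": frozenset(f"h{i}" for i in range(10))}
        )
        partitions = {
            tuple(sorted(map(tuple, map(sorted, scramble_cliques(cs, s).values()))))
            for s in range(5)
        }
        assert len(partitions) > 1

    def test_seeded_repeatability(self, two_cliques):
        assert scramble_cliques(two_cliques, 7) == scramble_cliques(two_cliques, 7)


class TestCliqueSetInvariants:
    def test_overlapping_cliques_rejected(self):
        with pytest.raises(ValueError, match="more than one"):
            CliqueSet({"a": frozenset("AB"), "b": frozenset("BC")})

    def test_empty_clique_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CliqueSet({"a": frozenset()})

    def test_sorted_edges_strongest_first(self):
        net = network_from_edges(
            {("B", "C"): 0.5, ("A", "B"): 0.9, ("A", "C"): 0.9}
        )
        assert [(u, v) for u, v, _ in _sorted_edges(net)] == [
            ("A", "B"), ("A", "C"), ("B", "C"),
        ]
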