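import itertools

import networkx as nx
import numpy as np
import pytest

from paleoweb import (
    chain_trophic_levels,
    count_motifs,
    structural_metrics,
    triad_census,
    trophic_levels,
)
from paleoweb.metrics import MotifCounts

from _oracles import (
    fixed_point_trophic_levels,
    naive_metrics,
)
from conftest import make_web, random_digraph


class TestTrophicLevels:
    def test_chain_levels(self, chain_web):
        tl = trophic_levels(chain_web)
        assert tl["producer"] == 1
        assert tl["A"] == 2 and tl["B"] == 3 and tl["C"] == 4

    def test_prey_averaged_closed_form(self):
        # B eats producer and A; A eats producer -> TL_B = 1 + (1+2)/2 = 2.5
        web = make_web(
            ["A", "B"],
            [("producer", "A"), ("producer", "B"), ("A", "B")],
        )
        tl = trophic_levels(web)
        assert tl["A"] == pytest.approx(2.0)
        assert tl["B"] == pytest.approx(2.5)

    def test_preyless_consumer_is_nan_with_warning(self):
        web = make_web(["A", "B"], [("producer", "A"), ("A", "B")])
        web.graph.add_node("loner", traits=None, members=[])
        with pytest.warns(UserWarning, match="loner"):
            tl = trophic_levels(web)
        assert np.isnan(tl["loner"])
        assert tl["B"] == 3

    @pytest.mark.parametrize("seed", range(6))
    def test_solution_matches_fixed_point_oracle(self, seed):
        # random acyclic web: edges only from lower to higher node index,
        # every node anchored to the producer so all levels are defined
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 15))
        names = [f"n{i}" for i in range(n)]
        edges = [("producer", names[0])]
        for j in range(1, n):
            prey = [names[i] for i in range(j) if rng.random() < 0.4]
            if not prey or rng.random() < 0.3:
                prey.append("producer")
            edges.extend((p, names[j]) for p in prey)
        web = make_web(names, edges)
        assert nx.is_directed_acyclic_graph(web.graph)
        tl = trophic_levels(web)
        oracle = fixed_point_trophic_levels(
            web.edges(), web.nodes(), "producer"
        )
        for node in web.nodes():
            assert tl[node] == pytest.approx(oracle[node], abs=1e-9)

    def test_chain_levels_longest_path(self):
        web = make_web(
            ["A", "B"],
            [("producer", "A"), ("producer", "B"), ("A", "B")],
        )
        ctl = chain_trophic_levels(web)
        assert ctl["B"] == 3  # longest chain producer -> A -> B


class TestStructuralMetrics:
    def test_connectance_formula(self):
        web = make_web(["A", "B"], [("producer", "A"), ("A", "B")])
        m = structural_metrics(web)
        assert m.connectance == pytest.approx(2 / 9)
        assert m.richness == 2 and m.richness_incl_producer == 3

    def test_alternative_connectance_denominator(self):
        web = make_web(["A", "B"], [("producer", "A"), ("A", "B")])
        m = structural_metrics(web, connectance_denominator="S(S-1)")
        assert m.connectance == pytest.approx(2 / 6)

    def test_uniform_generality_has_zero_sd(self):
        web = make_web(
            ["A", "B", "C"],
            [
                ("producer", "A"), ("producer", "B"),
                ("A", "C"), ("B", "C"),
                ("producer", "C"),
            ],
        )
        # consumers A, B have 1 prey; C has 3 -> not uniform; rebuild uniform:
        web = make_web(
            ["A", "B", "C", "D"],
            [
                ("producer", "A"), ("B", "A"),
                ("producer", "B"), ("C", "B"),
                ("producer", "C"), ("D", "C"),
                ("producer", "D"), ("A", "D"),
            ],
        )
        m = structural_metrics(web)
        assert m.generality == 2 and m.sd_generality == 0

    def test_generality_times_consumers_equals_links(self, random_feasible_web):
        web = random_feasible_web(3, richness=15)
        m = structural_metrics(web)
        n_consumers = sum(
            1 for n in web.nodes() if web.graph.in_degree(n) > 0
        )
        assert m.generality * n_consumers == pytest.approx(m.links)

    @pytest.mark.parametrize("seed", range(5))
    def test_fields_match_naive_recomputation(self, seed, random_feasible_web):
        web = random_feasible_web(seed, richness=13)
        m = structural_metrics(web)
        oracle = naive_metrics(web.edges(), web.nodes(), "producer")
        for key, val in oracle.items():
            assert getattr(m, key) == pytest.approx(val), key

    def test_empty_web_raises(self):
        from paleoweb import FoodWeb

        g = nx.DiGraph()
        with pytest.raises(ValueError):
            FoodWeb(g)  # no producer at all

    def test_invariant_max_tl_ge_mean_tl_ge_one(self, random_feasible_web):
        m = structural_metrics(random_feasible_web(9, richness=18))
        assert m.max_tl >= m.mean_tl >= 1


class TestMotifs:
    def test_chain_of_three_is_single_s1(self):
        web = make_web(["A", "B"], [("producer", "A"), ("A", "B")])
        assert count_motifs(web).as_dict() == {"S1": 1, "S2": 0, "S4": 0, "S5": 0}

    def test_fork_is_single_s5(self):
        web = make_web(
            ["A", "B"], [("producer", "A"), ("producer", "B")]
        )
        assert count_motifs(web).as_dict() == {"S1": 0, "S2": 0, "S4": 0, "S5": 1}

    def test_shared_predator_is_s4(self):
        web = make_web(["A", "B", "C"], [("A", "C"), ("B", "C")])
        assert count_motifs(web, include_producer=False).as_dict() == {
            "S1": 0, "S2": 0, "S4": 1, "S5": 0,
        }

    def test_omnivory_triangle_is_s2(self):
        web = make_web(["A", "B", "C"], [("A", "B"), ("B", "C"), ("A", "C")])
        assert count_motifs(web, include_producer=False).as_dict() == {
            "S1": 0, "S2": 1, "S4": 0, "S5": 0,
        }

    @pytest.mark.parametrize("seed", range(10))
    def test_random_digraphs_match_networkx_triadic_census(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 25))
        g = random_digraph(rng, n, p=float(rng.uniform(0.05, 0.3)))
        census = triad_census(g)
        nxc = nx.triadic_census(g)
        assert census.get("S1", 0) == nxc["021C"]
        assert census.get("S2", 0) == nxc["030T"]
        assert census.get("S4", 0) == nxc["021U"]
        assert census.get("S5", 0) == nxc["021D"]
        connected_types = [
            t for t in nxc if t not in ("003", "012", "102")
        ]
        assert sum(census.values()) == sum(nxc[t] for t in connected_types)

    def test_census_conservation_all_13_classes(self):
        rng = np.random.default_rng(42)
        g = random_digraph(rng, 20, 0.25)
        census = triad_census(g)
        n_connected = 0
        for triple in itertools.combinations(g.nodes, 3):
            sub = g.subgraph(triple)
            if sub.number_of_edges() and nx.is_connected(sub.to_undirected()):
                n_connected += 1
        assert sum(census.values()) == n_connected

    def test_adding_edge_never_decreases_connected_triples(self):
        rng = np.random.default_rng(7)
        g = random_digraph(rng, 12, 0.15)
        before = sum(triad_census(g).values())
        non_edges = [
            (u, v)
            for u in g
            for v in g
            if u != v and not g.has_edge(u, v)
        ]
        u, v = non_edges[int(rng.integers(len(non_edges)))]
        g.add_edge(u, v)
        assert sum(triad_census(g).values()) >= before

    def test_relabelling_invariance(self, random_feasible_web):
        web = random_feasible_web(2, richness=12)
        g = web.graph
        mapping = {n: f"node_{i}" for i, n in enumerate(sorted(g.nodes))}
        relabelled = nx.relabel_nodes(g, mapping)
        assert triad_census(g) == triad_census(relabelled)

    def test_frequencies_sum_over_named_motifs(self):
        mc = MotifCounts(s1=2, s2=1, s4=3, s5=4, n_connected_triads=20)
        freqs = mc.frequencies
        assert freqs["S4"] == pytest.approx(0.15)
        assert sum(freqs.values()) <= 1.0
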