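"""Cross-talk counting, constrained rewiring, and module-network inference."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats as sps

from modessence.catalog import Module, ModuleSet
from modessence.crosstalk import (
    count_crosstalk,
    filter_functionally_related,
    has_independent_pair,
    infer_crosstalk_network,
    intermodular_edges,
    odds_score,
    stub_rewire_intermodular,
)
from modessence.ontology import AnnotationSet, Ontology, propagate_annotations

from conftest import ess_map, make_net


class TestCountCrosstalk:
    def test_enumeration(self):
        m1 = Module("M1", frozenset({"a", "b"}))
        m2 = Module("M2", frozenset({"c", "d"}))
        net = make_net(("a", "c"), ("b", "d"), ("a", "d"))
        assert count_crosstalk(net, m1, m2) == 3

    def test_shared_protein_edges_excluded(self):
        m1 = Module("M1", frozenset({"x", "a"}))
        m2 = Module("M2", frozenset({"x", "c"}))
        net = make_net(("x", "c"), ("a", "c"))
        # (x, c): x is in both modules -> intramodular, excluded
        assert count_crosstalk(net, m1, m2) == 1

    def test_disjoint_no_edges_zero(self):
        m1 = Module("M1", frozenset({"a"}))
        m2 = Module("M2", frozenset({"b"}))
        assert count_crosstalk(make_net(("a", "z")), m1, m2) == 0


class TestIndependentPair:
    def test_disjoint_pair_true(self):
        assert has_independent_pair([("a", "c"), ("b", "d")])

    def test_shared_endpoint_false(self):
        assert not has_independent_pair([("a", "c"), ("a", "d")])

    def test_star_false_until_disjoint_edge_added(self):
        star = [("h", f"x{i}") for i in range(5)]
        assert not has_independent_pair(star)
        assert has_independent_pair(star + [("y", "z")])

    def test_matches_maximum_matching_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(2)
        for _ in range(50):
            nodes = [f"n{i}" for i in range(8)]
            edges = []
            for _ in range(rng.integers(1, 8)):
                u, v = rng.choice(8, 2, replace=False)
                edges.append((nodes[u], nodes[v]))
            g = nx.Graph(edges)
            want = len(nx.max_weight_matching(g)) >= 2
            assert has_independent_pair(edges) == want


class TestOddsScore:
    @pytest.mark.parametrize(
        "n_real,mean,expected", [(3, 3.0, 1.0), (9, 1.5, 4.0), (0, 4.0, 0.2)]
    )
    def test_values(self, n_real, mean, expected):
        assert odds_score(n_real, mean) == pytest.approx(expected)

    def test_monotonicity(self):
        assert odds_score(5, 1.0) > odds_score(4, 1.0)
        assert odds_score(5, 1.0) > odds_score(5, 2.0)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            odds_score(1, -0.1)


def two_module_fixture():
    """A = {a1..a3}, B = {b1..b3}, 4 intermodular edges with unequal degrees."""
    edges = [("a1", "b1"), ("a1", "b2"), ("a2", "b1"), ("a3", "b3")]
    net = make_net(*edges)
    modules = ModuleSet(
        [
            Module("A", frozenset({"a1", "a2", "a3"})),
            Module("B", frozenset({"b1", "b2", "b3"})),
        ]
    )
    return net, modules, edges


def enumerate_valid_states(edges):
    """All simple bipartite A-B edge sets with the same degree sequence."""
    a_nodes = sorted({u for u, _ in edges})
    b_nodes = sorted({v for _, v in edges})
    deg = Counter()
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    all_pairs = [(a, b) for a in a_nodes for b in b_nodes]
    states = []
    for combo in itertools.combinations(all_pairs, len(edges)):
        d = Counter()
        for u, v in combo:
            d[u] += 1
            d[v] += 1
        if d == deg:
            states.append(frozenset(frozenset(e) for e in combo))
    return states


class TestStubRewiring:
    def test_invariants_every_round(self, default_study):
        s = default_study
        base = intermodular_edges(s.interactome, s.modules)
        base_deg = Counter(itertools.chain.from_iterable(base))
        mem = s.modules.membership()
        for edges in stub_rewire_intermodular(
            s.interactome, s.modules, n_rounds=3, seed=0
        ):
            assert len(edges) == len(base)  # edge count preserved
            deg = Counter(itertools.chain.from_iterable(edges))
            assert deg == base_deg  # per-protein intermodular degree preserved
            assert len({frozenset(e) for e in edges}) == len(edges)  # simple
            for u, v in edges:
                assert u != v
                assert not (mem[u] & mem[v])  # zero intramodular edges

    def test_two_edge_case_yields_valid_pairing(self):
        net = make_net(("a1", "b1"), ("a2", "b2"))
        modules = ModuleSet(
            [Module("A", frozenset({"a1", "a2"})), Module("B", frozenset({"b1", "b2"}))]
        )
        valid = [
            {frozenset({"a1", "b1"}), frozenset({"a2", "b2"})},
            {frozenset({"a1", "b2"}), frozenset({"a2", "b1"})},
        ]
        seen = set()
        for i, edges in enumerate(
            stub_rewire_intermodular(net, modules, n_rounds=50, seed=4)
        ):
            state = {frozenset(e) for e in edges}
            assert state in valid
            seen.add(frozenset(state))
        assert len(seen) == 2  # both pairings reachable

    def test_sampler_approximately_uniform_on_toy(self):
        """Chi-square goodness of fit against the enumerated state space of
        a 4-edge toy instance, over 10,000 rewiring rounds."""
        net, modules, edges = two_module_fixture()
        states = enumerate_valid_states(edges)
        assert len(states) > 1
        index = {s: i for i, s in enumerate(states)}
        counts = np.zeros(len(states))
        for out in stub_rewire_intermodular(net, modules, n_rounds=10_000, seed=12):
            state = frozenset(frozenset(e) for e in out)
            counts[index[state]] += 1
        chi2 = sps.chisquare(counts)
        assert chi2.pvalue > 0.01

    def test_no_intermodular_edges_is_an_error(self):
        net = make_net(("a1", "a2"))
        modules = ModuleSet([Module("A", frozenset({"a1", "a2"}))])
        with pytest.raises(ValueError):
            next(stub_rewire_intermodular(net, modules))


class TestInference:
    def planted_fixture(self):
        """Twelve modules; A-B densely connected over a sparse random background.

        The background spreads intermodular stubs over many module pairs so
        degree-preserving rewiring can disperse the A-B edges.
        """
        rng = np.random.default_rng(6)
        names = [chr(ord("A") + i) for i in range(12)]
        members = {k: [f"{k.lower()}{i}" for i in range(8)] for k in names}
        edges = set()
        # enriched pair A-B: 20 edges
        pairs = [(u, v) for u in members["A"] for v in members["B"]]
        for i in rng.choice(len(pairs), 20, replace=False):
            edges.add(pairs[i])
        # sparse background between every other module pair
        for k1, k2 in itertools.combinations(names, 2):
            if {k1, k2} == {"A", "B"}:
                continue
            cross = [(u, v) for u in members[k1] for v in members[k2]]
            for i in rng.choice(len(cross), 2, replace=False):
                edges.add(cross[i])
        net = make_net(*sorted(edges))
        modules = ModuleSet(Module(k, frozenset(v)) for k, v in members.items())
        ess = ess_map(set(itertools.chain(*members.values())), {"a0", "b0"})
        return net, modules, ess

    def test_planted_pair_accepted_background_rejected(self):
        net, modules, ess = self.planted_fixture()
        mn = infer_crosstalk_network(net, modules, ess, odds_threshold=2.0, seed=9)
        accepted = {tuple(sorted((pc.m1, pc.m2))) for pc in mn.accepted}
        assert ("A", "B") in accepted
        assert ("C", "D") not in accepted

    def test_hub_only_support_rejected_by_independence_rule(self):
        # 3 edges all through hub a0: never two vertex-disjoint edges
        edges = [("a0", "b0"), ("a0", "b1"), ("a0", "b2"), ("x0", "y0")]
        modules = ModuleSet(
            [
                Module("A", frozenset({"a0", "a1"})),
                Module("B", frozenset({"b0", "b1", "b2"})),
                Module("X", frozenset({"x0"})),
                Module("Y", frozenset({"y0"})),
            ]
        )
        net = make_net(*edges)
        ess = ess_map({"a0", "a1", "b0", "b1", "b2", "x0", "y0"}, set())
        mn = infer_crosstalk_network(net, modules, ess, odds_threshold=0.0, seed=1)
        accepted = {tuple(sorted((pc.m1, pc.m2))) for pc in mn.accepted}
        assert ("A", "B") not in accepted

    def test_raising_threshold_never_adds_edges(self):
        net, modules, ess = self.planted_fixture()
        prev = None
        for thr in (1.0, 2.0, 4.0, 8.0):
            mn = infer_crosstalk_network(net, modules, ess, odds_threshold=thr, seed=9)
            accepted = {tuple(sorted((pc.m1, pc.m2))) for pc in mn.accepted}
            if prev is not None:
                assert accepted <= prev
            prev = accepted

    def test_node_annotations(self):
        net, modules, ess = self.planted_fixture()
        mn = infer_crosstalk_network(net, modules, ess, odds_threshold=2.0, seed=9)
        table = mn.node_table()
        assert table.loc["A", "binary_essential"] == 1
        assert table.loc["C", "binary_essential"] == 0
        assert table.loc["A", "fraction_essential"] == pytest.approx(1 / 8)
        a_deg = mn.crosstalk_degree("A")
        assert table.loc["A", "normalized_crosstalk_degree"] == pytest.approx(a_deg / 8)


class TestSlimFilter:
    def make_network(self):
        net, modules, ess = TestInference().planted_fixture()
        return infer_crosstalk_network(net, modules, ess, odds_threshold=2.0, seed=9)

    def slim_annotation(self, modules, terms_for):
        ontology = Ontology(
            {"T:ROOT": set(), "T:S1": {"T:ROOT"}, "T:S2": {"T:ROOT"}}
        )
        direct = {}
        for mid, term in terms_for.items():
            for p in modules.by_id[mid].members:
                direct.setdefault(p, set()).add(term)
        ann = propagate_annotations(
            AnnotationSet(direct=direct, proteome_size=64), ontology
        )
        return ann

    def test_shared_slim_term_removes_edge(self):
        mn = self.make_network()
        ann = self.slim_annotation(mn.modules, {"A": "T:S1", "B": "T:S1"})
        filtered = filter_functionally_related(mn, {"T:S1"}, ann)
        assert ("A", "B") not in {
            tuple(sorted((pc.m1, pc.m2))) for pc in filtered.accepted
        }

    def test_distinct_slim_terms_keep_edge(self):
        mn = self.make_network()
        ann = self.slim_annotation(mn.modules, {"A": "T:S1", "B": "T:S2"})
        filtered = filter_functionally_related(mn, {"T:S1", "T:S2"}, ann)
        assert ("A", "B") in {
            tuple(sorted((pc.m1, pc.m2))) for pc in filtered.accepted
        }

    def test_annotation_fraction_threshold(self):
        mn = self.make_network()
        # annotate only 3 of 8 members of A -> below the 0.5 fraction
        ontology = Ontology({"T:ROOT": set(), "T:S1": {"T:ROOT"}})
        direct = {p: {"T:S1"} for p in sorted(mn.modules.by_id["A"].members)[:3]}
        direct.update({p: {"T:S1"} for p in mn.modules.by_id["B"].members})
        ann = propagate_annotations(
            AnnotationSet(direct=direct, proteome_size=64), ontology
        )
        filtered = filter_functionally_related(mn, {"T:S1"}, ann, annotation_fraction=0.5)
        assert ("A", "B") in {
            tuple(sorted((pc.m1, pc.m2))) for pc in filtered.accepted
        }

    def test_broad_terms_ignored(self):
        mn = self.make_network()
        ann = self.slim_annotation(mn.modules, {"A": "T:S1", "B": "T:S1"})
        filtered = filter_functionally_related(mn, {"T:S1"}, ann, max_annotated=10)
        # T:S1 annotates 16 proteins > 10 -> ignored, edge kept
        assert ("A", "B") in {
            tuple(sorted((pc.m1, pc.m2))) for pc in filtered.accepted
        }
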