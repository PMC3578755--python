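"""Lin similarity against brute-force oracles, and the weighted degree."""

import itertools
import math

import numpy as np
import pytest

from modessence.ontology import AnnotationSet, propagate_annotations, term_probability
from modessence.semsim import (
    lin_term_similarity,
    protein_semantic_similarity,
    semsim_weighted_degree,
)

from conftest import make_net


# ---------------------------------------------------------------------------
# independent oracles: explicit search over all common ancestors / terms
# ---------------------------------------------------------------------------

def brute_ancestors_and_self(ontology, term):
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for parent in ontology.parents[t]:
            if parent not in out:
                out.add(parent)
                frontier.append(parent)
    return out


def brute_tss(t1, t2, ann, ontology):
    p1 = ann.term_count.get(t1, 0) / ann.proteome_size
    p2 = ann.term_count.get(t2, 0) / ann.proteome_size
    if t1 == t2:
        return 1.0
    common = brute_ancestors_and_self(ontology, t1) & brute_ancestors_and_self(ontology, t2)
    if not common:
        return 0.0
    pa = min(ann.term_count.get(a, 0) / ann.proteome_size for a in common)
    best = {a for a in common if ann.term_count.get(a, 0) / ann.proteome_size == pa}
    if best <= ontology.roots or pa >= 1.0:
        return 0.0  # most informative common ancestor is a root
    return max(0.0, min(1.0, 2 * math.log(pa) / (math.log(p1) + math.log(p2))))


def brute_pss(p1, p2, ann, ontology):
    s1, s2 = ann.propagated[p1], ann.propagated[p2]
    prob = lambda t: ann.term_count.get(t, 0) / ann.proteome_size
    shared = s1 & s2
    if not shared:
        return 0.0
    ps = min(prob(t) for t in shared)
    best = {t for t in shared if prob(t) == ps}
    if best <= ontology.roots or ps >= 1.0:
        return 0.0
    pm1 = min(prob(t) for t in s1)
    pm2 = min(prob(t) for t in s2)
    return max(0.0, min(1.0, 2 * math.log(ps) / (math.log(pm1) + math.log(pm2))))


class TestLinBoundaryContract:
    def test_identical_nonroot_terms_exactly_one(self, chain_ontology):
        ann = propagate_annotations(
            AnnotationSet(direct={"P1": {"T:LEAF"}, "P2": {"T:MID"}}), chain_ontology
        )
        assert lin_term_similarity("T:LEAF", "T:LEAF", ann, chain_ontology) == 1.0

    def test_root_only_common_ancestor_exactly_zero(self, diamond_ontology):
        # annotate disjoint branches so T:A and T:B only share the root
        ann = propagate_annotations(
            AnnotationSet(direct={"P1": {"T:A"}, "P2": {"T:B"}}), diamond_ontology
        )
        assert lin_term_similarity("T:A", "T:B", ann, diamond_ontology) == 0.0

    def test_hand_arithmetic_example(self, diamond_ontology):
        # force p(T:A)=0.05, p(T:B)=0.04, p(root)=... build custom counts
        ann = AnnotationSet(
            direct={},
            propagated={},
            term_count={"T:ROOT": 100, "T:A": 20, "T:B": 4, "T:LEAF": 5},
            proteome_size=100,
        )
        # T:LEAF vs T:B share ancestor set {T:B(0.04)... } -- instead test
        # the formula directly through two siblings under a 0.2 parent:
        ann2 = AnnotationSet(
            direct={}, propagated={},
            term_count={"T:ROOT": 100, "T:A": 20, "T:B": 20, "T:LEAF": 4},
            proteome_size=100,
        )
        # leaf (p=0.04) vs its parent's sibling is not expressible in the
        # diamond; check leaf vs parent T:A: a* = T:A with p=0.2
        value = lin_term_similarity("T:LEAF", "T:A", ann2, diamond_ontology)
        expected = 2 * math.log(0.2) / (math.log(0.04) + math.log(0.2))
        assert value == pytest.approx(expected, abs=1e-12)

    def test_zero_probability_term_raises(self, chain_ontology):
        ann = propagate_annotations(
            AnnotationSet(direct={"P1": {"T:MID"}}), chain_ontology
        )
        with pytest.raises(ValueError, match="undefined"):
            lin_term_similarity("T:LEAF", "T:MID", ann, chain_ontology)


class TestAgainstBruteForce:
    def test_all_term_pairs_match_oracle(self, dag20):
        ontology, ann = dag20
        annotated = [t for t in sorted(ontology.terms) if ann.term_count.get(t, 0) > 0]
        for t1, t2 in itertools.combinations_with_replacement(annotated, 2):
            got = lin_term_similarity(t1, t2, ann, ontology)
            want = brute_tss(t1, t2, ann, ontology)
            assert got == pytest.approx(want, abs=1e-10), (t1, t2)
            # symmetry
            assert lin_term_similarity(t2, t1, ann, ontology) == pytest.approx(got, abs=1e-12)
            assert 0.0 <= got <= 1.0

    def test_all_protein_pairs_match_oracle(self, dag20):
        ontology, ann = dag20
        proteins = sorted(ann.propagated)
        for p1, p2 in itertools.combinations(proteins, 2):
            got = protein_semantic_similarity(p1, p2, ann, ontology)
            assert got == pytest.approx(brute_pss(p1, p2, ann, ontology), abs=1e-10), (p1, p2)
            assert 0.0 <= got <= 1.0

    def test_base_invariance_of_log(self, dag20):
        ontology, ann = dag20
        annotated = [t for t in sorted(ontology.terms) if ann.term_count.get(t, 0) > 0]
        prob = lambda t: term_probability(ann, t)
        for t1, t2 in itertools.combinations(annotated[:10], 2):
            got = lin_term_similarity(t1, t2, ann, ontology)
            common = brute_ancestors_and_self(ontology, t1) & brute_ancestors_and_self(ontology, t2)
            if not common or t1 == t2:
                continue
            pa = min(prob(a) for a in common)
            if pa >= 1.0:
                continue
            base2 = 2 * math.log2(pa) / (math.log2(prob(t1)) + math.log2(prob(t2)))
            assert got == pytest.approx(min(1.0, max(0.0, base2)), abs=1e-12)


class TestProteinSimilarityEdges:
    def test_identical_propagated_sets_score_one(self, chain_ontology):
        ann = propagate_annotations(
            AnnotationSet(direct={"P1": {"T:LEAF"}, "P2": {"T:LEAF"}, "P3": {"T:MID"}}),
            chain_ontology,
        )
        assert protein_semantic_similarity("P1", "P2", ann, chain_ontology) == 1.0

    def test_sharing_only_root_scores_zero(self, diamond_ontology):
        ann = propagate_annotations(
            AnnotationSet(direct={"P1": {"T:A"}, "P2": {"T:B"}}), diamond_ontology
        )
        assert protein_semantic_similarity("P1", "P2", ann, diamond_ontology) == 0.0

    def test_unannotated_protein_is_nan_not_zero(self, chain_ontology):
        ann = propagate_annotations(
            AnnotationSet(direct={"P1": {"T:LEAF"}}), chain_ontology
        )
        assert math.isnan(protein_semantic_similarity("P1", "NOPE", ann, chain_ontology))

    def test_best_match_average_symmetric_and_bounded(self, dag20):
        ontology, ann = dag20
        proteins = sorted(ann.propagated)[:6]
        for p1, p2 in itertools.combinations(proteins, 2):
            a = protein_semantic_similarity(p1, p2, ann, ontology, "best_match_average")
            b = protein_semantic_similarity(p2, p1, ann, ontology, "best_match_average")
            assert a == pytest.approx(b, abs=1e-12)
            assert 0.0 <= a <= 1.0


class TestWeightedDegree:
    def test_additivity_and_isolated(self, dag20):
        ontology, ann = dag20
        proteins = sorted(ann.propagated)
        net = make_net((proteins[0], proteins[1]), (proteins[0], proteins[2]))
        wd = semsim_weighted_degree(net, proteins[0], ann, ontology)
        expected = brute_pss(proteins[0], proteins[1], ann, ontology) + brute_pss(
            proteins[0], proteins[2], ann, ontology
        )
        assert wd.value == pytest.approx(expected, abs=1e-10)

    def test_unannotated_partner_contributes_zero_and_counted(self, chain_ontology):
        ann = propagate_annotations(
            AnnotationSet(direct={"P1": {"T:LEAF"}, "P2": {"T:LEAF"}}, proteome_size=10),
            chain_ontology,
        )
        net = make_net(("P1", "P2"), ("P1", "XX"))
        wd = semsim_weighted_degree(net, "P1", ann, chain_ontology)
        assert wd.value == pytest.approx(1.0)
        assert wd.n_edges == 2
        assert wd.n_undefined == 1

    def test_weighted_degree_bounded_by_annotated_degree(self, dag20):
        ontology, ann = dag20
        proteins = sorted(ann.propagated)[:10]
        edges = [(proteins[i], proteins[j]) for i in range(5) for j in range(5, 10)]
        net = make_net(*edges)
        for p in proteins[:5]:
            wd = semsim_weighted_degree(net, p, ann, ontology)
            assert wd.value <= wd.n_edges + 1e-12

    def test_semsim_degree_correlates_at_least_as_well_as_raw_degree(self, default_study):
        """On degree-driven essentiality, weighting interactions by semantic
        similarity should not weaken the correlation with essentiality
        relative to the raw annotated degree (the weighting emphasizes
        intramodular context)."""
        from modessence.centrality import compute_degrees
        from modessence.semsim import semsim_degree_table
        from modessence.stats import spearman_rcc

        s = default_study
        sub = s.interactome.induced_subgraph(s.modules.universe & s.interactome.proteins)
        table = compute_degrees(sub, s.modules, s.essentiality)
        ss = semsim_degree_table(sub, s.annotations, s.ontology)
        joined = table.join(ss[["semsim_degree"]])
        ess = joined["essential"].to_numpy(float)
        r_raw = spearman_rcc(ess, joined["total_annotated_degree"].to_numpy(float)).rho
        r_ss = spearman_rcc(ess, joined["semsim_degree"].to_numpy(float)).rho
        assert r_ss >= r_raw - 0.02

    def test_all_partners_sharing_most_specific_term_gives_plain_degree(self, chain_ontology):
        # every protein's most specific term is T:LEAF -> pSS = 1 per edge
        direct = {f"P{i}": {"T:LEAF"} for i in range(4)}
        ann = propagate_annotations(
            AnnotationSet(direct=direct, proteome_size=20), chain_ontology
        )
        net = make_net(("P0", "P1"), ("P0", "P2"), ("P0", "P3"))
        wd = semsim_weighted_degree(net, "P0", ann, chain_ontology)
        assert wd.value == pytest.approx(3.0)
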