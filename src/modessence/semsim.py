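"""Lin semantic similarity between terms and proteins, and weighted degree.

The Lin similarity of two terms t1, t2 with annotation probabilities
p(t1), p(t2) is

    tSS(t1, t2) = 2 log p(a*) / (log p(t1) + log p(t2))

where a* is the common ancestor of t1 and t2 with minimum probability (the
most informative common ancestor, resolving "a least common ancestor" in a
DAG).  Identical terms score 1; terms whose only common ancestor is a root
(probability 1) score 0.  The ratio of logarithms makes the log base
immaterial.

Protein-level similarity (pSS) extends this to the propagated annotation
sets S(p).  The default aggregation scores

    pSS(p1, p2) = 2 log p(s*) / (log p(m1) + log p(m2))

with s* the minimum-probability term shared by S(p1) and S(p2) and m1, m2
each protein's own minimum-probability term; identical annotation sets
score 1 and sharing only a root scores 0.  A best-match-average
aggregation over direct terms is available as an alternative (a naive max
over propagated term pairs would degenerate to 1 for any shared
annotation).

The semantic-similarity degree of a protein is the sum of pSS over its
interactions, a continuous counterpart of the intramodular degree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .network_io import Interactome
from .ontology import AnnotationSet, Ontology, term_probability

__all__ = [
    "lin_term_similarity",
    "protein_semantic_similarity",
    "semsim_weighted_degree",
    "semsim_degree_table",
    "WeightedDegree",
]


def _min_probability_term(
    terms: Iterable[str], ann: AnnotationSet, roots: frozenset = frozenset()
) -> tuple[str, float]:
    """The minimum-probability (most informative) term; ties by term id.

    On a probability tie a non-root term is preferred over a root, so the
    structural "root ancestor scores zero" rule only fires when every most
    informative candidate is a root.
    """
    best_t, best_p = None, None
    for t in sorted(terms):
        p = term_probability(ann, t)
        if best_p is None or p < best_p or (p == best_p and best_t in roots and t not in roots):
            best_t, best_p = t, p
    return best_t, best_p


def lin_term_similarity(t1: str, t2: str, ann: AnnotationSet, ontology: Ontology) -> float:
    """Lin similarity of two terms in [0, 1]."""
    p1, p2 = term_probability(ann, t1), term_probability(ann, t2)
    if p1 <= 0.0 or p2 <= 0.0:
        raise ValueError(
            f"similarity undefined: term probabilities must be positive "
            f"(p({t1})={p1}, p({t2})={p2})"
        )
    if t1 == t2:
        return 1.0
    common = ontology.ancestors_and_self(t1) & ontology.ancestors_and_self(t2)
    if not common:
        return 0.0
    roots = frozenset(ontology.roots)
    a_star, pa = _min_probability_term(common, ann, roots)
    # a root as the most informative common ancestor carries no shared
    # information, whatever its annotation probability
    if a_star in roots or pa >= 1.0:
        return 0.0
    value = 2.0 * math.log(pa) / (math.log(p1) + math.log(p2))
    return min(1.0, max(0.0, value))


def protein_semantic_similarity(
    p1: str,
    p2: str,
    ann: AnnotationSet,
    ontology: Ontology,
    aggregation: str = "most_specific",
) -> float:
    """Semantic similarity of two proteins in [0, 1]; NaN when undefined.

    Undefined (NaN) when either protein has no propagated annotation.
    ``aggregation`` is ``most_specific`` (default, see module docstring) or
    ``best_match_average``.
    """
    s1, s2 = ann.terms_of(p1), ann.terms_of(p2)
    if not s1 or not s2:
        return float("nan")
    if aggregation == "most_specific":
        shared = s1 & s2
        if not shared:
            return 0.0
        roots = frozenset(ontology.roots)
        s_star, ps = _min_probability_term(shared, ann, roots)
        if s_star in roots or ps >= 1.0:
            return 0.0  # only uninformative (root-level) terms shared
        _, pm1 = _min_probability_term(s1, ann)
        _, pm2 = _min_probability_term(s2, ann)
        value = 2.0 * math.log(ps) / (math.log(pm1) + math.log(pm2))
        return min(1.0, max(0.0, value))
    if aggregation == "best_match_average":
        d1 = ann.direct.get(p1) or s1
        d2 = ann.direct.get(p2) or s2

        def best(ts_from, ts_to):
            return sum(
                max(lin_term_similarity(t, u, ann, ontology) for u in ts_to)
                for t in ts_from
            ) / len(ts_from)

        return 0.5 * (best(d1, d2) + best(d2, d1))
    raise ValueError(f"unknown aggregation {aggregation!r}")


@dataclass(frozen=True)
class WeightedDegree:
    """Semantic-similarity degree with a coverage diagnostic."""

    value: float
    n_edges: int
    n_undefined: int


def semsim_weighted_degree(
    net: Interactome,
    protein: str,
    ann: AnnotationSet,
    ontology: Ontology,
    aggregation: str = "most_specific",
) -> WeightedDegree:
    """Sum of pSS over a protein's interactions.

    Interactions with undefined pSS (an unannotated partner) contribute 0
    and are reported in ``n_undefined``.
    """
    if protein not in net.graph:
        raise KeyError(f"protein {protein!r} not in network")
    total, n_edges, n_undef = 0.0, 0, 0
    for q in net.graph.neighbors(protein):
        n_edges += 1
        pss = protein_semantic_similarity(protein, q, ann, ontology, aggregation)
        if math.isnan(pss):
            n_undef += 1
        else:
            total += pss
    return WeightedDegree(total, n_edges, n_undef)


def semsim_degree_table(
    net: Interactome,
    ann: AnnotationSet,
    ontology: Ontology,
    aggregation: str = "most_specific",
) -> pd.DataFrame:
    """Semantic-similarity degree for every protein in the network."""
    rows = []
    for p in net.graph.nodes:
        wd = semsim_weighted_degree(net, p, ann, ontology, aggregation)
        rows.append(
            {
                "protein": p,
                "semsim_degree": wd.value,
                "n_edges": wd.n_edges,
                "n_undefined": wd.n_undefined,
                "aggregation": aggregation,
            }
        )
    return pd.DataFrame(rows).set_index("protein").sort_index()
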