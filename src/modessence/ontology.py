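"""Term ontology handling: OBO parsing, GAF annotations, true-path propagation.

An :class:`Ontology` is a rooted DAG of terms (``is_a`` plus, by default,
``part_of`` edges).  An :class:`AnnotationSet` maps proteins to terms, either
directly (as asserted in a GAF file) or propagated under the true-path rule:
a term annotating a protein implies all of its ancestors annotate it too.
Term probabilities — the fraction of the reference proteome a term annotates
after propagation — are the information-content basis for Lin semantic
similarity (see :mod:`modessence.semsim`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Optional

import networkx as nx
import obonet
from Bio.UniProt import GOA

logger = logging.getLogger(__name__)

__all__ = [
    "Ontology",
    "AnnotationSet",
    "parse_obo",
    "parse_gaf",
    "propagate_annotations",
    "select_specific_terms",
    "term_probability",
]

#: GAF aspect code for each GO namespace.
_ASPECT = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}


class Ontology:
    """A rooted, acyclic term DAG with parent links."""

    def __init__(
        self,
        parents: Mapping[str, set],
        namespaces: Optional[Mapping[str, str]] = None,
    ):
        self.parents: dict[str, frozenset] = {
            t: frozenset(ps) for t, ps in parents.items()
        }
        # make sure every referenced parent is a term
        for ps in list(self.parents.values()):
            for p in ps:
                self.parents.setdefault(p, frozenset())
        self.namespaces: dict[str, str] = dict(namespaces or {})
        self._ancestor_cache: dict[str, frozenset] = {}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for t, ps in self.parents.items():
            g.add_edges_from((t, p) for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology parent structure is cyclic: {cycle}")

    @property
    def terms(self) -> set:
        return set(self.parents)

    @property
    def roots(self) -> set:
        return {t for t, ps in self.parents.items() if not ps}

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> frozenset:
        """All proper ancestors of ``term`` (term itself excluded)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        out: set = set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def ancestors_and_self(self, term: str) -> frozenset:
        return self.ancestors(term) | {term}


@dataclass
class AnnotationSet:
    """Protein -> term annotations, direct and true-path propagated.

    ``term_count`` is computed on the propagated sets.  ``proteome_size`` is
    the size of the reference protein universe used as the denominator of
    term probabilities; by default the number of annotated proteins, but
    typically reset to the essentiality-tested universe by the pipeline.
    """

    direct: dict
    propagated: Optional[dict] = None
    term_count: dict = field(default_factory=dict)
    proteome_size: int = 0
    known_terms: Optional[frozenset] = None

    @property
    def proteins(self) -> set:
        return set(self.direct)

    def terms_of(self, protein: str) -> frozenset:
        """Propagated term set of a protein (empty if unannotated)."""
        if self.propagated is None:
            raise ValueError("annotations are not propagated yet")
        return self.propagated.get(protein, frozenset())


def parse_obo(path, include_part_of: bool = True) -> Ontology:
    """Load an OBO 1.2 ontology; obsolete terms are dropped.

    ``is_a`` edges always contribute to ancestry; ``part_of`` relationship
    edges do as well unless ``include_part_of`` is false.
    """
    graph = obonet.read_obo(path)  # MultiDiGraph, child -> parent, key = relation
    keep = {"is_a"} | ({"part_of"} if include_part_of else set())
    parents: dict[str, set] = {t: set() for t in graph.nodes}
    for child, parent, relation in graph.edges(keys=True):
        if relation in keep:
            parents[child].add(parent)
    namespaces = {
        t: data["namespace"] for t, data in graph.nodes(data=True) if "namespace" in data
    }
    return Ontology(parents, namespaces)


def parse_gaf(
    path,
    ontology: Ontology,
    namespace_filter: Optional[str] = "biological_process",
    id_field: str = "DB_Object_Symbol",
) -> AnnotationSet:
    """Parse a GAF 2.x file into direct annotations.

    NOT-qualified rows are skipped; rows outside the requested namespace and
    rows whose term is unknown to the ontology are skipped with a log
    message.  Protein ids are upper-cased.
    """
    aspect = _ASPECT.get(namespace_filter) if namespace_filter else None
    direct: dict[str, set] = {}
    n_unknown = n_skipped = 0
    with open(path) as fh:
        for rec in GOA.gafiterator(fh):
            try:
                protein = rec[id_field].strip().upper()
                term = rec["GO_ID"].strip()
                qualifiers = rec.get("Qualifier", [])
                rec_aspect = rec.get("Aspect", "")
            except (KeyError, AttributeError):
                n_skipped += 1
                continue
            if not protein or not term:
                n_skipped += 1
                continue
            if any(q == "NOT" or q.startswith("NOT|") for q in qualifiers):
                continue
            if aspect is not None and rec_aspect != aspect:
                continue
            if term not in ontology:
                n_unknown += 1
                continue
            direct.setdefault(protein, set()).add(term)
    if n_unknown:
        logger.warning("skipped %d annotations with term ids unknown to the ontology", n_unknown)
    if n_skipped:
        logger.warning("skipped %d malformed GAF rows", n_skipped)
    return AnnotationSet(
        direct=direct,
        proteome_size=len(direct),
        known_terms=frozenset(ontology.terms),
    )


def propagate_annotations(ann: AnnotationSet, ontology: Ontology) -> AnnotationSet:
    """Close each protein's annotation set under ancestors (true-path rule).

    Idempotent; ``term_count`` is recomputed on the propagated sets.  The
    ``proteome_size`` of ``ann`` is carried over (set it before or after as
    needed).
    """
    propagated: dict[str, frozenset] = {}
    for protein, terms in ann.direct.items():
        closed: set = set()
        for t in terms:
            closed |= ontology.ancestors_and_self(t)
        propagated[protein] = frozenset(closed)
    term_count: dict[str, int] = {}
    for terms in propagated.values():
        for t in terms:
            term_count[t] = term_count.get(t, 0) + 1
    proteome = ann.proteome_size or len(propagated)
    return AnnotationSet(
        direct={p: set(ts) for p, ts in ann.direct.items()},
        propagated=propagated,
        term_count=term_count,
        proteome_size=proteome,
        known_terms=ann.known_terms or frozenset(ontology.terms),
    )


def select_specific_terms(
    ann: AnnotationSet, max_annotated: int = 50, min_annotated: int = 0
) -> set:
    """Terms whose propagated annotation count lies in [min, max]."""
    if min_annotated > max_annotated:
        raise ValueError("min_annotated must not exceed max_annotated")
    if not ann.term_count:
        raise ValueError("propagate annotations before selecting specific terms")
    return {
        t
        for t, n in ann.term_count.items()
        if min_annotated <= n <= max_annotated
    }


def term_probability(ann: AnnotationSet, term: str) -> float:
    """Fraction of the reference proteome annotated (propagated) with term."""
    if ann.known_terms is not None and term not in ann.known_terms:
        raise KeyError(f"unknown term {term!r}")
    if ann.proteome_size <= 0:
        raise ValueError("proteome_size is not set")
    return ann.term_count.get(term, 0) / ann.proteome_size
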