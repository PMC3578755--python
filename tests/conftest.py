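"""Shared fixtures: tiny hand-built networks/ontologies and the default study."""

from __future__ import annotations

import numpy as np
import pytest

from modessence.catalog import Module, ModuleSet
from modessence.network_io import EssentialityMap, Interactome, InteractionRecord
from modessence.ontology import AnnotationSet, Ontology, propagate_annotations
from modessence.synthetic import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (heavy; shared across the session)."""
    return generate_study(GeneratorConfig(seed=17))


@pytest.fixture(scope="session")
def default_fixture_dir(default_study, tmp_path_factory):
    from modessence.synthetic import write_fixture

    d = tmp_path_factory.mktemp("fixture")
    write_fixture(default_study, d)
    return d


@pytest.fixture
def chain_ontology():
    """root <- mid <- leaf."""
    return Ontology(
        {"T:ROOT": set(), "T:MID": {"T:ROOT"}, "T:LEAF": {"T:MID"}},
        namespaces={t: "biological_process" for t in ("T:ROOT", "T:MID", "T:LEAF")},
    )


@pytest.fixture
def diamond_ontology():
    """leaf with two parents that share one root."""
    return Ontology(
        {
            "T:ROOT": set(),
            "T:A": {"T:ROOT"},
            "T:B": {"T:ROOT"},
            "T:LEAF": {"T:A", "T:B"},
        }
    )


def random_dag_with_annotations(
    n_terms: int = 20, n_proteins: int = 30, seed: int = 5
) -> tuple[Ontology, AnnotationSet]:
    """A seeded random rooted DAG with direct annotations, propagated.

    Term i may have parents among terms 0..i-1 (term 0 is the root), so the
    structure is acyclic by construction; every protein gets 1-3 direct
    annotations at random terms.
    """
    rng = np.random.default_rng(seed)
    terms = [f"T:{i:03d}" for i in range(n_terms)]
    parents: dict[str, set] = {terms[0]: set()}
    for i in range(1, n_terms):
        n_par = 1 + int(rng.random() < 0.3)  # some terms have two parents
        choices = rng.choice(i, size=min(n_par, i), replace=False)
        parents[terms[i]] = {terms[j] for j in choices}
    ontology = Ontology(parents)
    direct: dict[str, set] = {}
    for p in range(n_proteins):
        k = rng.integers(1, 4)
        chosen = rng.choice(n_terms, size=k, replace=False)
        direct[f"P{p:03d}"] = {terms[j] for j in chosen}
    ann = propagate_annotations(AnnotationSet(direct=direct), ontology)
    return ontology, ann


@pytest.fixture(scope="session")
def dag20():
    return random_dag_with_annotations()


@pytest.fixture
def toy_modules():
    return ModuleSet(
        [
            Module("M1", frozenset({"A", "B", "C"})),
            Module("M2", frozenset({"D", "E"})),
            Module("M3", frozenset({"C", "F"})),
        ]
    )


def make_net(*edges: tuple[str, str]) -> Interactome:
    return Interactome.from_records(
        InteractionRecord(u, v, system="Two-hybrid", source="S") for u, v in edges
    )


def ess_map(tested, essential) -> EssentialityMap:
    return EssentialityMap(frozenset(tested), frozenset(essential))
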