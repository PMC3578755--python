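"""Seeded synthetic interactomes with modular and essentiality structure.

The generator emulates the statistical structure the analyses assume in a
yeast-like interactome: a set of protein complexes (dense intramodule
blocks, edge probability ``p_in``) embedded in a sparse background
(``p_out``), a subset of planted module pairs with elevated intermodule
edge probability (``p_crosstalk``) standing in for genuine cross-talks, a
small rooted BP-like ontology whose leaf terms annotate exactly the module
members, and essentiality labels that rise with intramodular degree inside
"essential" modules (a logistic model on intramodule degree) against a low
base rate elsewhere.  Planted cross-talk pairs are preferentially drawn
between essential modules, making the module-level essentiality/cross-talk
association a controllable effect.

Everything is driven by one integer seed through a single
``numpy.random.Generator``; fixture files written twice with the same seed
are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .catalog import Module, ModuleSet
from .network_io import EssentialityMap, Interactome
from .ontology import AnnotationSet, Ontology, propagate_annotations

__all__ = [
    "GeneratorConfig",
    "SyntheticStudy",
    "generate_interactome",
    "assign_essentiality",
    "generate_toy_ontology",
    "generate_study",
    "write_fixture",
    "write_obo",
    "write_gaf",
]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic interactome.

    Defaults give ~2000 proteins carrying 40 complexes of 10-30 proteins,
    dense inside (p_in = 0.3), sparse between (p_out = 0.005), with 20
    planted cross-talk pairs at p_crosstalk = 0.15 drawn preferentially
    (bias 0.75) between essential modules, each module hosting at most two
    planted pairs; 60% of modules are essential (comparable to the
    essential fraction of curated yeast complexes) and within them the
    chance a protein is essential follows logistic(-5 + 1.0 * intramodule
    degree) — a sharp degree dependence centred on the mean intramodule
    degree — against ~5% elsewhere, which lands the overall essential
    fraction near that of systematic yeast deletion screens.
    """

    n_proteins: int = 2000
    n_complexes: int = 40
    complex_size_range: tuple[int, int] = (10, 30)
    p_in: float = 0.3
    p_out: float = 0.005
    n_crosstalk_pairs: int = 20
    p_crosstalk: float = 0.15
    crosstalk_pairs: Optional[list[tuple[str, str]]] = None
    frac_essential_modules: float = 0.6
    crosstalk_essential_bias: float = 0.75
    alpha: float = -5.0
    beta: float = 1.0
    base_rate: float = 0.05
    overlap_fraction: float = 0.0
    seed: int = 17

    def __post_init__(self):
        lo, hi = self.complex_size_range
        if not (1 <= lo <= hi):
            raise ValueError("complex_size_range must satisfy 1 <= min <= max")
        if self.n_complexes * hi > self.n_proteins:
            raise ValueError("complex sizes may exceed the protein universe")
        for name in ("p_in", "p_out", "p_crosstalk", "frac_essential_modules",
                     "crosstalk_essential_bias", "base_rate", "overlap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.p_out < self.p_in:
            raise ValueError("require p_out < p_in")
        if self.n_crosstalk_pairs > 0 and not self.p_out < self.p_crosstalk:
            raise ValueError("require p_out < p_crosstalk")


@dataclass
class SyntheticStudy:
    """A complete generated study: network, modules, labels, ontology."""

    config: GeneratorConfig
    interactome: Interactome
    modules: ModuleSet
    essentiality: EssentialityMap
    ontology: Ontology
    annotations: AnnotationSet
    planted_pairs: list[tuple[str, str]]
    essential_modules: set[str]


def _module_ids(n: int) -> list[str]:
    return [f"CPX{i:03d}" for i in range(1, n + 1)]


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(1, n + 1)]


def _select_essential_modules(cfg: GeneratorConfig, rng: np.random.Generator) -> set:
    ids = _module_ids(cfg.n_complexes)
    k = int(round(cfg.frac_essential_modules * cfg.n_complexes))
    chosen = rng.choice(len(ids), size=k, replace=False)
    return {ids[i] for i in chosen}


def _select_planted_pairs(
    cfg: GeneratorConfig, essential_modules: set, rng: np.random.Generator
) -> list[tuple[str, str]]:
    if cfg.crosstalk_pairs is not None:
        return [tuple(sorted(p)) for p in cfg.crosstalk_pairs]
    ids = _module_ids(cfg.n_complexes)
    ess = sorted(essential_modules)
    non = sorted(set(ids) - essential_modules)
    pairs: set = set()
    multiplicity: dict[str, int] = {}
    max_multiplicity = 2  # avoid concentrating planted pairs on a few modules
    budget = 0
    while len(pairs) < cfg.n_crosstalk_pairs:
        budget += 1
        if budget > 10_000:
            raise RuntimeError("could not draw the requested number of planted pairs")
        if budget % 2_000 == 0:
            max_multiplicity += 1  # relax the cap if the draw stalls

        def draw_endpoint():
            if ess and (not non or rng.random() < cfg.crosstalk_essential_bias):
                return ess[rng.integers(0, len(ess))]
            return non[rng.integers(0, len(non))]

        a, b = draw_endpoint(), draw_endpoint()
        if a == b or (a, b) in pairs or (b, a) in pairs:
            continue
        if multiplicity.get(a, 0) >= max_multiplicity or multiplicity.get(b, 0) >= max_multiplicity:
            continue
        pairs.add(tuple(sorted((a, b))))
        multiplicity[a] = multiplicity.get(a, 0) + 1
        multiplicity[b] = multiplicity.get(b, 0) + 1
    return sorted(pairs)


def generate_interactome(
    cfg: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    planted_pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> tuple[Interactome, ModuleSet, list[tuple[str, str]]]:
    """Generate the protein network and its ground-truth module catalog.

    Complexes are disjoint protein sets by default (``overlap_fraction``
    adds multi-membership).  Each intramodule pair is joined with ``p_in``.
    Cross pairs of planted module pairs are joined with ``p_crosstalk``.
    Background intermodule edges are drawn as a uniform random graph with
    Binomial(#eligible pairs, p_out) edges, equivalent in distribution to
    per-pair Bernoulli sampling for a simple graph.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    proteins = _protein_ids(cfg.n_proteins)
    module_ids = _module_ids(cfg.n_complexes)
    lo, hi = cfg.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_complexes)
    members: dict[str, set] = {}
    cursor = 0
    for mid, size in zip(module_ids, sizes):
        members[mid] = set(proteins[cursor : cursor + size])
        cursor += size
    if cfg.overlap_fraction > 0:
        for mid in module_ids:
            n_extra = int(np.floor(cfg.overlap_fraction * len(members[mid])))
            pool = sorted(set(proteins[:cursor]) - members[mid])
            if n_extra and pool:
                extra = rng.choice(len(pool), size=min(n_extra, len(pool)), replace=False)
                members[mid] |= {pool[i] for i in extra}
    modules = ModuleSet(
        Module(mid, frozenset(members[mid]), origin="complex") for mid in module_ids
    )
    if planted_pairs is None:
        essential_modules = _select_essential_modules(cfg, rng)
        planted_pairs = _select_planted_pairs(cfg, essential_modules, rng)

    g = nx.Graph()
    g.add_nodes_from(proteins)
    # intramodule edges
    for mid in module_ids:
        mem = sorted(members[mid])
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                if rng.random() < cfg.p_in:
                    g.add_edge(mem[i], mem[j])
    # planted cross-talk edges
    planted_cross: set = set()
    for a, b in planted_pairs:
        ma, mb = sorted(members[a] - members[b]), sorted(members[b] - members[a])
        for u in ma:
            for v in mb:
                planted_cross.add(frozenset((u, v)))
                if rng.random() < cfg.p_crosstalk:
                    g.add_edge(u, v)
    # background edges: G(n, m)-style draw over all remaining pairs
    n = cfg.n_proteins
    n_pairs = n * (n - 1) // 2
    n_background = rng.binomial(n_pairs, cfg.p_out)
    placed = 0
    mem_of = modules.membership()
    while placed < n_background:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        u, v = proteins[i], proteins[j]
        if mem_of.get(u, frozenset()) & mem_of.get(v, frozenset()):
            continue  # intramodule pairs already drawn at p_in
        if frozenset((u, v)) in planted_cross:
            continue  # planted cross pairs already drawn at p_crosstalk
        if g.has_edge(u, v):
            continue
        g.add_edge(u, v)
        placed += 1
    for e in g.edges():
        g.edges[e]["records"] = {("Two-hybrid", "SYN-HT-1")}
    return Interactome(g), modules, list(planted_pairs)


def _intramodule_degrees(net: Interactome, modules: ModuleSet) -> dict[str, int]:
    mem = modules.membership()
    degs: dict[str, int] = {}
    for p in net.graph.nodes:
        mp = mem.get(p, frozenset())
        if mp:
            degs[p] = sum(
                1 for q in net.graph.neighbors(p) if mem.get(q, frozenset()) & mp
            )
        else:
            degs[p] = 0
    return degs


def assign_essentiality(
    modules: ModuleSet,
    degrees: dict,
    cfg: GeneratorConfig,
    essential_modules: set,
    rng: Optional[np.random.Generator] = None,
    proteins: Optional[Sequence[str]] = None,
) -> EssentialityMap:
    """Label proteins essential with degree-dependent probability.

    Inside essential modules P(essential) = logistic(alpha + beta * intra
    degree); everywhere else the flat ``base_rate`` applies.  All proteins
    are "tested".
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    if proteins is None:
        proteins = sorted(degrees)
    mem = modules.membership()
    essential: set = set()
    for p in proteins:
        in_essential = bool(mem.get(p, frozenset()) & essential_modules)
        if in_essential:
            logit = cfg.alpha + cfg.beta * degrees.get(p, 0)
            prob = 1.0 / (1.0 + np.exp(-logit))
        else:
            prob = cfg.base_rate
        if rng.random() < prob:
            essential.add(p)
    return EssentialityMap(frozenset(proteins), frozenset(essential))


def generate_toy_ontology(
    modules: ModuleSet, group_size: int = 5
) -> tuple[Ontology, AnnotationSet]:
    """A small BP-like DAG: one leaf term per module, mid-level groups, one root.

    Leaf terms annotate exactly the module members; modules are grouped in
    chunks of ``group_size`` under mid-level parents.  The returned
    annotation set is propagated, with proteome size equal to the number of
    annotated proteins (callers typically reset it to the tested universe).
    """
    root = "GO:9000000"
    parents: dict[str, set] = {root: set()}
    namespaces = {root: "biological_process"}
    direct: dict[str, set] = {}
    ordered = sorted(modules, key=lambda m: m.id)
    for gi in range(0, len(ordered), group_size):
        mid_term = f"GO:91000{gi // group_size:02d}"
        parents[mid_term] = {root}
        namespaces[mid_term] = "biological_process"
        for offset, module in enumerate(ordered[gi : gi + group_size]):
            leaf = f"GO:92{gi // group_size:02d}{offset:03d}"
            parents[leaf] = {mid_term}
            namespaces[leaf] = "biological_process"
            for p in module.members:
                direct.setdefault(p, set()).add(leaf)
    ontology = Ontology(parents, namespaces)
    ann = AnnotationSet(direct=direct, proteome_size=len(direct))
    return ontology, propagate_annotations(ann, ontology)


def generate_study(cfg: Optional[GeneratorConfig] = None) -> SyntheticStudy:
    """Generate a full synthetic study from one config (one seed)."""
    cfg = GeneratorConfig() if cfg is None else cfg
    rng = np.random.default_rng(cfg.seed)
    essential_modules = _select_essential_modules(cfg, rng)
    planted = (
        [tuple(sorted(p)) for p in cfg.crosstalk_pairs]
        if cfg.crosstalk_pairs is not None
        else _select_planted_pairs(cfg, essential_modules, rng)
    )
    net, modules, planted = generate_interactome(cfg, rng=rng, planted_pairs=planted)
    degrees = _intramodule_degrees(net, modules)
    ess = assign_essentiality(
        modules, degrees, cfg, essential_modules, rng=rng, proteins=sorted(net.graph.nodes)
    )
    ontology, ann = generate_toy_ontology(modules)
    ann.proteome_size = len(ess.tested)
    return SyntheticStudy(
        config=cfg,
        interactome=net,
        modules=modules,
        essentiality=ess,
        ontology=ontology,
        annotations=ann,
        planted_pairs=sorted(planted),
        essential_modules=essential_modules,
    )


def write_obo(ontology: Ontology, path) -> None:
    """Serialize an ontology as OBO 1.2 (is_a edges only)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(ontology.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            ns = ontology.namespaces.get(term, "biological_process")
            fh.write(f"namespace: {ns}\n")
            for parent in sorted(ontology.parents[term]):
                fh.write(f"is_a: {parent}\n")


def write_gaf(ann: AnnotationSet, path) -> None:
    """Serialize direct annotations as GAF 2.1."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for protein in sorted(ann.direct):
            for term in sorted(ann.direct[protein]):
                fields = [
                    "SYN", protein, protein, "", term, "SYN:0001", "IEA", "",
                    "P", "", "", "protein", "taxon:4932", "20130101", "SYN", "", "",
                ]
                fh.write("\t".join(fields) + "\n")


def write_fixture(study: SyntheticStudy, out_dir) -> dict:
    """Write all fixture files plus a ground-truth manifest; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": out / "interactions.tsv",
        "modules": out / "modules.tsv",
        "obo": out / "ontology.obo",
        "gaf": out / "annotations.gaf",
        "essentiality": out / "essentiality.tsv",
        "manifest": out / "manifest.json",
    }
    with open(paths["interactions"], "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in study.interactome.graph.edges()):
            fh.write(f"{u}\t{v}\tTwo-hybrid\tSYN-HT-1\t{u}\n")
    study.modules.write_tsv(paths["modules"])
    write_obo(study.ontology, paths["obo"])
    write_gaf(study.annotations, paths["gaf"])
    study.essentiality.to_table(paths["essentiality"])
    cfg = asdict(study.config)
    cfg["complex_size_range"] = list(cfg["complex_size_range"])
    manifest = {
        "seed": study.config.seed,
        "config": cfg,
        "planted_pairs": [list(p) for p in study.planted_pairs],
        "essential_modules": sorted(study.essential_modules),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
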