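"""Module-level cross-talk networks via degree-preserving randomization.

Two functional modules "cross-talk" when the number of interactions between
them exceeds what degree-preserving randomization of the intermodular edge
set produces.  The null model rewires the intermodular edges by repeated
double-edge swaps, preserving each protein's intermodular degree, every
module membership and the total number of intermodular edges, while
forbidding self-loops, duplicate edges and edges whose endpoints share a
module.  For a module pair with n_real observed cross-talk interactions and
mean randomized count n_rand, the odds-score is

    odds = (n_real + 1) / (n_rand + 1)

(the pseudocount damps pairs whose randomized counts are near zero).  A pair
is accepted as a cross-talk when its odds-score reaches a threshold and it
is supported by at least two vertex-disjoint interactions.  The resulting
module network carries per-module size, binary essentiality (>= 1 essential
member), essential fraction, cross-talk degree and size-normalized degree.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import ModuleSet
from .network_io import EssentialityMap, Interactome
from .ontology import AnnotationSet
from .stats import (
    CorrelationResult,
    partial_spearman,
    spearman_rcc,
    wilcoxon_rank_sum,
)
from .centrality import hub_fraction_curve

__all__ = [
    "ModulePairCount",
    "ModuleNetwork",
    "intermodular_edges",
    "count_crosstalk",
    "has_independent_pair",
    "stub_rewire_intermodular",
    "odds_score",
    "infer_crosstalk_network",
    "crosstalk_essentiality_analysis",
    "filter_functionally_related",
]


@dataclass(frozen=True)
class ModulePairCount:
    """Cross-talk evidence for one module pair."""

    m1: str
    m2: str
    n_real: int
    n_rand_mean: float
    independent: bool

    @property
    def odds(self) -> float:
        return odds_score(self.n_real, self.n_rand_mean)


def odds_score(n_real: int, n_rand_mean: float) -> float:
    """Pseudocounted ratio of observed to mean-randomized counts."""
    if n_rand_mean < 0:
        raise ValueError("n_rand_mean must be nonnegative")
    return (n_real + 1.0) / (n_rand_mean + 1.0)


def intermodular_edges(net: Interactome, modules: ModuleSet) -> list[tuple[str, str]]:
    """Edges between module members whose endpoints share no module."""
    mem = modules.membership()
    out = []
    for u, v in net.graph.edges():
        mu, mv = mem.get(u), mem.get(v)
        if mu and mv and not (mu & mv):
            out.append((u, v) if u <= v else (v, u))
    out.sort()
    return out


def count_crosstalk(net: Interactome, m1, m2) -> int:
    """Number of cross-talk interactions between two modules.

    Counts edges with one endpoint in each module, excluding edges where
    either endpoint belongs to both modules (those are intramodular).
    """
    a, b = m1.members, m2.members
    both = a & b
    count = 0
    for u, v in net.graph.edges():
        if u in both or v in both:
            continue
        if (u in a and v in b) or (u in b and v in a):
            count += 1
    return count


def has_independent_pair(edges: Sequence[tuple[str, str]]) -> bool:
    """True iff two of the edges share no protein (matching number >= 2)."""
    for i, (a, b) in enumerate(edges):
        for c, d in edges[i + 1 :]:
            if len({a, b, c, d}) == 4:
                return True
    return False


def _pairs_supported(u: str, v: str, mem: dict) -> list[tuple[str, str]]:
    """Module pairs to which edge (u, v) contributes a cross-talk count.

    An edge supports pair (m1, m2) with m1 containing u and m2 containing
    v (or vice versa) unless either endpoint belongs to both modules.
    """
    mu, mv = mem.get(u, frozenset()), mem.get(v, frozenset())
    out = []
    for a in mu:
        for b in mv:
            if a == b:
                continue
            # b in mu: u belongs to both modules; a in mv: v does.  Either
            # way the edge is intramodular for this pair.  Unreachable for
            # intermodular edges (mu and mv disjoint) but kept for safety
            # when called on arbitrary edges.
            if b in mu or a in mv:
                continue
            out.append((a, b) if a <= b else (b, a))
    return sorted(set(out))


def stub_rewire_intermodular(
    net: Interactome,
    modules: ModuleSet,
    n_rounds: int = 100,
    seed: Optional[int] = None,
    n_swap_factor: int = 10,
):
    """Yield randomized intermodular edge sets, one list per round.

    Each round starts from the observed intermodular edges and performs
    ``n_swap_factor * |E|`` proposed double-edge swaps: two edges are drawn
    uniformly, randomly oriented as (a, b) and (c, d), and rewired to
    (a, d), (c, b); a proposal is rejected if it would create a self-loop,
    a duplicate edge, or an edge whose endpoints share a module.  The
    proposal kernel is symmetric, so the chain's stationary distribution is
    uniform over the reachable valid configurations.  Per-protein
    intermodular degree, module memberships and the edge count are all
    preserved exactly.
    """
    base = intermodular_edges(net, modules)
    mem = modules.membership()
    rng = np.random.default_rng(seed)
    n_edges = len(base)
    if n_edges == 0:
        raise ValueError("network has no intermodular edges to rewire")
    n_proposals = n_swap_factor * n_edges
    for _ in range(n_rounds):
        edges = list(base)
        edge_set = {frozenset(e) for e in edges}
        if n_edges >= 2:
            idx = rng.integers(0, n_edges, size=(n_proposals, 2))
            flips = rng.integers(0, 2, size=(n_proposals, 2))
            for (i, j), (fi, fj) in zip(idx, flips):
                if i == j:
                    continue
                a, b = edges[i]
                if fi:
                    a, b = b, a
                c, d = edges[j]
                if fj:
                    c, d = d, c
                if a == d or c == b:
                    continue
                e1, e2 = frozenset((a, d)), frozenset((c, b))
                if e1 == e2 or e1 in edge_set or e2 in edge_set:
                    continue
                if mem[a] & mem[d] or mem[c] & mem[b]:
                    continue
                edge_set.discard(frozenset((a, b)))
                edge_set.discard(frozenset((c, d)))
                edge_set.add(e1)
                edge_set.add(e2)
                edges[i] = (a, d) if a <= d else (d, a)
                edges[j] = (c, b) if c <= b else (b, c)
        yield sorted(edges)


class ModuleNetwork:
    """Inferred cross-talk graph over modules.

    Nodes are all modules of the catalog, annotated with size, binary
    essentiality, and essential fraction; edges are accepted cross-talks
    with their counts and odds-scores.  ``crosstalk_degree`` is the number
    of accepted partners; ``normalized_crosstalk_degree`` divides by module
    size.
    """

    def __init__(
        self,
        modules: ModuleSet,
        ess: EssentialityMap,
        accepted: Sequence[ModulePairCount],
        candidates: Optional[Sequence[ModulePairCount]] = None,
    ):
        self.modules = modules
        self.ess = ess
        self.accepted = list(accepted)
        self.candidates = list(candidates) if candidates is not None else list(accepted)
        g = nx.Graph()
        for m in modules:
            n_ess = sum(1 for p in m.members if ess.is_essential(p))
            g.add_node(
                m.id,
                size=m.size,
                binary_essential=int(n_ess >= 1),
                fraction_essential=n_ess / m.size,
            )
        for pc in self.accepted:
            g.add_edge(pc.m1, pc.m2, n_real=pc.n_real, n_rand_mean=pc.n_rand_mean, odds=pc.odds)
        self.graph = g

    def crosstalk_degree(self, module_id: str) -> int:
        return self.graph.degree(module_id)

    def node_table(self, include_isolated: bool = True) -> pd.DataFrame:
        rows = []
        for mid, data in self.graph.nodes(data=True):
            deg = self.graph.degree(mid)
            if not include_isolated and deg == 0:
                continue
            rows.append(
                {
                    "module": mid,
                    "size": data["size"],
                    "crosstalk_degree": deg,
                    "normalized_crosstalk_degree": deg / data["size"],
                    "binary_essential": data["binary_essential"],
                    "fraction_essential": data["fraction_essential"],
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "module",
                "size",
                "crosstalk_degree",
                "normalized_crosstalk_degree",
                "binary_essential",
                "fraction_essential",
            ],
        ).set_index("module").sort_index()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "m1": pc.m1,
                "m2": pc.m2,
                "n_real": pc.n_real,
                "n_rand_mean": pc.n_rand_mean,
                "odds": pc.odds,
            }
            for pc in sorted(self.accepted, key=lambda pc: (pc.m1, pc.m2))
        ]
        return pd.DataFrame(rows, columns=["m1", "m2", "n_real", "n_rand_mean", "odds"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    @property
    def n_crosstalks(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_modules_with_crosstalk(self) -> int:
        return sum(1 for m in self.graph.nodes if self.graph.degree(m) > 0)

    def fraction_essential_modules(self) -> float:
        """Fraction of modules with >= 1 cross-talk that are essential."""
        with_ct = [m for m in self.graph.nodes if self.graph.degree(m) > 0]
        if not with_ct:
            return float("nan")
        return sum(self.graph.nodes[m]["binary_essential"] for m in with_ct) / len(with_ct)


def infer_crosstalk_network(
    net: Interactome,
    modules: ModuleSet,
    ess: EssentialityMap,
    odds_threshold: float = 5.0,
    n_rounds: int = 100,
    seed: Optional[int] = None,
) -> ModuleNetwork:
    """Infer the cross-talk module network.

    Counts cross-talk interactions for every module pair, estimates the
    null mean over ``n_rounds`` stub-rewired networks (shared across all
    pairs; rounds where a pair has no edge contribute zero to its mean),
    and accepts pairs with at least two vertex-disjoint supporting edges
    and odds-score >= ``odds_threshold``.
    """
    mem = modules.membership()
    real_edges = intermodular_edges(net, modules)

    def pair_counts(edges):
        counts: dict[tuple[str, str], int] = {}
        for u, v in edges:
            for pair in _pairs_supported(u, v, mem):
                counts[pair] = counts.get(pair, 0) + 1
        return counts

    n_real = pair_counts(real_edges)
    support: dict[tuple[str, str], list] = {p: [] for p in n_real}
    for u, v in real_edges:
        for pair in _pairs_supported(u, v, mem):
            support[pair].append((u, v))

    rand_total: dict[tuple[str, str], int] = {}
    if real_edges:
        for edges in stub_rewire_intermodular(net, modules, n_rounds=n_rounds, seed=seed):
            for pair, c in pair_counts(edges).items():
                rand_total[pair] = rand_total.get(pair, 0) + c

    candidates = []
    for pair, count in sorted(n_real.items()):
        mean = rand_total.get(pair, 0) / n_rounds
        candidates.append(
            ModulePairCount(
                pair[0],
                pair[1],
                n_real=count,
                n_rand_mean=mean,
                independent=has_independent_pair(support[pair]),
            )
        )
    accepted = [
        pc for pc in candidates if pc.independent and pc.odds >= odds_threshold
    ]
    return ModuleNetwork(modules, ess, accepted, candidates)


def crosstalk_essentiality_analysis(
    mn: ModuleNetwork, group_size: int = 20, include_isolated: bool = True
) -> dict:
    """Relate cross-talk degree to module essentiality.

    Reports SRCC of binary module essentiality against cross-talk degree,
    the partial SRCC controlling for module size, SRCC against the
    size-normalized degree, SRCC of the essential fraction against degree,
    a Wilcoxon rank-sum comparison of degree between essential and
    non-essential modules, and the hub-module fraction curve (modules
    admitted in groups of ``group_size`` by decreasing degree).
    """
    table = mn.node_table(include_isolated=include_isolated)
    if len(table) < 4:
        raise ValueError("need at least 4 modules for the essentiality analysis")
    binary = table["binary_essential"].to_numpy(dtype=float)
    degree = table["crosstalk_degree"].to_numpy(dtype=float)
    out: dict = {
        "srcc_binary_vs_degree": spearman_rcc(binary, degree),
        "partial_srcc_binary_vs_degree_given_size": partial_spearman(
            binary, degree, table["size"].to_numpy(dtype=float), controlled_for="module_size"
        ),
        "srcc_binary_vs_normalized_degree": spearman_rcc(
            binary, table["normalized_crosstalk_degree"].to_numpy(dtype=float)
        ),
        "srcc_fraction_vs_degree": spearman_rcc(
            table["fraction_essential"].to_numpy(dtype=float), degree
        ),
    }
    ess_deg = degree[binary == 1]
    non_deg = degree[binary == 0]
    out["wilcoxon_degree_essential_vs_not"] = (
        wilcoxon_rank_sum(ess_deg, non_deg) if len(ess_deg) and len(non_deg) else None
    )
    curve_input = table.rename(columns={"binary_essential": "essential"})
    out["hub_module_curve"] = hub_fraction_curve(
        curve_input, degree_field="crosstalk_degree", group_size=group_size
    )
    return out


def filter_functionally_related(
    mn: ModuleNetwork,
    slim_terms: Iterable[str],
    ann: AnnotationSet,
    annotation_fraction: float = 0.5,
    max_annotated: int = 500,
) -> ModuleNetwork:
    """Drop cross-talks between modules sharing a broad functional label.

    Slim terms annotating more than ``max_annotated`` proteins are ignored.
    A module carries a slim term when at least ``annotation_fraction`` of
    its members are (propagated-)annotated with it; edges between modules
    sharing any carried term are removed and degrees recomputed.
    """
    usable = {
        t
        for t in slim_terms
        if ann.term_count.get(t, 0) <= max_annotated
    }
    module_slims: dict[str, frozenset] = {}
    for m in mn.modules:
        carried = set()
        for t in usable:
            n_with = sum(1 for p in m.members if t in ann.terms_of(p))
            if n_with / m.size >= annotation_fraction:
                carried.add(t)
        module_slims[m.id] = frozenset(carried)
    kept = [
        pc
        for pc in mn.accepted
        if not (module_slims.get(pc.m1, frozenset()) & module_slims.get(pc.m2, frozenset()))
    ]
    return ModuleNetwork(mn.modules, mn.ess, kept, mn.candidates)
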