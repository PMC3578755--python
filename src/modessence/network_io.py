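"""Reading protein-interaction tables and building evidence-class interactomes.

Interaction records come from BioGRID-style tab-delimited tables carrying two
protein identifiers plus provenance (experimental system, publication/source
id, and optionally the bait protein of the record).  Networks are undirected
simple graphs; bait/prey direction is kept only as provenance.

The provenance filters implemented here are the standard curation steps for
yeast interactome studies: a "sticky protein" filter that discards all
interactions a protein accrues from a single over-productive data source, an
evidence-class selection splitting records into *direct* (binary assays),
*pull-down* (co-complex assays) and *full* networks, and a high-throughput
restriction keeping only large multi-bait experiments.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "Interactome",
    "EssentialityMap",
    "DEFAULT_DIALECT",
    "DIRECT_SYSTEMS",
    "PULLDOWN_SYSTEMS",
    "EXCLUDED_SYSTEMS",
    "parse_interaction_table",
    "filter_sticky_proteins",
    "select_evidence_class",
    "filter_high_throughput",
    "restrict_to_tested",
]

#: Default column mapping for interaction tables (0-based indices).
DEFAULT_DIALECT: dict[str, int] = {"a": 0, "b": 1, "system": 2, "source": 3, "bait": 4}

#: Experimental systems whose records indicate a direct physical contact.
DIRECT_SYSTEMS = frozenset(
    {
        "biochemical activity",
        "co-crystal structure",
        "far western",
        "fret",
        "protein-peptide",
        "reconstituted complex",
        "two-hybrid",
    }
)

#: Co-complex (pull-down) experimental systems.
PULLDOWN_SYSTEMS = frozenset({"affinity capture-western", "affinity capture-ms"})

#: Systems excluded even from the full network (protein-RNA evidence).
EXCLUDED_SYSTEMS = frozenset({"affinity capture-rna", "protein-rna"})


@dataclass(frozen=True)
class InteractionRecord:
    """One row of an interaction table, protein pair stored unordered."""

    protein_a: str
    protein_b: str
    system: str = "unknown"
    source: str = "unknown"
    bait: Optional[str] = None

    @property
    def pair(self) -> frozenset:
        return frozenset((self.protein_a, self.protein_b))


class Interactome:
    """Undirected simple protein graph with per-edge provenance.

    Thin wrapper around :class:`networkx.Graph`; edge attribute ``records``
    holds the set of ``(system, source)`` tuples supporting the edge.
    """

    def __init__(self, graph: Optional[nx.Graph] = None):
        self.graph = graph if graph is not None else nx.Graph()

    @classmethod
    def from_records(cls, records: Iterable[InteractionRecord]) -> "Interactome":
        g = nx.Graph()
        for r in records:
            if r.protein_a == r.protein_b:
                continue
            if g.has_edge(r.protein_a, r.protein_b):
                g.edges[r.protein_a, r.protein_b]["records"].add((r.system, r.source))
            else:
                g.add_edge(r.protein_a, r.protein_b, records={(r.system, r.source)})
        return cls(g)

    @property
    def proteins(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_proteins(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self):
        return list(self.graph.edges())

    def provenance(self, u: str, v: str) -> set:
        return set(self.graph.edges[u, v].get("records", set()))

    def induced_subgraph(self, nodes: Iterable[str]) -> "Interactome":
        return Interactome(self.graph.subgraph(set(nodes)).copy())

    # -- serialization -------------------------------------------------

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges()):
                fh.write(f"{u}\t{v}\n")

    def write_provenance(self, path) -> None:
        with open(path, "w") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges()):
                for system, source in sorted(self.provenance(u, v)):
                    fh.write(f"{u}\t{v}\t{system}\t{source}\n")

    @classmethod
    def read_edgelist(cls, path) -> "Interactome":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                u, v = line.split("\t")[:2]
                if u != v:
                    g.add_edge(u, v, records=set())
        return cls(g)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Interactome({self.n_proteins} proteins, {self.n_edges} edges)"


@dataclass(frozen=True)
class EssentialityMap:
    """Proteins tested for essentiality and the essential subset."""

    tested: frozenset
    essential: frozenset

    def __post_init__(self):
        if not self.essential <= self.tested:
            raise ValueError("essential proteins must be a subset of tested proteins")

    def is_essential(self, protein: str) -> bool:
        return protein in self.essential

    @classmethod
    def from_table(cls, path) -> "EssentialityMap":
        """Read a two-column TSV: protein id, essentiality flag (0/1)."""
        tested, essential = set(), set()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                protein, flag = line.split("\t")[:2]
                protein = protein.upper()
                tested.add(protein)
                if flag.strip() in ("1", "true", "True"):
                    essential.add(protein)
        return cls(frozenset(tested), frozenset(essential))

    def to_table(self, path) -> None:
        with open(path, "w") as fh:
            for p in sorted(self.tested):
                fh.write(f"{p}\t{1 if p in self.essential else 0}\n")


def parse_interaction_table(
    path, dialect: Optional[Mapping[str, int]] = None
) -> list[InteractionRecord]:
    """Parse a tab-delimited interaction table into records.

    ``dialect`` maps field names (``a``, ``b``, ``system``, ``source``,
    ``bait``) to 0-based column indices.  Protein ids are upper-cased;
    self-interactions are dropped.  Duplicate rows yield duplicate records:
    deduplication happens at graph-build time.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    for mandatory in ("a", "b"):
        if mandatory not in dialect:
            raise ValueError(f"dialect is missing the mandatory column mapping {mandatory!r}")
    records: list[InteractionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                a = cols[dialect["a"]].strip().upper()
                b = cols[dialect["b"]].strip().upper()
            except IndexError:
                raise ValueError(
                    f"line {lineno}: missing mandatory protein-id column "
                    f"(need columns {dialect['a']} and {dialect['b']})"
                ) from None
            if a == b:
                continue

            def _opt(field_name: str) -> Optional[str]:
                idx = dialect.get(field_name)
                if idx is None or idx >= len(cols):
                    return None
                value = cols[idx].strip()
                return value or None

            system = _opt("system") or "unknown"
            source = _opt("source") or "unknown"
            bait = _opt("bait")
            if bait is not None:
                bait = bait.upper()
            records.append(InteractionRecord(a, b, system=system, source=source, bait=bait))
    if not records:
        warnings.warn(f"no interaction records parsed from {path}", stacklevel=2)
    return records


def filter_sticky_proteins(
    records: Sequence[InteractionRecord],
    max_per_source: int = 30,
    group_by: str = "source",
) -> list[InteractionRecord]:
    """Remove all of a protein's records from any source contributing too many.

    If a protein has strictly more than ``max_per_source`` records from a
    single data source, every record touching that protein from that source
    is removed; its records from other sources are untouched.  ``group_by``
    selects the granularity of "data source": the source/publication id
    (default) or the experimental ``system``.
    """
    if group_by not in ("source", "system"):
        raise ValueError("group_by must be 'source' or 'system'")
    key = (lambda r: r.source) if group_by == "source" else (lambda r: r.system)
    counts: Counter = Counter()
    for r in records:
        counts[(r.protein_a, key(r))] += 1
        counts[(r.protein_b, key(r))] += 1
    sticky = {k for k, n in counts.items() if n > max_per_source}
    if sticky:
        logger.info("sticky filter removed %d (protein, %s) pairs", len(sticky), group_by)
    return [
        r
        for r in records
        if (r.protein_a, key(r)) not in sticky and (r.protein_b, key(r)) not in sticky
    ]


def select_evidence_class(
    records: Sequence[InteractionRecord],
    evidence_class: str,
    direct_systems: Iterable[str] = DIRECT_SYSTEMS,
    pulldown_systems: Iterable[str] = PULLDOWN_SYSTEMS,
    excluded_systems: Iterable[str] = EXCLUDED_SYSTEMS,
) -> Interactome:
    """Build the interactome for one evidence class.

    ``direct`` admits only binary-assay systems, ``pulldown`` only co-complex
    capture systems, and ``full`` everything except the configured exclusion
    list (protein-RNA evidence).  System labels are compared
    case-insensitively.  Provenance of admitted records is aggregated per
    edge.
    """
    direct = {s.lower() for s in direct_systems}
    pulldown = {s.lower() for s in pulldown_systems}
    excluded = {s.lower() for s in excluded_systems}
    if evidence_class == "direct":
        admit = lambda s: s in direct
    elif evidence_class == "pulldown":
        admit = lambda s: s in pulldown
    elif evidence_class == "full":
        admit = lambda s: s not in excluded
    else:
        raise ValueError(
            f"unknown evidence class {evidence_class!r}; expected direct, pulldown or full"
        )
    return Interactome.from_records(r for r in records if admit(r.system.lower()))


def filter_high_throughput(
    records: Sequence[InteractionRecord],
    min_experiment_size: int = 50,
    min_baits: int = 10,
) -> list[InteractionRecord]:
    """Keep records from large multi-bait experiments only.

    A source is kept iff it contributed at least ``min_experiment_size``
    records and used strictly more than ``min_baits`` distinct bait proteins.
    """
    if any(r.bait is None for r in records):
        raise ValueError(
            "high-throughput filtering needs bait information for every record; "
            "supply a bait column in the input dialect"
        )
    per_source: Counter = Counter(r.source for r in records)
    baits: defaultdict = defaultdict(set)
    for r in records:
        baits[r.source].add(r.bait)
    keep = {
        src
        for src, n in per_source.items()
        if n >= min_experiment_size and len(baits[src]) > min_baits
    }
    return [r for r in records if r.source in keep]


def restrict_to_tested(net: Interactome, ess: EssentialityMap) -> Interactome:
    """Induced subgraph on the proteins tested for essentiality."""
    return net.induced_subgraph(net.proteins & set(ess.tested))
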