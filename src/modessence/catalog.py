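"""Module catalogs: protein complexes and specific biological processes.

A :class:`Module` is a named protein set — a curated complex, a specific
BP-term process (a term annotating at most ~50 proteins), or a "filtered"
process with complex contributions subtracted.  Catalog construction follows
the standard curation steps: strict-subset complexes removed, highly
overlapping pairs (Jaccard above a threshold) reduced to the larger member,
ribosomal complexes dropped, and processes pruned of proteins they share
with complexes so that process-level analyses are not dominated by complex
structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Module",
    "ModuleSet",
    "jaccard_index",
    "deduplicate_complexes",
    "build_process_modules",
    "filter_processes_against_complexes",
]


@dataclass(frozen=True)
class Module:
    """A named protein set with an origin tag."""

    id: str
    members: frozenset
    origin: str = "complex"  # complex | process | filtered_process
    declared_size: Optional[int] = None

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"module {self.id!r} has no members")

    @property
    def size(self) -> int:
        return len(self.members)


class ModuleSet:
    """An ordered collection of modules with unique ids."""

    def __init__(self, modules: Iterable[Module]):
        self.modules: list[Module] = list(modules)
        self.by_id: dict[str, Module] = {}
        for m in self.modules:
            if m.id in self.by_id:
                raise ValueError(f"duplicate module id {m.id!r}")
            self.by_id[m.id] = m
        self._membership: Optional[dict] = None

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def __contains__(self, module_id: str) -> bool:
        return module_id in self.by_id

    @property
    def universe(self) -> set:
        out: set = set()
        for m in self.modules:
            out |= m.members
        return out

    def membership(self) -> dict:
        """Protein -> frozenset of containing module ids (cached)."""
        if self._membership is None:
            idx: dict[str, set] = {}
            for m in self.modules:
                for p in m.members:
                    idx.setdefault(p, set()).add(m.id)
            self._membership = {p: frozenset(ms) for p, ms in idx.items()}
        return self._membership

    def modules_of(self, protein: str) -> frozenset:
        return self.membership().get(protein, frozenset())

    # -- serialization: module_id<TAB>p1,p2,... -------------------------

    @classmethod
    def read_tsv(cls, path, origin: str = "complex") -> "ModuleSet":
        modules = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                mid, members = parts[0], parts[1]
                declared = int(parts[2]) if len(parts) > 2 and parts[2] else None
                modules.append(
                    Module(
                        mid,
                        frozenset(p.strip().upper() for p in members.split(",") if p.strip()),
                        origin=origin,
                        declared_size=declared,
                    )
                )
        return cls(modules)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for m in sorted(self.modules, key=lambda m: m.id):
                members = ",".join(sorted(m.members))
                declared = "" if m.declared_size is None else str(m.declared_size)
                fh.write(f"{m.id}\t{members}\t{declared}\n")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ModuleSet({len(self.modules)} modules, {len(self.universe)} proteins)"


def jaccard_index(a: frozenset, b: frozenset) -> float:
    """|a ∩ b| / |a ∪ b|; undefined when both sets are empty."""
    union = a | b
    if not union:
        raise ValueError("Jaccard index is undefined for two empty sets")
    return len(a & b) / len(union)


def _sorted_for_sweep(modules: Sequence[Module]) -> list[Module]:
    # deterministic processing order: descending size, ties by id
    return sorted(modules, key=lambda m: (-m.size, m.id))


def _smaller_of(a: Module, b: Module) -> Module:
    """The module removed in an overlap conflict: smaller, ties by larger id."""
    if a.size != b.size:
        return a if a.size < b.size else b
    return a if a.id > b.id else b


def deduplicate_complexes(
    raw: ModuleSet,
    jaccard_threshold: float = 0.5,
    ribosome_ids: Iterable[str] = (),
) -> ModuleSet:
    """Remove redundant and ribosomal complexes.

    Three passes, repeated to a fixpoint for the overlap rules:
    (1) any complex whose members are a strict subset of another's is
    removed; (2) for any pair with Jaccard index >= ``jaccard_threshold``
    the smaller complex is removed (size ties: the lexicographically larger
    id); (3) the explicitly listed ribosome modules are removed.
    """
    current = list(raw.modules)
    changed = True
    while changed:
        changed = False
        ordered = _sorted_for_sweep(current)
        removed: set = set()
        for i, big in enumerate(ordered):
            if big.id in removed:
                continue
            for small in ordered[i + 1 :]:
                if small.id in removed:
                    continue
                if small.members < big.members:
                    removed.add(small.id)
                    changed = True
                elif small.members == big.members:
                    removed.add(_smaller_of(big, small).id)
                    changed = True
                elif jaccard_index(big.members, small.members) >= jaccard_threshold:
                    removed.add(_smaller_of(big, small).id)
                    changed = True
        current = [m for m in current if m.id not in removed]
    ribosome = set(ribosome_ids)
    missing = ribosome - {m.id for m in current}
    if missing:
        logger.warning("ribosome ids not present in catalog: %s", sorted(missing))
    current = [m for m in current if m.id not in ribosome]
    return ModuleSet(current)


def build_process_modules(ann, terms: Iterable[str]) -> ModuleSet:
    """One process module per selected term, from propagated annotations."""
    if ann.propagated is None:
        raise ValueError("annotations must be propagated to build process modules")
    reverse: dict[str, set] = {}
    for protein, pterms in ann.propagated.items():
        for t in pterms:
            reverse.setdefault(t, set()).add(protein)
    modules = []
    for t in sorted(terms):
        members = reverse.get(t, set())
        if members:
            modules.append(
                Module(t, frozenset(members), origin="process", declared_size=len(members))
            )
    return ModuleSet(modules)


def filter_processes_against_complexes(
    processes: ModuleSet,
    complexes_raw: ModuleSet,
    intersection_threshold: int = 2,
    jaccard_threshold: float = 0.5,
) -> ModuleSet:
    """Subtract complex contributions from process modules.

    For each process, every complex from the *pre-deduplication* complex
    catalog sharing at least ``intersection_threshold`` proteins with the
    process's full membership has the shared proteins removed from the
    process.  Processes left with fewer than 2 proteins, or with less than
    half their declared annotation count, are dropped.  Survivors then go
    through the same subset/Jaccard dedup as complexes.
    """
    filtered = []
    for proc in processes:
        original = proc.members
        to_remove: set = set()
        for cx in complexes_raw:
            inter = original & cx.members
            if len(inter) >= intersection_threshold:
                to_remove |= inter
        remaining = original - to_remove
        declared = proc.declared_size if proc.declared_size is not None else len(original)
        if len(remaining) < 2 or len(remaining) < declared / 2:
            continue
        filtered.append(
            Module(proc.id, frozenset(remaining), origin="filtered_process", declared_size=declared)
        )
    return deduplicate_complexes(ModuleSet(filtered), jaccard_threshold=jaccard_threshold)
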