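"""Interaction categorization and per-protein degree statistics.

Given an interactome and a module universe (complexes or processes), every
edge is intramodular (endpoints share a module), intermodular (both
annotated, no shared module) or unannotated (an endpoint belongs to no
module).  Per-protein degree statistics follow:

* ``intra_degree`` / ``inter_degree`` — number of partners of each class,
  each edge counted once per protein no matter how many shared modules
  cover it;
* ``total_annotated_degree`` — their sum;
* ``largest_module_size`` and ``intra_in_largest`` — size of the protein's
  largest containing module and its partner count inside that one module,
  answering the multi-membership concern by looking at a single module;
* ``normalized_intra`` — ``intra_in_largest`` divided by that module's size.

The hub-fraction curve reports the cumulative fraction of essential
proteins as proteins are admitted to the "hub" set in fixed-size groups in
non-increasing order of a chosen degree.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .catalog import ModuleSet
from .network_io import EssentialityMap, Interactome

__all__ = ["classify_edge", "compute_degrees", "hub_fraction_curve"]

DEGREE_COLUMNS = [
    "intra_degree",
    "inter_degree",
    "total_annotated_degree",
    "largest_module_size",
    "intra_in_largest",
    "normalized_intra",
    "essential",
]


def classify_edge(u: str, v: str, modules: ModuleSet) -> str:
    """Classify an edge as intramodular, intermodular or unannotated."""
    mu, mv = modules.modules_of(u), modules.modules_of(v)
    if not mu or not mv:
        return "unannotated"
    return "intramodular" if mu & mv else "intermodular"


def _largest_module(modules: ModuleSet, protein: str) -> Optional[str]:
    """Id of the protein's largest containing module; ties -> smallest id."""
    ids = modules.modules_of(protein)
    if not ids:
        return None
    return min(ids, key=lambda mid: (-modules.by_id[mid].size, mid))


def compute_degrees(
    net: Interactome,
    modules: ModuleSet,
    ess: EssentialityMap,
    restrict_to_module_members: bool = False,
) -> pd.DataFrame:
    """Per-protein degree table over the (optionally restricted) network.

    With ``restrict_to_module_members`` the network is first reduced to the
    induced subgraph on module members (the "complex subnetwork"), and only
    module members appear as rows; otherwise every protein in the network
    gets a row.
    """
    graph = net.graph
    if restrict_to_module_members:
        graph = graph.subgraph(set(graph.nodes) & modules.universe)
    rows = []
    for p in graph.nodes:
        member_of = modules.modules_of(p)
        intra = inter = 0
        if member_of:
            for q in graph.neighbors(p):
                mq = modules.modules_of(q)
                if not mq:
                    continue
                if member_of & mq:
                    intra += 1
                else:
                    inter += 1
        largest = _largest_module(modules, p)
        if largest is not None:
            largest_members = modules.by_id[largest].members
            largest_size = len(largest_members)
            intra_in_largest = sum(1 for q in graph.neighbors(p) if q in largest_members)
            normalized = intra_in_largest / largest_size
        else:
            largest_size = 0
            intra_in_largest = 0
            normalized = np.nan
        rows.append(
            {
                "protein": p,
                "intra_degree": intra,
                "inter_degree": inter,
                "total_annotated_degree": intra + inter,
                "largest_module_size": largest_size,
                "intra_in_largest": intra_in_largest,
                "normalized_intra": normalized,
                "essential": ess.is_essential(p),
            }
        )
    table = pd.DataFrame(rows, columns=["protein"] + DEGREE_COLUMNS)
    return table.set_index("protein").sort_index()


def hub_fraction_curve(
    table: pd.DataFrame,
    degree_field: str = "intra_degree",
    group_size: int = 50,
    extend_ties: bool = False,
) -> pd.DataFrame:
    """Cumulative essential fraction among the top-degree proteins.

    Proteins are sorted by non-increasing ``degree_field`` (ties broken by
    protein id for determinism) and admitted in cumulative groups of
    ``group_size``; each curve point reports the essential fraction of the
    admitted set.  With ``extend_ties`` a group boundary is pushed forward
    so proteins with equal degree never straddle it.  A final partial group
    is included when n is not a multiple of ``group_size``.
    """
    if degree_field not in table.columns:
        raise KeyError(f"degree field {degree_field!r} not in table")
    if table.empty:
        return pd.DataFrame(columns=["n_considered", "fraction_essential"])
    ordered = table.sort_values(
        [degree_field, table.index.name or "protein"],
        ascending=[False, True],
        kind="mergesort",
    )
    degrees = ordered[degree_field].to_numpy()
    essential = ordered["essential"].to_numpy(dtype=bool)
    cum_essential = np.cumsum(essential)
    n = len(ordered)
    points = []
    boundary = group_size
    while True:
        if boundary >= n:
            boundary = n
        elif extend_ties:
            while boundary < n and degrees[boundary] == degrees[boundary - 1]:
                boundary += 1
        points.append((boundary, cum_essential[boundary - 1] / boundary))
        if boundary >= n:
            break
        boundary += group_size
    return pd.DataFrame(points, columns=["n_considered", "fraction_essential"])
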