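"""Group-level network structure: weighted modularity and community detection.

Directed grooming graphs are symmetrized by summing the two directions, and
Newman weighted modularity Q = sum_c (e_cc - a_c^2) is computed on the
result, where e_cc is the fraction of total edge weight inside community c
and a_c the fraction of weight incident to c.  Q is 0 for the trivial
all-in-one partition and never exceeds 1.

Community detection runs a seeded portfolio of heuristics (greedy
agglomerative modularity, Louvain multilevel, leading eigenvector) and keeps
the partition with the largest Q.  The group-level summary pairs each
group's mean fitted eta with its modularity — the more unevenly individuals
spread their grooming, the more modular the group network tends to be.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import igraph as ig
import networkx as nx
import pandas as pd

from .core import CircleFitContinuous
from .network_io import GroupNetwork

__all__ = [
    "CommunityPartition",
    "GroupStructureSummary",
    "symmetrize",
    "modularity_q",
    "detect_communities",
    "group_structure_table",
]


@dataclass(frozen=True)
class CommunityPartition:
    """A node -> community labelling with its modularity."""

    assignment: Mapping[str, int]
    n_communities: int
    q: float


@dataclass(frozen=True)
class GroupStructureSummary:
    """Per-group pairing of mean eta with network modularity."""

    group_id: str
    species: str
    mean_eta: float
    q: float
    n_egos: int
    n_communities: int


def symmetrize(group: GroupNetwork | nx.DiGraph) -> nx.Graph:
    """Undirected weight(u, v) = directed(u->v) + directed(v->u); nodes preserved."""
    digraph = group.graph if isinstance(group, GroupNetwork) else group
    G = nx.Graph()
    G.add_nodes_from(digraph.nodes)
    for u, v, d in digraph.edges(data=True):
        w = d.get("weight", 1.0)
        if G.has_edge(u, v):
            G[u][v]["weight"] += w
        else:
            G.add_edge(u, v, weight=w)
    return G


def modularity_q(graph: nx.Graph, partition: Mapping[str, int]) -> float:
    """Newman weighted modularity of a given partition.

    Q = sum over communities of (within-weight fraction) minus (incident
    weight fraction squared).  Requires at least one edge.
    """
    missing = [n for n in graph.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    two_m = sum(d.get("weight", 1.0) for _, _, d in graph.edges(data=True)) * 2.0
    if two_m == 0:
        raise ValueError("graph has no edges; modularity undefined")
    within: dict[int, float] = {}
    incident: dict[int, float] = {}
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        cu, cv = partition[u], partition[v]
        if cu == cv:
            within[cu] = within.get(cu, 0.0) + 2.0 * w
        incident[cu] = incident.get(cu, 0.0) + w
        incident[cv] = incident.get(cv, 0.0) + w
    q = 0.0
    for c in set(partition[n] for n in graph.nodes):
        q += within.get(c, 0.0) / two_m - (incident.get(c, 0.0) / two_m) ** 2
    return q


def _greedy_partition(graph: nx.Graph) -> dict[str, int]:
    comms = nx.community.greedy_modularity_communities(graph, weight="weight")
    return {n: i for i, c in enumerate(comms) for n in c}


def _louvain_partition(graph: nx.Graph, seed: int) -> dict[str, int]:
    comms = nx.community.louvain_communities(graph, weight="weight", seed=seed)
    return {n: i for i, c in enumerate(comms) for n in c}


def _leading_eigenvector_partition(graph: nx.Graph, seed: int) -> dict[str, int]:
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    weights = [graph[u][v].get("weight", 1.0) for u, v in graph.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    # igraph draws from a process-global generator; pin it for determinism
    ig.set_random_number_generator(random.Random(seed))
    try:
        clustering = g.community_leading_eigenvector(weights=weights)
    finally:
        ig.set_random_number_generator(random)
    return {n: clustering.membership[index[n]] for n in nodes}


def detect_communities(graph: nx.Graph, seed: int = 0) -> CommunityPartition:
    """Run the heuristic portfolio and return the max-modularity partition.

    Isolated nodes are assigned their own singleton communities by each
    heuristic; determinism is guaranteed by the seed and by sorted node
    order.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_edges() == 0:
        assignment = {n: i for i, n in enumerate(sorted(graph.nodes))}
        return CommunityPartition(assignment=assignment, n_communities=len(assignment), q=0.0)
    candidates = [
        _greedy_partition(graph),
        _louvain_partition(graph, seed),
        _leading_eigenvector_partition(graph, seed),
    ]
    best = max(candidates, key=lambda p: modularity_q(graph, p))
    q = modularity_q(graph, best)
    # relabel communities in order of first appearance over sorted nodes
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for n in sorted(graph.nodes):
        c = best[n]
        if c not in relabel:
            relabel[c] = len(relabel)
        assignment[n] = relabel[c]
    return CommunityPartition(assignment=assignment, n_communities=len(relabel), q=q)


def group_structure_table(
    groups: Iterable[GroupNetwork],
    eta_fits: Mapping[str, Sequence[CircleFitContinuous]],
    species: Mapping[str, str] | None = None,
    seed: int = 0,
) -> list[GroupStructureSummary]:
    """One summary row per group: mean fitted eta and detected modularity.

    ``eta_fits`` maps group_id to the retained per-ego fits of that group.
    Raises if a listed group has no retained egos.
    """
    rows: list[GroupStructureSummary] = []
    for grp in groups:
        fits = eta_fits.get(grp.group_id, [])
        if not fits:
            raise ValueError(f"group {grp.group_id!r} has no retained eta fits")
        part = detect_communities(symmetrize(grp), seed=seed)
        rows.append(
            GroupStructureSummary(
                group_id=grp.group_id,
                species=(species or {}).get(grp.group_id, ""),
                mean_eta=float(sum(f.eta for f in fits) / len(fits)),
                q=part.q,
                n_egos=len(fits),
                n_communities=part.n_communities,
            )
        )
    return rows


def structure_frame(rows: Iterable[GroupStructureSummary]) -> pd.DataFrame:
    """Tabular form of the group structure summaries."""
    return pd.DataFrame(
        [
            {
                "group_id": r.group_id,
                "species": r.species,
                "n_egos": r.n_egos,
                "mean_eta": r.mean_eta,
                "q": r.q,
                "n_communities": r.n_communities,
            }
            for r in rows
        ]
    )
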