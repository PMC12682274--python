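"""Read grooming records and metadata, build group networks, apply filters.

Input schemas (CSV or TSV, UTF-8, header required):

* interactions: ``group_id, actor_id, receiver_id, weight`` — one aggregated
  row per directed dyad, or one row per event with weight 1.  Mutual grooming
  appears as two records, one per direction.
* metadata: ``individual_id, group_id, species, sex, age, habitat``.

Inclusion filters follow the study design: whole groups with fewer than 6
individuals are dropped, and within retained groups egos that groomed fewer
than 5 distinct partners (or whose weights are all equal) are excluded.
Every exclusion is recorded in a :class:`FilterAudit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .core import DegenerateWeightsError, TieWeights, normalize_distances

__all__ = [
    "InteractionRecord",
    "IndividualMeta",
    "GroupNetwork",
    "FilterAudit",
    "SchemaError",
    "read_interactions",
    "read_metadata",
    "build_group_networks",
    "extract_ego",
    "apply_filters",
]

INTERACTION_COLUMNS = ("group_id", "actor_id", "receiver_id", "weight")
META_COLUMNS = ("individual_id", "group_id", "species", "sex", "age", "habitat")

MIN_GROUP_SIZE = 6
MIN_PARTNERS = 5


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


@dataclass(frozen=True)
class InteractionRecord:
    """One directed grooming dyad: actor groomed receiver with total weight."""

    group_id: str
    actor_id: str
    receiver_id: str
    weight: float

    def __post_init__(self) -> None:
        if self.actor_id == self.receiver_id:
            raise ValueError(f"self-loop for individual {self.actor_id!r}")
        if not self.weight > 0:
            raise ValueError(
                f"non-positive weight {self.weight} for {self.actor_id}->{self.receiver_id}"
            )


@dataclass(frozen=True)
class IndividualMeta:
    """Demographics of one individual (age in years)."""

    individual_id: str
    group_id: str
    species: str
    sex: str
    age: float
    habitat: str


@dataclass
class GroupNetwork:
    """Directed weighted grooming graph of one group.

    ``group_size`` counts every individual listed in the metadata for the
    group, including socially inactive ones that never appear on an edge.
    """

    group_id: str
    members: frozenset[str]
    graph: nx.DiGraph

    @property
    def group_size(self) -> int:
        return len(self.members)

    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))


@dataclass
class FilterAudit:
    """Reconciliation of inclusion filtering: who went in, who survived, why not."""

    groups_in: int = 0
    groups_retained: int = 0
    egos_in: int = 0
    egos_retained: int = 0
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["id", "reason"])


def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read and validate grooming records; repeated dyad rows are summed.

    Raises :class:`SchemaError` for missing columns, ``ValueError`` (with the
    1-based data row number) for self-loops or non-positive weights.
    """
    df = _read_table(path, INTERACTION_COLUMNS)
    records: dict[tuple[str, str, str], float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            w = float(row.weight)
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: non-numeric weight {row.weight!r}") from exc
        if row.actor_id == row.receiver_id:
            raise ValueError(f"{path}: row {i}: self-loop for {row.actor_id!r}")
        if not w > 0:
            raise ValueError(f"{path}: row {i}: non-positive weight {w}")
        key = (str(row.group_id), str(row.actor_id), str(row.receiver_id))
        records[key] = records.get(key, 0.0) + w
    return [
        InteractionRecord(group_id=g, actor_id=a, receiver_id=r, weight=w)
        for (g, a, r), w in sorted(records.items())
    ]


def read_metadata(path: str | Path) -> list[IndividualMeta]:
    """Read the individual metadata table; one row per individual."""
    df = _read_table(path, META_COLUMNS)
    metas: list[IndividualMeta] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        iid = str(row.individual_id)
        if iid in seen:
            raise ValueError(f"{path}: row {i}: duplicate individual {iid!r}")
        seen.add(iid)
        try:
            age = float(row.age)
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: non-numeric age {row.age!r}") from exc
        if age < 0:
            raise ValueError(f"{path}: row {i}: negative age {age}")
        metas.append(
            IndividualMeta(
                individual_id=iid,
                group_id=str(row.group_id),
                species=str(row.species),
                sex=str(row.sex),
                age=age,
                habitat=str(row.habitat),
            )
        )
    return metas


def build_group_networks(
    records: Iterable[InteractionRecord], meta: Iterable[IndividualMeta]
) -> list[GroupNetwork]:
    """Assemble one directed weighted graph per group.

    Every individual referenced by a record must appear in the metadata with
    a matching group; cross-group interactions are rejected.  Individuals in
    the metadata with no interactions still count toward group size.
    """
    group_of: dict[str, str] = {}
    members: dict[str, set[str]] = {}
    for m in meta:
        group_of[m.individual_id] = m.group_id
        members.setdefault(m.group_id, set()).add(m.individual_id)

    graphs: dict[str, nx.DiGraph] = {g: nx.DiGraph() for g in members}
    for g, ms in members.items():
        graphs[g].add_nodes_from(sorted(ms))

    for rec in records:
        for iid in (rec.actor_id, rec.receiver_id):
            if iid not in group_of:
                raise ValueError(f"unknown individual {iid!r} in interaction records")
            if group_of[iid] != rec.group_id:
                raise ValueError(
                    f"cross-group interaction: {iid!r} belongs to "
                    f"{group_of[iid]!r}, record says {rec.group_id!r}"
                )
        G = graphs[rec.group_id]
        if G.has_edge(rec.actor_id, rec.receiver_id):
            G[rec.actor_id][rec.receiver_id]["weight"] += rec.weight
        else:
            G.add_edge(rec.actor_id, rec.receiver_id, weight=rec.weight)

    return [
        GroupNetwork(group_id=g, members=frozenset(members[g]), graph=graphs[g])
        for g in sorted(members)
    ]


def extract_ego(group: GroupNetwork, individual_id: str) -> TieWeights:
    """Outgoing grooming weights of one individual, one entry per distinct partner.

    The ego's resource distribution is its *given* grooming; an individual
    with no outgoing edges yields L = 0.
    """
    if individual_id not in group.members:
        raise ValueError(f"{individual_id!r} is not a member of group {group.group_id!r}")
    succ = sorted(group.graph.successors(individual_id)) if group.graph.has_node(individual_id) else []
    weights = tuple(group.graph[individual_id][v]["weight"] for v in succ)
    if not weights:
        # bypass the positivity check path with an explicitly empty ego
        tw = object.__new__(TieWeights)
        object.__setattr__(tw, "ego_id", individual_id)
        object.__setattr__(tw, "weights", ())
        object.__setattr__(tw, "L", 0)
        return tw
    return TieWeights(ego_id=individual_id, weights=weights)


def apply_filters(
    groups: Iterable[GroupNetwork],
    min_group_size: int = MIN_GROUP_SIZE,
    min_partners: int = MIN_PARTNERS,
) -> tuple[list[tuple[GroupNetwork, TieWeights]], FilterAudit]:
    """Apply the study's inclusion filters with a full audit trail.

    Groups smaller than ``min_group_size`` are dropped whole; within retained
    groups, egos with fewer than ``min_partners`` distinct groomed partners or
    with degenerate (all-equal) weights are excluded.  Returns the retained
    (group, ego) pairs and the audit.
    """
    audit = FilterAudit()
    retained: list[tuple[GroupNetwork, TieWeights]] = []
    for grp in groups:
        audit.groups_in += 1
        if grp.group_size < min_group_size:
            audit.exclusions.append((grp.group_id, f"group_size<{min_group_size}"))
            continue
        audit.groups_retained += 1
        for iid in sorted(grp.members):
            audit.egos_in += 1
            tw = extract_ego(grp, iid)
            if tw.L < min_partners:
                audit.exclusions.append((iid, f"min_partners<{min_partners}"))
                continue
            try:
                normalize_distances(tw)
            except DegenerateWeightsError:
                audit.exclusions.append((iid, "degenerate_weights"))
                continue
            audit.egos_retained += 1
            retained.append((grp, tw))
    return retained, audit


def metadata_index(meta: Iterable[IndividualMeta]) -> Mapping[str, IndividualMeta]:
    """Index metadata by individual id."""
    return {m.individual_id: m for m in meta}
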