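"""Cohesion scoring inside infection clusters and the SLBIC locator.

SLBNE misses a source whenever two sources sit next to each other: only one
of two adjacent nodes can be a strict local NE maximum.  SLBIC recovers such
sources by dividing the infected set into clusters around the cores and
picking, in each cluster, the node of largest *cohesion*

    delta_i = sum over distances d in path_dic_i of
                 (M_dis + 1 - d)/(M_dis + 1) * count_d / APN * 0.5
            + NE_i * 0.5,

where path_dic_i histograms the shortest-path distances (in the infected
subgraph) from i to the other cluster members, M_dis is the largest such
distance, and APN normalizes the histogram term.  APN defaults to the
number of distinct distance values; the alternative convention
``apn="reachable"`` uses the number of reachable members, which turns
count_d/APN into a probability distribution.  The per-cluster delta maximizer
is the *condensed node*; the SLBIC prediction is the union of the core set
and the condensed nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .network import ContactNetwork, InfectionSnapshot, infected_subgraph
from .entropy import (
    DEFAULT_ALPHA,
    EntropyTable,
    LocalizationResult,
    compute_entropy_table,
    core_convex_set,
)
from .clusters import ClusterAssignment, divide_clusters

__all__ = [
    "CohesionRecord",
    "path_length_histogram",
    "cohesion",
    "cluster_cohesion_records",
    "condensed_nodes",
    "slbic",
]


@dataclass(frozen=True)
class CohesionRecord:
    """Cohesion evidence for one node within one cluster."""

    node: str
    path_hist: dict[int, int]
    m_dis: int
    apn: int
    delta: float


def path_length_histogram(
    i: str,
    cluster_members: frozenset[str] | set[str],
    snapshot: InfectionSnapshot,
) -> dict[int, int]:
    """Histogram {distance: member count} from ``i`` to its cluster mates.

    Distances are shortest paths in the infected subgraph — paths may pass
    through any infected node, but only cluster members are counted as
    endpoints.  Unreachable members are omitted; ``i`` itself is excluded.
    """
    if i not in cluster_members:
        raise ValueError(f"{i!r} is not a member of the cluster")
    sub = infected_subgraph(snapshot)
    dists = nx.single_source_shortest_path_length(sub.graph, i)
    hist: dict[int, int] = {}
    for j in cluster_members:
        if j == i or j not in dists:
            continue
        d = dists[j]
        hist[d] = hist.get(d, 0) + 1
    return hist


def _delta_from_hist(hist: dict[int, int], ne: float, apn: str) -> tuple[int, int, float]:
    """Return (m_dis, apn_value, delta) under the chosen APN convention."""
    if not hist:
        return 0, 0, 0.5 * ne
    m_dis = max(hist)
    if apn == "distinct":
        apn_value = len(hist)
    elif apn == "reachable":
        apn_value = sum(hist.values())
    else:
        raise ValueError(f"apn must be 'distinct' or 'reachable', got {apn!r}")
    dist_term = sum(
        (m_dis + 1 - d) / (m_dis + 1) * count / apn_value for d, count in hist.items()
    )
    return m_dis, apn_value, 0.5 * dist_term + 0.5 * ne


def cohesion(
    i: str,
    cluster_members: frozenset[str] | set[str],
    snapshot: InfectionSnapshot,
    table: EntropyTable,
    apn: str = "distinct",
) -> float:
    """delta_i: distance-histogram centrality blended 50/50 with NE_i."""
    hist = path_length_histogram(i, cluster_members, snapshot)
    _, _, delta = _delta_from_hist(hist, table.ne(i), apn)
    return delta


def cluster_cohesion_records(
    cluster_members: frozenset[str] | set[str],
    snapshot: InfectionSnapshot,
    table: EntropyTable,
    apn: str = "distinct",
    normalize_ne: bool = False,
) -> list[CohesionRecord]:
    """Cohesion records for every member of one cluster.

    With ``normalize_ne=True`` the NE term is min–max rescaled to [0, 1]
    within the cluster before entering delta (all-equal NE maps to 0.5).
    The default keeps NE raw.
    """
    members = sorted(cluster_members)
    ne_values = {v: table.ne(v) for v in members}
    if normalize_ne and members:
        lo, hi = min(ne_values.values()), max(ne_values.values())
        if hi > lo:
            ne_values = {v: (x - lo) / (hi - lo) for v, x in ne_values.items()}
        else:
            ne_values = {v: 0.5 for v in ne_values}
    sub = infected_subgraph(snapshot)
    records = []
    for v in members:
        dists = nx.single_source_shortest_path_length(sub.graph, v)
        hist: dict[int, int] = {}
        for j in cluster_members:
            if j != v and j in dists:
                hist[dists[j]] = hist.get(dists[j], 0) + 1
        m_dis, apn_value, delta = _delta_from_hist(hist, ne_values[v], apn)
        records.append(
            CohesionRecord(node=v, path_hist=hist, m_dis=m_dis, apn=apn_value, delta=delta)
        )
    return records


def condensed_nodes(
    assignment: ClusterAssignment,
    snapshot: InfectionSnapshot,
    table: EntropyTable,
    apn: str = "distinct",
    normalize_ne: bool = False,
) -> frozenset[str]:
    """C_s1: the per-cluster cohesion maximizers.

    Ties broken by larger NE, then smaller node id.
    """
    if not assignment.clusters:
        raise ValueError("cluster assignment is empty")
    out = set()
    for cluster in assignment.clusters:
        records = cluster_cohesion_records(
            cluster.members, snapshot, table, apn=apn, normalize_ne=normalize_ne
        )
        best = max(records, key=lambda r: (r.delta, table.ne(r.node)))
        winners = [
            r.node
            for r in records
            if r.delta == best.delta and table.ne(r.node) == table.ne(best.node)
        ]
        out.add(min(winners))
    return frozenset(out)


def slbic(
    network: ContactNetwork,
    snapshot: InfectionSnapshot,
    alpha: float = DEFAULT_ALPHA,
    eta_neighbors: str = "infected",
    apn: str = "distinct",
    normalize_ne: bool = False,
) -> LocalizationResult:
    """Source localization by infection cluster: S-hat = C_s ∪ C_s1.

    Runs the neighborhood-entropy stack, divides the infected set into
    clusters around the core convex set, then adds each cluster's condensed
    node.  The prediction always contains the SLBNE prediction, so
    |C_s| <= |S-hat| <= 2 |C_s|.
    """
    if snapshot.network is not network:
        snapshot = InfectionSnapshot(network=network, infected=snapshot.infected)
    table = compute_entropy_table(snapshot, alpha=alpha, eta_neighbors=eta_neighbors)
    core = core_convex_set(snapshot, table)
    assignment = divide_clusters(snapshot, core, table=table)
    extra = set()
    delta: dict[str, float] = {}
    for cluster in assignment.clusters:
        records = cluster_cohesion_records(
            cluster.members, snapshot, table, apn=apn, normalize_ne=normalize_ne
        )
        for r in records:
            delta[r.node] = r.delta
        best = max(records, key=lambda r: (r.delta, table.ne(r.node)))
        winners = [
            r.node
            for r in records
            if r.delta == best.delta and table.ne(r.node) == table.ne(best.node)
        ]
        extra.add(min(winners))
    extra = frozenset(extra)
    return LocalizationResult(
        method="SLBIC",
        predicted=core.members | extra,
        core_part=core.members,
        condensed_part=extra,
        table=table,
        clusters=assignment,
        delta=delta,
    )
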