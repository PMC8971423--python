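"""Infection cluster division (ICD): split V_I into r clusters around cores.

Given the core convex set, the infected node set is divided into r = |C_s|
infection clusters in two steps:

1. every infected node directly adjacent to at least one core joins the
   cluster of the core it is most similar to, where similarity between two
   nodes combines their direct common-neighbor overlap with the pairwise
   overlap of their neighborhoods (a second-order common-neighbor index);
2. the remaining infected nodes are swept breadth-first outward from the
   assigned frontier, each joining the cluster(s) it shares the most edges
   with among already-assigned neighbors — an exact tie places the node in
   every tied cluster (overlapping membership).

All neighborhoods here are taken in the infected subgraph: the division
operates on the infection network, not the full contact graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .network import ContactNetwork, InfectionSnapshot, infected_subgraph
from .entropy import CoreSet, EntropyTable

__all__ = [
    "Cluster",
    "ClusterAssignment",
    "common_neighbors",
    "similarity",
    "divide_clusters",
]


@dataclass(frozen=True)
class Cluster:
    core: str
    members: frozenset[str]


@dataclass(frozen=True)
class ClusterAssignment:
    """r infection clusters, one per core; membership may overlap on ties."""

    clusters: tuple[Cluster, ...]
    membership: dict[str, frozenset[int]]

    @property
    def r(self) -> int:
        return len(self.clusters)

    def members_of(self, index: int) -> frozenset[str]:
        return self.clusters[index].members

    def covered(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.clusters:
            out |= c.members
        return frozenset(out)


def common_neighbors(x: str, y: str, network: ContactNetwork) -> int:
    """Com(x, y) = |N(x) ∩ N(y)|, with the convention Com(x, x) = |N(x)|."""
    if x == y:
        return network.degree(x)
    return len(network.neighbors(x) & network.neighbors(y))


def similarity(n1: str, n2: str, network: ContactNetwork) -> float:
    """Second-order common-neighbor similarity between two distinct nodes.

    Sim(n1, n2) = Com(n1, n2)/|N(n1) ∪ N(n2)|
                + sum over i in N(n1), j in N(n2) of Com(i, j)/|N(i) ∪ N(j)|.

    The double sum includes every pair literally, i = j included (handled by
    the Com(x, x) convention, where the ratio is 1 for any non-isolated
    node).  A ratio with an empty neighborhood union is taken as 0.
    Symmetric in its arguments; 0 when no common neighbors exist at either
    level.
    """

    def ratio(a: str, b: str) -> float:
        if a == b:
            return 1.0 if network.degree(a) > 0 else 0.0
        union = len(network.neighbors(a) | network.neighbors(b))
        if union == 0:
            return 0.0
        return common_neighbors(a, b, network) / union

    total = ratio(n1, n2)
    for i in sorted(network.neighbors(n1)):
        for j in sorted(network.neighbors(n2)):
            total += ratio(i, j)
    return total


def divide_clusters(
    snapshot: InfectionSnapshot,
    core: CoreSet,
    table: EntropyTable | None = None,
) -> ClusterAssignment:
    """Two-step division of the infected set into r = |C_s| clusters.

    Step 1 assigns every infected direct neighbor of a core to the cluster
    of the most similar core (similarity in the infected subgraph; ties go
    to the core with larger NE when a table is supplied, then to the
    smaller core id).  Step 2 sweeps the remaining infected nodes in
    deterministic breadth-first order from the assigned frontier — nodes at
    equal depth in ascending id order — each joining the cluster(s) with
    which it shares the most edges among already-assigned neighbors; exact
    ties join all tied clusters.  Infected nodes never reached by the sweep
    (disconnected from every core in the infected subgraph) fall back to
    the cluster whose core is nearest by shortest path, ties to the
    smallest cluster index.  Cores belong to their own cluster only.
    """
    if not core.members:
        raise ValueError("core set must be non-empty")
    if not core.members <= snapshot.infected:
        raise ValueError("all core members must be infected")

    sub = infected_subgraph(snapshot)
    cores = sorted(core.members)  # cluster index = position in this order
    core_index = {c: k for k, c in enumerate(cores)}
    membership: dict[str, set[int]] = {c: {core_index[c]} for c in cores}

    def ne(v: str) -> float:
        return table.ne(v) if table is not None else 0.0

    # step 1 — direct neighbors of cores, by second-order similarity
    frontier_nodes = sorted(
        {v for c in cores for v in sub.neighbors(c)} - core.members
    )
    for v in frontier_nodes:
        # tie-break: larger similarity, then larger core NE, then smaller id.
        # Common-neighbor similarity vanishes identically on tree-like
        # regions, so the argmax only ranges over cores with positive
        # similarity; when none exists the node stays with a core it is
        # actually adjacent to, keeping disconnected components separate.
        sims = [(similarity(v, c, sub), ne(c), c) for c in cores]
        pool = [t for t in sims if t[0] > 0.0]
        if not pool:
            adjacent = sub.neighbors(v)
            pool = [t for t in sims if t[2] in adjacent]
        best_sim = max(s for s, _, _ in pool)
        best_ne = max(n for s, n, _ in pool if s == best_sim)
        winner = min(c for s, n, c in pool if s == best_sim and n == best_ne)
        membership[v] = {core_index[winner]}

    # step 2 — BFS sweep outward from the assigned frontier
    assigned = set(membership)
    level = sorted(
        {v for a in assigned for v in sub.neighbors(a)} - assigned
    )
    seen = assigned | set(level)
    while level:
        next_level: set[str] = set()
        for v in level:
            counts: dict[int, int] = {}
            for u in sub.neighbors(v):
                for k in membership.get(u, ()):
                    counts[k] = counts.get(k, 0) + 1
            if counts:
                top = max(counts.values())
                membership[v] = {k for k, c in counts.items() if c == top}
                assigned.add(v)
            for u in sub.neighbors(v):
                if u not in seen:
                    next_level.add(u)
                    seen.add(u)
        level = sorted(next_level)

    # disconnected leftovers: nearest core by shortest path in the infected
    # subgraph; unreachable distances compare as infinity, ties to the
    # smallest cluster index
    leftovers = sorted(snapshot.infected - set(membership))
    if leftovers:
        dist_from_core = {
            c: nx.single_source_shortest_path_length(sub.graph, c) for c in cores
        }
        for v in leftovers:
            dists = [
                (dist_from_core[c].get(v, float("inf")), core_index[c]) for c in cores
            ]
            membership[v] = {min(dists)[1]}

    members: list[set[str]] = [set() for _ in cores]
    for v, ks in membership.items():
        for k in ks:
            members[k].add(v)
    clusters = tuple(
        Cluster(core=c, members=frozenset(members[k])) for k, c in enumerate(cores)
    )
    return ClusterAssignment(
        clusters=clusters,
        membership={v: frozenset(ks) for v, ks in membership.items()},
    )
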