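"""Contact networks and infection snapshots: containers, readers, writers.

A contact network is an undirected simple graph over opaque string node
identifiers, optionally carrying a symmetric per-edge transmission
probability ``P_uv`` strictly inside (0, 1).  An infection snapshot is the
observed set of infected nodes ``V_I`` on such a network, from which source
localization starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "ContactNetwork",
    "InfectionSnapshot",
    "EdgeListParseError",
    "SnapshotParseError",
    "ValidationError",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "read_snapshot",
    "write_snapshot",
    "bundled_network",
    "infected_subgraph",
]


class EdgeListParseError(ValueError):
    """A malformed line was encountered while parsing an edge list."""


class SnapshotParseError(ValueError):
    """A malformed row was encountered while parsing a snapshot CSV."""


class ValidationError(ValueError):
    """Input violates a structural invariant (self-loop, bad probability, ...)."""


# Edge attribute under which the transmission probability is stored.
PROB_KEY = "p"


class ContactNetwork:
    """Undirected contact network with optional per-edge transmission probabilities.

    Thin wrapper around :class:`networkx.Graph` that enforces the container
    invariants: no self-loops, opaque string node ids, and — when
    probabilities are present — one probability per edge, strictly in (0, 1),
    symmetric by construction (the graph is undirected).
    """

    def __init__(self, graph: nx.Graph):
        self._validate(graph)
        self.graph = graph

    @staticmethod
    def _validate(graph: nx.Graph) -> None:
        if graph.is_directed() or graph.is_multigraph():
            raise ValidationError("contact networks are undirected simple graphs")
        loops = list(nx.selfloop_edges(graph))
        if loops:
            raise ValidationError(f"self-loops are not allowed: {loops[:3]}")
        n_with_p = sum(1 for _, _, d in graph.edges(data=True) if PROB_KEY in d)
        if n_with_p not in (0, graph.number_of_edges()):
            raise ValidationError(
                "edge probabilities must be present on every edge or on none"
            )
        for u, v, d in graph.edges(data=True):
            if PROB_KEY in d and not (0.0 < float(d[PROB_KEY]) < 1.0):
                raise ValidationError(
                    f"edge probability for ({u}, {v}) must lie strictly in (0, 1), "
                    f"got {d[PROB_KEY]}"
                )

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        edge_prob: Mapping[tuple[str, str], float] | None = None,
    ) -> "ContactNetwork":
        """Build a network from an edge iterable (+ optional isolated nodes)."""
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        for u, v in edges:
            g.add_edge(str(u), str(v))
        if edge_prob is not None:
            for (u, v), p in edge_prob.items():
                u, v = str(u), str(v)
                if not g.has_edge(u, v):
                    raise ValidationError(f"probability given for missing edge ({u}, {v})")
                g.edges[u, v][PROB_KEY] = float(p)
        return cls(g)

    # -- container views -------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset((u, v)) for u, v in self.graph.edges)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, v: str) -> set[str]:
        return set(self.graph.neighbors(v))

    def degree(self, v: str) -> int:
        return self.graph.degree(v)

    @property
    def has_probabilities(self) -> bool:
        if self.graph.number_of_edges() == 0:
            return False
        _, _, d = next(iter(self.graph.edges(data=True)))
        return PROB_KEY in d

    def probability(self, u: str, v: str) -> float:
        """Transmission probability on edge (u, v); symmetric by construction."""
        try:
            return float(self.graph.edges[u, v][PROB_KEY])
        except KeyError as exc:
            raise ValidationError(
                f"no probability stored on edge ({u}, {v})"
            ) from exc

    @property
    def edge_prob(self) -> dict[frozenset[str], float] | None:
        if not self.has_probabilities:
            return None
        return {
            frozenset((u, v)): float(d[PROB_KEY])
            for u, v, d in self.graph.edges(data=True)
        }

    def with_probabilities(
        self, mapping: Mapping[tuple[str, str] | frozenset[str], float]
    ) -> "ContactNetwork":
        """Return a copy with the given probability on every edge."""
        g = self.graph.copy()
        for key, p in mapping.items():
            u, v = tuple(key)
            if not g.has_edge(u, v):
                raise ValidationError(f"probability given for missing edge ({u}, {v})")
            g.edges[u, v][PROB_KEY] = float(p)
        return ContactNetwork(g)

    def copy(self) -> "ContactNetwork":
        return ContactNetwork(self.graph.copy())

    def __contains__(self, v: str) -> bool:
        return v in self.graph

    def __eq__(self, other) -> bool:
        if not isinstance(other, ContactNetwork):
            return NotImplemented
        if self.nodes != other.nodes or self.edges != other.edges:
            return False
        return self.edge_prob == other.edge_prob

    def __repr__(self) -> str:
        return (
            f"ContactNetwork(|V|={self.number_of_nodes()}, "
            f"|E|={self.number_of_edges()}, "
            f"probabilities={self.has_probabilities})"
        )


@dataclass(frozen=True)
class InfectionSnapshot:
    """Observed infected node set ``V_I`` over a contact network.

    ``infected`` must be a non-empty subset of the network's nodes.  The
    accessors split each node's neighborhood into its infected part ``I_i``
    and uninfected part ``U_i`` (full-network neighborhoods).
    """

    network: ContactNetwork
    infected: frozenset[str] = field()

    def __post_init__(self):
        object.__setattr__(self, "infected", frozenset(str(v) for v in self.infected))
        if not self.infected:
            raise ValidationError("infected set must be non-empty")
        missing = self.infected - self.network.nodes
        if missing:
            raise ValidationError(f"infected nodes not in network: {sorted(missing)[:5]}")

    def is_infected(self, v: str) -> bool:
        return v in self.infected

    def infected_neighbors(self, i: str) -> set[str]:
        """I_i = N(i) ∩ V_I."""
        return self.network.neighbors(i) & self.infected

    def uninfected_neighbors(self, i: str) -> set[str]:
        """U_i = N(i) \\ V_I."""
        return self.network.neighbors(i) - self.infected

    def subgraph(self) -> ContactNetwork:
        return infected_subgraph(self)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> ContactNetwork:
    """Read a 2- or 3-column edge list (whitespace- or comma-separated).

    Lines starting with ``#`` and blank lines are skipped.  A third column,
    when present, is the transmission probability of the edge and must lie
    strictly in (0, 1).  Duplicate and reversed-duplicate edges collapse to a
    single undirected edge; for a duplicated probability the last value wins.
    """
    path = Path(path)
    g = nx.Graph()
    saw_prob = False
    saw_bare = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) not in (2, 3):
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(tokens)}"
                )
            u, v = tokens[0], tokens[1]
            if u == v:
                raise ValidationError(f"{path}:{lineno}: self-loop on node {u!r}")
            if len(tokens) == 3:
                saw_prob = True
                try:
                    p = float(tokens[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: third column {tokens[2]!r} is not a float"
                    ) from exc
                if not (0.0 < p < 1.0):
                    raise ValidationError(
                        f"{path}:{lineno}: probability {p} outside (0, 1)"
                    )
                g.add_edge(u, v, **{PROB_KEY: p})
            else:
                saw_bare = True
                if g.has_edge(u, v):
                    continue  # keep any probability already parsed
                g.add_edge(u, v)
    if saw_prob and saw_bare:
        raise ValidationError(
            f"{path}: probabilities must be given on every edge or on none"
        )
    return ContactNetwork(g)


def write_edge_list(network: ContactNetwork, path: str | Path) -> None:
    """Write a network back out in the same edge-list dialect (sorted edges)."""
    path = Path(path)
    with path.open("w") as fh:
        for v in sorted(network.nodes):
            if network.degree(v) == 0:
                fh.write(f"# isolated {v}\n")
        for u, v in sorted(tuple(sorted(e)) for e in network.edges):
            if network.has_probabilities:
                fh.write(f"{u} {v} {network.probability(u, v):.12g}\n")
            else:
                fh.write(f"{u} {v}\n")


def read_graphml(path: str | Path) -> ContactNetwork:
    """Read a GraphML file; an edge attribute ``p`` maps to the probability."""
    g = nx.read_graphml(Path(path))
    out = nx.Graph()
    out.add_nodes_from(str(n) for n in g.nodes)
    for u, v, d in g.edges(data=True):
        attrs = {PROB_KEY: float(d[PROB_KEY])} if PROB_KEY in d else {}
        out.add_edge(str(u), str(v), **attrs)
    return ContactNetwork(out)


def read_snapshot(path: str | Path, network: ContactNetwork) -> InfectionSnapshot:
    """Read a node-state CSV (header ``node,state``; state in {S, I}).

    Nodes absent from the file default to susceptible.  Unknown states and
    node ids not in the network are errors; an all-susceptible file violates
    the non-empty-infected invariant and raises ``ValidationError``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    expected = ["node", "state"]
    if list(df.columns[:2]) != expected:
        raise SnapshotParseError(
            f"{path}: expected header 'node,state', got {list(df.columns)}"
        )
    bad = df.loc[~df["state"].isin(["S", "I"]), "state"]
    if not bad.empty:
        raise SnapshotParseError(f"{path}: unknown state token(s) {sorted(set(bad))}")
    unknown = set(df["node"]) - network.nodes
    if unknown:
        raise ValidationError(f"{path}: node(s) not in network: {sorted(unknown)[:5]}")
    infected = frozenset(df.loc[df["state"] == "I", "node"])
    return InfectionSnapshot(network=network, infected=infected)


def write_snapshot(snapshot: InfectionSnapshot, path: str | Path) -> None:
    rows = [
        {"node": v, "state": "I" if v in snapshot.infected else "S"}
        for v in sorted(snapshot.network.nodes)
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def infected_subgraph(snapshot: InfectionSnapshot) -> ContactNetwork:
    """Subgraph induced on the infected set; probabilities carried over."""
    sub = snapshot.network.graph.subgraph(snapshot.infected).copy()
    return ContactNetwork(sub)


# ---------------------------------------------------------------------------
# Bundled fixture: Zachary's karate club (34 nodes, 78 edges)
# ---------------------------------------------------------------------------

_KARATE_EDGES = """\
0,1 0,2 0,3 0,4 0,5 0,6 0,7 0,8 0,10 0,11
0,12 0,13 0,17 0,19 0,21 0,31 1,2 1,3 1,7 1,13
1,17 1,19 1,21 1,30 2,3 2,7 2,8 2,9 2,13 2,27
2,28 2,32 3,7 3,12 3,13 4,6 4,10 5,6 5,10 5,16
6,16 8,30 8,32 8,33 9,33 13,33 14,32 14,33 15,32 15,33
18,32 18,33 19,33 20,32 20,33 22,32 22,33 23,25 23,27 23,29
23,32 23,33 24,25 24,27 24,31 25,31 26,29 26,33 27,33 28,31
28,33 29,32 29,33 30,32 30,33 31,32 31,33 32,33
"""


def bundled_network(name: str) -> ContactNetwork:
    """Return a bundled fixture network by name.

    Currently only ``"karate"`` — Zachary's karate club, the classic 34-node
    social network — is bundled (embedded in source, no download).
    """
    if name != "karate":
        raise KeyError(f"no bundled network named {name!r}; available: ['karate']")
    edges = [tuple(tok.split(",")) for tok in _KARATE_EDGES.split()]
    return ContactNetwork.from_edges(edges)
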