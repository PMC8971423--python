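"""Neighborhood-entropy scoring and the SLBNE locator.

The score stack, evaluated on an infection snapshot:

* infection intensity  xi_i  = (|N(i)| - |U_i|) / |N(i)| * 1/(1 + e^{-|N(i)|})
  — the fraction of infected neighbors, discounted towards 0 for nodes whose
  neighborhood is mostly uninfected, with a sigmoid factor that damps the
  degree dependence.  Full-network neighborhood: counting uninfected
  neighbors is the point of this score.
* infection intensity entropy  IE_i = -xi_i log2 xi_i  (0 log 0 := 0).
* infection degree  eta_j = sum_t (1/|N(t)|) xi_t over j's infected
  neighbors t — how plausibly j is the parent of its neighborhood.
* contribution  psi_i(j) = (1/|N(i)|) / eta_j — i's share of j's infection
  degree; may exceed 1.
* infection adjacency entropy  AE_i = -sum_j psi_i(j) log2 psi_i(j) over
  infected neighbors j; psi > 1 terms contribute negatively and are kept.
* neighborhood entropy  NE_i = AE_i - alpha * IE_i, the node-level source
  score (alpha defaults to 4).

A node whose NE strictly exceeds the NE of every infected neighbor is a core
convex node; the core convex set C_s is the SLBNE prediction.  The entropy
sums (eta, psi, AE) run over infected neighbors only, so that eta_j > 0 for
every infected j with an infected neighbor; degrees 1/|N(.)| are always
full-network degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .network import ContactNetwork, InfectionSnapshot

__all__ = [
    "EntropyTable",
    "CoreSet",
    "LocalizationResult",
    "DegenerateNeighborhoodError",
    "infection_intensity",
    "intensity_entropy",
    "infection_degree",
    "contribution",
    "adjacency_entropy",
    "neighborhood_entropy",
    "compute_entropy_table",
    "core_convex_set",
    "slbne",
]

DEFAULT_ALPHA = 4.0


class DegenerateNeighborhoodError(ValueError):
    """A contribution ratio was requested against a zero infection degree."""


@dataclass(frozen=True)
class EntropyTable:
    """Per-node entropy scores for every infected node of a snapshot.

    ``scores`` is a DataFrame indexed by node id with columns
    ``xi, ie, eta, ae, ne``; ``alpha`` is the intensity-entropy weight used.
    """

    alpha: float
    scores: pd.DataFrame
    eta_neighbors: str = "infected"

    def xi(self, node: str) -> float:
        return float(self.scores.at[node, "xi"])

    def ie(self, node: str) -> float:
        return float(self.scores.at[node, "ie"])

    def eta(self, node: str) -> float:
        return float(self.scores.at[node, "eta"])

    def ae(self, node: str) -> float:
        return float(self.scores.at[node, "ae"])

    def ne(self, node: str) -> float:
        return float(self.scores.at[node, "ne"])

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.scores.index)


@dataclass(frozen=True)
class CoreSet:
    """The core convex set C_s: local NE maxima among infected nodes."""

    members: frozenset[str]
    fallback_used: bool = False

    @property
    def r(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class LocalizationResult:
    """Predicted sources with the evidence behind them.

    ``predicted`` is always ``core_part | condensed_part``; for SLBNE the
    condensed part is empty.  ``delta`` (cohesion scores) and ``clusters``
    are attached by SLBIC only.
    """

    method: str
    predicted: frozenset[str]
    core_part: frozenset[str]
    condensed_part: frozenset[str]
    table: EntropyTable | None = None
    clusters: object | None = None
    delta: dict[str, float] | None = None

    def __post_init__(self):
        if not self.predicted:
            raise ValueError("a localization result must predict at least one node")
        if self.predicted != self.core_part | self.condensed_part:
            raise ValueError("predicted must equal core_part | condensed_part")


# ---------------------------------------------------------------------------
# Score stack
# ---------------------------------------------------------------------------

def infection_intensity(i: str, snapshot: InfectionSnapshot) -> float:
    """xi_i: infected-neighbor fraction with the sigmoid degree correction.

    Uses the full-network neighborhood of ``i``.  An isolated node has no
    neighborhood to measure; its intensity is returned as 0 with a warning.
    """
    deg = snapshot.network.degree(i)
    if deg == 0:
        warnings.warn(f"infection intensity of isolated node {i!r} is undefined; using 0")
        return 0.0
    n_uninfected = len(snapshot.uninfected_neighbors(i))
    return ((deg - n_uninfected) / deg) * (1.0 / (1.0 + math.exp(-deg)))


def intensity_entropy(xi: float) -> float:
    """IE = -xi log2 xi in bits, with the 0 log 0 := 0 convention."""
    if not (0.0 <= xi <= 1.0):
        raise ValueError(f"intensity must lie in [0, 1], got {xi}")
    if xi == 0.0:
        return 0.0
    return -xi * math.log2(xi)


def infection_degree(
    j: str, snapshot: InfectionSnapshot, neighbors: str = "infected"
) -> float:
    """eta_j = sum over neighbors t of (1/|N(t)|) * xi_t.

    ``neighbors="infected"`` (default) restricts the sum to infected
    neighbors of ``j``; ``"all"`` sums over the full neighborhood.  Degrees
    |N(t)| are full-network degrees either way.
    """
    if neighbors == "infected":
        terms = snapshot.infected_neighbors(j)
    elif neighbors == "all":
        terms = snapshot.network.neighbors(j)
    else:
        raise ValueError(f"neighbors must be 'infected' or 'all', got {neighbors!r}")
    total = 0.0
    for t in terms:
        deg_t = snapshot.network.degree(t)
        if deg_t == 0:  # unreachable for a neighbor, kept for safety
            continue
        total += (1.0 / deg_t) * infection_intensity(t, snapshot)
    return total


def contribution(
    i: str, j: str, snapshot: InfectionSnapshot, eta_neighbors: str = "infected"
) -> float:
    """psi_i(j) = (1/|N(i)|) / eta_j — i's share of j's infection degree."""
    eta_j = infection_degree(j, snapshot, neighbors=eta_neighbors)
    if eta_j <= 0.0:
        raise DegenerateNeighborhoodError(
            f"infection degree of {j!r} is zero; contribution of {i!r} is undefined"
        )
    return (1.0 / snapshot.network.degree(i)) / eta_j


def adjacency_entropy(
    i: str, snapshot: InfectionSnapshot, eta_neighbors: str = "infected"
) -> float:
    """AE_i = -sum over infected neighbors j of psi_i(j) log2 psi_i(j).

    psi > 1 yields a negative term; nothing is clamped, so AE may be
    negative.  A node with no infected neighbors has AE := 0.
    """
    infected_nb = snapshot.infected_neighbors(i)
    if not infected_nb:
        return 0.0
    total = 0.0
    for j in infected_nb:
        psi = contribution(i, j, snapshot, eta_neighbors=eta_neighbors)
        total -= psi * math.log2(psi)
    return total


def neighborhood_entropy(
    i: str,
    snapshot: InfectionSnapshot,
    alpha: float = DEFAULT_ALPHA,
    eta_neighbors: str = "infected",
) -> float:
    """NE_i = AE_i - alpha * IE_i."""
    ae = adjacency_entropy(i, snapshot, eta_neighbors=eta_neighbors)
    ie = intensity_entropy(infection_intensity(i, snapshot))
    return ae - alpha * ie


def compute_entropy_table(
    snapshot: InfectionSnapshot,
    alpha: float = DEFAULT_ALPHA,
    eta_neighbors: str = "infected",
) -> EntropyTable:
    """Evaluate the full score stack for every infected node."""
    rows = {}
    for i in sorted(snapshot.infected):
        xi = infection_intensity(i, snapshot)
        ie = intensity_entropy(xi)
        eta = infection_degree(i, snapshot, neighbors=eta_neighbors)
        ae = adjacency_entropy(i, snapshot, eta_neighbors=eta_neighbors)
        rows[i] = {"xi": xi, "ie": ie, "eta": eta, "ae": ae, "ne": ae - alpha * ie}
    scores = pd.DataFrame.from_dict(rows, orient="index")
    scores.index.name = "node"
    return EntropyTable(alpha=alpha, scores=scores, eta_neighbors=eta_neighbors)


def core_convex_set(snapshot: InfectionSnapshot, table: EntropyTable) -> CoreSet:
    """C_s: infected nodes whose NE strictly exceeds every infected neighbor's.

    Infected nodes with no infected neighbor qualify vacuously (a plausible
    un-spread source).  If the strict rule selects nothing — as on perfectly
    symmetric snapshots where all NE values tie — fall back to the single
    node of globally maximal NE (ties broken by smallest node id).
    """
    members = set()
    for i in snapshot.infected:
        nb = snapshot.infected_neighbors(i)
        if not nb:
            members.add(i)
        elif table.ne(i) > max(table.ne(j) for j in nb):
            members.add(i)
    if members:
        return CoreSet(members=frozenset(members))
    best = min(sorted(snapshot.infected), key=lambda v: (-table.ne(v), v))
    return CoreSet(members=frozenset({best}), fallback_used=True)


def slbne(
    network: ContactNetwork,
    snapshot: InfectionSnapshot,
    alpha: float = DEFAULT_ALPHA,
    eta_neighbors: str = "infected",
) -> LocalizationResult:
    """Source localization by neighborhood entropy: predict S-hat = C_s."""
    if snapshot.network is not network:
        snapshot = InfectionSnapshot(network=network, infected=snapshot.infected)
    table = compute_entropy_table(snapshot, alpha=alpha, eta_neighbors=eta_neighbors)
    core = core_convex_set(snapshot, table)
    return LocalizationResult(
        method="SLBNE",
        predicted=core.members,
        core_part=core.members,
        condensed_part=frozenset(),
        table=table,
    )
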