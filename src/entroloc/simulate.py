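"""Discrete-time SI diffusion on contact networks.

The susceptible–infected (SI) model: every node is either susceptible (S) or
infected (I); infected nodes never recover.  At each discrete step every
infected node ``u`` independently attempts to infect each susceptible
neighbor ``v`` with the per-edge probability ``P_uv``, so the one-step hazard
for a susceptible node is

    lambda(v) = 1 - prod_{u in I_v} (1 - P_uv),

the complement of all attempts failing.  Updates are synchronous: all
infections at step ``t`` are computed from the state at ``t - 1``.  The run
stops at the first step after which the infected fraction strictly exceeds
``stop_fraction`` (default 0.30), or at ``max_steps``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ContactNetwork, InfectionSnapshot, PROB_KEY, ValidationError

__all__ = [
    "SimulationConfig",
    "SimulationTrace",
    "assign_edge_probabilities",
    "step_hazard",
    "simulate",
    "sample_sources",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Run parameters for one SI diffusion.

    stop_fraction : stop once the infected fraction strictly exceeds this
        (default 0.30); must lie in (0, 1].
    max_steps : hard cap on steps; ``None`` means 10 * |V|, a safety cap that
        guarantees termination on pathological inputs.
    seed : RNG seed for the infection draws.
    """

    stop_fraction: float = 0.30
    max_steps: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.stop_fraction <= 1.0):
            raise ValueError(f"stop_fraction must lie in (0, 1], got {self.stop_fraction}")
        if self.max_steps is not None and self.max_steps < 1:
            raise ValueError(f"max_steps must be >= 1, got {self.max_steps}")


@dataclass(frozen=True)
class SimulationTrace:
    """Outcome of one diffusion run.

    sources : the seed set S* (all at infection time 0).
    infection_time : step at which each infected node turned I.
    final_snapshot : the observed snapshot at the stop step.
    steps_run : number of synchronous steps executed.
    """

    sources: frozenset[str]
    infection_time: dict[str, int]
    final_snapshot: InfectionSnapshot
    steps_run: int


def assign_edge_probabilities(network: ContactNetwork, seed: int) -> ContactNetwork:
    """Draw an independent Uniform(0, 1) transmission probability per edge.

    The draw is symmetric (one value per undirected edge) and reproducible
    from ``seed``.  Values are nudged away from exact 0/1 so the open-interval
    invariant holds even for degenerate float draws.
    """
    rng = np.random.default_rng(seed)
    edges = sorted(tuple(sorted(e)) for e in network.edges)
    draws = rng.uniform(0.0, 1.0, size=len(edges))
    eps = 1e-12
    draws = np.clip(draws, eps, 1.0 - eps)
    g = network.graph.copy()
    for (u, v), p in zip(edges, draws):
        g.edges[u, v][PROB_KEY] = float(p)
    return ContactNetwork(g)


def step_hazard(v: str, snapshot: InfectionSnapshot) -> float:
    """One-step infection probability of susceptible ``v`` given the snapshot.

    Returns ``1 - prod_{u in I_v} (1 - P_uv)`` over currently infected
    neighbors ``u``; 0 when no neighbor is infected.
    """
    network = snapshot.network
    infected_nb = snapshot.infected_neighbors(v)
    if not infected_nb:
        return 0.0
    if not network.has_probabilities:
        raise ValidationError(
            "step_hazard requires edge probabilities; call assign_edge_probabilities first"
        )
    survive = 1.0
    for u in infected_nb:
        survive *= 1.0 - network.probability(u, v)
    return 1.0 - survive


def simulate(
    network: ContactNetwork,
    sources: set[str] | frozenset[str],
    config: SimulationConfig = SimulationConfig(),
) -> SimulationTrace:
    """Run one synchronous SI diffusion from ``sources``.

    Each step, every susceptible node with at least one infected neighbor is
    infected with its current ``step_hazard``.  The loop ends at the first
    step where the infected fraction strictly exceeds ``config.stop_fraction``
    (checked after each full step, and before the first step in case the
    seeds already exceed it), or at ``max_steps``.
    """
    sources = frozenset(str(s) for s in sources)
    if not sources:
        raise ValueError("sources must be non-empty")
    if not sources <= network.nodes:
        raise ValueError(f"sources not in network: {sorted(sources - network.nodes)[:5]}")
    if not network.has_probabilities:
        raise ValidationError(
            "simulate requires edge probabilities; call assign_edge_probabilities first"
        )

    n = network.number_of_nodes()
    max_steps = config.max_steps if config.max_steps is not None else 10 * n
    rng = np.random.default_rng(config.seed)

    infected: set[str] = set(sources)
    infection_time = {s: 0 for s in sources}
    step = 0
    while len(infected) / n <= config.stop_fraction and step < max_steps:
        # frontier of susceptibles adjacent to the infected set, in sorted
        # order so draws are reproducible from the seed alone
        frontier = sorted(
            {v for u in infected for v in network.neighbors(u)} - infected
        )
        if not frontier:
            break
        step += 1
        snap = InfectionSnapshot(network=network, infected=frozenset(infected))
        hazards = [step_hazard(v, snap) for v in frontier]
        draws = rng.uniform(size=len(frontier))
        newly = [v for v, h, d in zip(frontier, hazards, draws) if d < h]
        for v in newly:
            infected.add(v)
            infection_time[v] = step

    final = InfectionSnapshot(network=network, infected=frozenset(infected))
    return SimulationTrace(
        sources=sources,
        infection_time=infection_time,
        final_snapshot=final,
        steps_run=step,
    )


def sample_sources(network: ContactNetwork, m: int, seed: int) -> frozenset[str]:
    """Draw ``m`` distinct source nodes uniformly without replacement."""
    nodes = sorted(network.nodes)
    if not (1 <= m <= len(nodes)):
        raise ValueError(f"m must lie in [1, {len(nodes)}], got {m}")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(nodes), size=m, replace=False)
    return frozenset(nodes[i] for i in picked)
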