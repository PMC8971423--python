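"""Evaluation metrics, synthetic network generators, and the benchmark harness.

Metrics follow the standard source-detection protocol: precision, recall and
F-score (beta = 1) of the predicted source set against the true seeds, the
average error distance

    Delta = (1/|S*|) ( sum_{i in S*} min_{j in S-hat} dis(i, j)
                       + rho * | |S*| - |S-hat| | ),

with rho = 0.5 and shortest-path distances in the full contact network, and
the fraction of replicates in which the predicted source count equals the
true count.  The harness repeats the full protocol — sample seeds, draw
Uniform(0, 1) edge probabilities, diffuse until just over the stop fraction
is infected, locate, score — for a configurable number of replicates, all
reproducibly derived from one master seed.
"""

from __future__ import annotations


from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import ContactNetwork, InfectionSnapshot, bundled_network, read_edge_list
from .simulate import SimulationConfig, assign_edge_probabilities, sample_sources, simulate
from .entropy import slbne
from .cohesion import slbic

__all__ = [
    "EvalReport",
    "BenchmarkConfig",
    "BenchmarkResult",
    "precision_recall_f",
    "average_error_distance",
    "evaluate",
    "count_accuracy",
    "generate_er",
    "generate_ba",
    "random_baseline",
    "build_network",
    "run_benchmark",
]

DEFAULT_RHO = 0.5


@dataclass(frozen=True)
class EvalReport:
    """Scores of one predicted source set against the truth."""

    precision: float
    recall: float
    f_score: float
    avg_error_distance: float
    count_correct: bool


def precision_recall_f(
    predicted: frozenset[str] | set[str], truth: frozenset[str] | set[str]
) -> tuple[float, float, float]:
    """Precision, recall and F-score (beta = 1) of a source prediction.

    F is 0 when both precision and recall are 0; empty predictions score 0
    precision.  An empty truth set is an argument error.
    """
    truth = set(truth)
    predicted = set(predicted)
    if not truth:
        raise ValueError("truth set must be non-empty")
    hits = len(predicted & truth)
    precision = hits / len(predicted) if predicted else 0.0
    recall = hits / len(truth)
    if precision + recall == 0.0:
        return precision, recall, 0.0
    return precision, recall, 2 * precision * recall / (precision + recall)


def average_error_distance(
    predicted: frozenset[str] | set[str],
    truth: frozenset[str] | set[str],
    network: ContactNetwork,
    rho: float = DEFAULT_RHO,
) -> float:
    """Delta: mean nearest-prediction distance per true source, plus penalty.

    Distances are shortest paths in the full network; an unreachable
    (source, prediction) pair counts as |V|, a finite eccentricity cap so
    Delta stays defined on disconnected graphs.  The source-count mismatch
    penalty rho * ||S*| - |S-hat|| is added once, inside the 1/|S*| factor.
    Delta = 0 iff the sets are equal... up to count: exactly 0 when
    predicted == truth.
    """
    truth = set(truth)
    predicted = set(predicted)
    if not truth:
        raise ValueError("truth set must be non-empty")
    if not predicted:
        raise ValueError("predicted set must be non-empty")
    cap = network.number_of_nodes()
    total = 0.0
    for i in truth:
        dists = nx.single_source_shortest_path_length(network.graph, i)
        best = min((dists[j] for j in predicted if j in dists), default=cap)
        total += min(best, cap)
    total += rho * abs(len(truth) - len(predicted))
    return total / len(truth)


def evaluate(
    predicted: frozenset[str] | set[str],
    truth: frozenset[str] | set[str],
    network: ContactNetwork,
    rho: float = DEFAULT_RHO,
) -> EvalReport:
    """Full report: precision/recall/F, average error distance, count check."""
    precision, recall, f = precision_recall_f(predicted, truth)
    delta = average_error_distance(predicted, truth, network, rho=rho)
    return EvalReport(
        precision=precision,
        recall=recall,
        f_score=f,
        avg_error_distance=delta,
        count_correct=len(predicted) == len(truth),
    )


def count_accuracy(reports: list[EvalReport]) -> float:
    """Fraction of replicates whose predicted source count was exactly right."""
    if not reports:
        raise ValueError("need at least one report")
    return sum(r.count_correct for r in reports) / len(reports)


# ---------------------------------------------------------------------------
# Synthetic networks
# ---------------------------------------------------------------------------

def generate_er(n: int, mean_degree: float, seed: int) -> ContactNetwork:
    """Erdős–Rényi G(n, p) with p = mean_degree / (n - 1), string node ids."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not (0 < mean_degree < n):
        raise ValueError(f"mean_degree must lie in (0, {n}), got {mean_degree}")
    p = mean_degree / (n - 1)
    g = nx.fast_gnp_random_graph(n, p, seed=int(seed))
    return ContactNetwork.from_edges(g.edges, nodes=(str(v) for v in g.nodes))


def generate_ba(n: int, m_attach: int, seed: int) -> ContactNetwork:
    """Barabási–Albert preferential attachment, string node ids."""
    if not (1 <= m_attach < n):
        raise ValueError(f"m_attach must lie in [1, {n - 1}], got {m_attach}")
    g = nx.barabasi_albert_graph(n, m_attach, seed=int(seed))
    return ContactNetwork.from_edges(g.edges, nodes=(str(v) for v in g.nodes))


def random_baseline(snapshot: InfectionSnapshot, k: int, seed: int) -> frozenset[str]:
    """k infected nodes drawn uniformly at random — the chance-level control."""
    infected = sorted(snapshot.infected)
    if not (1 <= k <= len(infected)):
        raise ValueError(f"k must lie in [1, {len(infected)}], got {k}")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(infected), size=k, replace=False)
    return frozenset(infected[i] for i in picked)


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkConfig:
    """One benchmark cell: network family, diffusion and replication settings.

    network : "er", "ba", "karate", or a path to an edge-list file.
    n, mean_degree : ER size and target mean degree (fresh draw per
        replicate); m_attach likewise for BA.
    m : number of true sources sampled uniformly per replicate.
    stop_fraction : diffusion stops once the infected fraction strictly
        exceeds this (default 0.30).
    replicates : number of independent repetitions (protocol default 100).
    seed : master seed; every replicate's randomness is derived from it.
    alpha : intensity-entropy weight passed to the locators.
    """

    network: str = "er"
    n: int = 500
    mean_degree: float = 10.0
    m_attach: int = 5
    m: int = 5
    stop_fraction: float = 0.30
    replicates: int = 100
    seed: int = 0
    alpha: float = 4.0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-replicate scores plus the per-method summary table."""

    replicates: pd.DataFrame
    config: BenchmarkConfig

    def summary(self) -> pd.DataFrame:
        g = self.replicates.groupby("method")
        out = pd.DataFrame(
            {
                "mean_f": g["f_score"].mean(),
                "sd_f": g["f_score"].std(ddof=1).fillna(0.0),
                "mean_delta": g["avg_error_distance"].mean(),
                "sd_delta": g["avg_error_distance"].std(ddof=1).fillna(0.0),
                "mean_precision": g["precision"].mean(),
                "mean_recall": g["recall"].mean(),
                "count_acc": g["count_correct"].mean(),
            }
        )
        return out.reset_index()


def build_network(config: BenchmarkConfig, seed: int) -> ContactNetwork:
    """Materialize the configured network family (fresh synthetic draw)."""
    if config.network == "er":
        return generate_er(config.n, config.mean_degree, seed)
    if config.network == "ba":
        return generate_ba(config.n, config.m_attach, seed)
    if config.network == "karate":
        return bundled_network("karate")
    return read_edge_list(config.network)


def run_benchmark(
    config: BenchmarkConfig,
    methods: list[str] | dict[str, object] = ("slbne", "slbic", "random"),
) -> BenchmarkResult:
    """Repeat the full sample–diffuse–locate–score protocol.

    ``methods`` may list the built-ins "slbne", "slbic" and "random" (the
    random control is size-matched to SLBNE's prediction on the same
    replicate when SLBNE runs, otherwise it guesses m nodes), or map names
    to callables ``locator(network, snapshot, seed) -> node set``.
    Bit-reproducible from ``config.seed``: replicate seeds are spawned from
    one SeedSequence.
    """
    if isinstance(methods, (list, tuple)):
        method_spec: dict[str, object] = {name: name for name in methods}
    else:
        method_spec = dict(methods)

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.replicates)
    rows = []
    for rep, child in enumerate(children):
        sub_seeds = child.generate_state(4)
        network = build_network(config, int(sub_seeds[0]))
        sources = sample_sources(network, config.m, int(sub_seeds[1]))
        network = assign_edge_probabilities(network, int(sub_seeds[2]))
        trace = simulate(
            network,
            sources,
            SimulationConfig(
                stop_fraction=config.stop_fraction, seed=int(sub_seeds[3])
            ),
        )
        snapshot = trace.final_snapshot

        try:
            predictions: dict[str, frozenset[str]] = {}
            for name, spec in method_spec.items():
                if spec == "slbne":
                    predictions[name] = slbne(
                        network, snapshot, alpha=config.alpha
                    ).predicted
                elif spec == "slbic":
                    predictions[name] = slbic(
                        network, snapshot, alpha=config.alpha
                    ).predicted
                elif spec == "random":
                    if "slbne" in method_spec.values():
                        ref = next(
                            k for k, v in method_spec.items() if v == "slbne"
                        )
                        if ref not in predictions:
                            predictions[ref] = slbne(
                                network, snapshot, alpha=config.alpha
                            ).predicted
                        k = min(len(predictions[ref]), len(snapshot.infected))
                    else:
                        k = min(config.m, len(snapshot.infected))
                    baseline_seed = int(child.generate_state(5)[4])
                    predictions[name] = random_baseline(snapshot, k, baseline_seed)
                else:
                    predictions[name] = frozenset(spec(network, snapshot, int(sub_seeds[3])))
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"locator failed on replicate {rep}") from exc

        for name, predicted in predictions.items():
            report = evaluate(predicted, sources, network)
            rows.append(
                {
                    "replicate": rep,
                    "method": name,
                    "n_nodes": network.number_of_nodes(),
                    "n_infected": len(snapshot.infected),
                    "n_true": len(sources),
                    "n_predicted": len(predicted),
                    "precision": report.precision,
                    "recall": report.recall,
                    "f_score": report.f_score,
                    "avg_error_distance": report.avg_error_distance,
                    "count_correct": report.count_correct,
                }
            )
    return BenchmarkResult(replicates=pd.DataFrame(rows), config=config)
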