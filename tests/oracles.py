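"""Independent, naively-coded reference implementations used only by tests.

Everything here is written directly from the score definitions with plain
Python loops over a networkx graph and an infected set — no code shared
with the package under test.
"""

from __future__ import annotations

import itertools
import math


def naive_scores(graph, infected, alpha=4.0):
    """Per-node (xi, ie, eta, ae, ne) for every infected node, from scratch.

    Entropy sums run over infected neighbors; xi uses the full neighborhood.
    """
    infected = set(infected)

    def xi(i):
        nb = list(graph.neighbors(i))
        if not nb:
            return 0.0
        n_inf = sum(1 for t in nb if t in infected)
        return (n_inf / len(nb)) * (1.0 / (1.0 + math.exp(-len(nb))))

    def eta(j):
        total = 0.0
        for t in graph.neighbors(j):
            if t in infected:
                total += xi(t) / graph.degree(t)
        return total

    def ie(i):
        x = xi(i)
        return 0.0 if x == 0.0 else -x * math.log2(x)

    def ae(i):
        total = 0.0
        for j in graph.neighbors(i):
            if j not in infected:
                continue
            psi = (1.0 / graph.degree(i)) / eta(j)
            total -= psi * math.log2(psi)
        return total

    out = {}
    for i in infected:
        a, e = ae(i), ie(i)
        out[i] = (xi(i), e, eta(i), a, a - alpha * e)
    return out


def naive_core_set(graph, infected, alpha=4.0):
    """Strict local NE maxima among infected nodes, with the fallback rule."""
    infected = set(infected)
    ne = {i: s[4] for i, s in naive_scores(graph, infected, alpha).items()}
    core = set()
    for i in infected:
        nb = [j for j in graph.neighbors(i) if j in infected]
        if not nb or ne[i] > max(ne[j] for j in nb):
            core.add(i)
    if not core:
        core = {min(sorted(infected), key=lambda v: (-ne[v], v))}
    return core


def naive_cohesion(graph_infected, i, members, ne_i, apn_mode="distinct"):
    """delta_i from the definition, via explicit BFS over the infected subgraph.

    ``graph_infected`` is the infected subgraph as a networkx graph.
    """
    # plain BFS distances
    dist = {i: 0}
    queue = [i]
    while queue:
        nxt = []
        for u in queue:
            for v in graph_infected.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        queue = nxt
    hist = {}
    for j in members:
        if j != i and j in dist:
            hist[dist[j]] = hist.get(dist[j], 0) + 1
    if not hist:
        return 0.5 * ne_i
    m = max(hist)
    apn = len(hist) if apn_mode == "distinct" else sum(hist.values())
    term = sum((m + 1 - d) / (m + 1) * c / apn for d, c in hist.items())
    return 0.5 * term + 0.5 * ne_i


def naive_similarity(graph, n1, n2):
    """Second-order common-neighbor similarity, literal double sum."""

    def com(a, b):
        if a == b:
            return graph.degree(a)
        return len(set(graph.neighbors(a)) & set(graph.neighbors(b)))

    def ratio(a, b):
        union = set(graph.neighbors(a)) | set(graph.neighbors(b))
        if a == b:
            return 1.0 if graph.degree(a) > 0 else 0.0
        return com(a, b) / len(union) if union else 0.0

    total = ratio(n1, n2)
    for i, j in itertools.product(graph.neighbors(n1), graph.neighbors(n2)):
        total += ratio(i, j)
    return total


def naive_f_score(predicted, truth):
    predicted, truth = set(predicted), set(truth)
    hits = len(predicted & truth)
    p = hits / len(predicted) if predicted else 0.0
    r = hits / len(truth)
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def naive_error_distance(graph, predicted, truth, rho=0.5):
    """Delta by explicit per-source BFS with the |V| unreachable cap."""
    cap = graph.number_of_nodes()

    def bfs_dist(src):
        dist = {src: 0}
        queue = [src]
        while queue:
            nxt = []
            for u in queue:
                for v in graph.neighbors(u):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            queue = nxt
        return dist

    total = 0.0
    for i in truth:
        d = bfs_dist(i)
        total += min((min((d.get(j, cap) for j in predicted)), cap))
    total += rho * abs(len(truth) - len(predicted))
    return total / len(truth)
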