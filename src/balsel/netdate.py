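"""Median-joining haplotype networks, the rho statistic, and rho-based
coalescence dating.

The network follows the median-joining construction for binary data: start
from the minimum-spanning network (the union of all minimum spanning trees,
with an ``epsilon`` tolerance on the greedy distance levels) and iteratively
add median (Steiner) vectors — the site-wise majority of node triplets —
whenever they reduce the total connection cost; inferred nodes that end up
redundant (degree <= 2, unsampled) are pruned.

rho is the multiplicity-weighted mean mutational distance through the network
from a designated ancestral node to each derived sampled haplotype; dividing
by mu x L (mutation rate x locus length) converts it to an age.  The units of
the mutation rate (per site per year vs per site per generation) must be
declared explicitly — the conversion is never guessed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

PER_YEAR = "per_year"
PER_GENERATION = "per_generation"


@dataclass
class HaplotypeNetwork:
    """Condensed haplotype graph: nodes are distinct haplotypes (tuples of
    0/1), edges carry mutational step counts."""

    graph: nx.Graph
    multiplicity: dict[tuple, int]
    ancestral: tuple | None = None

    @property
    def sampled_nodes(self) -> list[tuple]:
        return [v for v, mult in self.multiplicity.items() if mult > 0]

    @property
    def median_nodes(self) -> list[tuple]:
        return [v for v in self.graph.nodes if self.multiplicity.get(v, 0) == 0]

    def total_cost(self) -> float:
        return float(sum(w for _, _, w in self.graph.edges.data("weight")))

    def edge_list(self) -> list[tuple[tuple, tuple, int]]:
        return [(u, v, int(w)) for u, v, w in self.graph.edges.data("weight")]


def _hamming(a: tuple, b: tuple) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_edges(nodes: list[tuple], epsilon: int = 0) -> list[tuple[tuple, tuple, int]]:
    """Minimum-spanning-network edges: process distance levels in increasing
    order; a pair at level d is linked if its endpoints are not already
    connected through links of level < d - epsilon."""
    dist = {}
    for u, v in itertools.combinations(nodes, 2):
        dist[(u, v)] = _hamming(u, v)
    edges = []
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for d in sorted(set(dist.values())):
        # connectivity as of levels < d - epsilon
        ref = nx.Graph()
        ref.add_nodes_from(nodes)
        ref.add_edges_from((u, v) for (u, v, w) in edges if w < d - epsilon)
        comp = {node: i for i, cc in enumerate(nx.connected_components(ref)) for node in cc}
        for (u, v), w in dist.items():
            if w == d and comp[u] != comp[v]:
                edges.append((u, v, w))
    return edges


def _median(u: tuple, v: tuple, w: tuple) -> tuple:
    return tuple(int(a + b + c >= 2) for a, b, c in zip(u, v, w))


def _mst_cost(nodes: list[tuple]) -> float:
    if len(nodes) < 2:
        return 0.0
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b in itertools.combinations(nodes, 2):
        g.add_edge(a, b, weight=_hamming(a, b))
    return float(
        sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))
    )


def build_network(
    haplotypes,
    counts=None,
    epsilon: int = 0,
    mode: str = "mj",
    max_iter: int = 50,
) -> HaplotypeNetwork:
    """Median-joining (or, with ``mode='msn'``, minimum-spanning) network.

    ``haplotypes`` are 0/1 sequences (rows of a matrix or tuples);
    ``counts`` gives sampled multiplicities (default 1 each; duplicate input
    haplotypes are condensed and their counts summed).
    """
    haps = [tuple(int(x) for x in h) for h in haplotypes]
    if counts is None:
        counts = [1] * len(haps)
    multiplicity: dict[tuple, int] = {}
    for h, c in zip(haps, counts):
        multiplicity[h] = multiplicity.get(h, 0) + int(c)
    nodes = list(multiplicity)
    if len(nodes) < 2:
        raise ValueError("need at least 2 distinct haplotypes")

    if mode == "mj":
        for _ in range(max_iter):
            edges = _msn_edges(nodes, epsilon)
            adj: dict[tuple, set] = {v: set() for v in nodes}
            for u, v, _w in edges:
                adj[u].add(v)
                adj[v].add(u)
            base_cost = _mst_cost(nodes)
            best_cost, best_m = base_cost, None
            seen = set(nodes)
            for v in nodes:
                for u, w in itertools.combinations(adj[v], 2):
                    m = _median(u, v, w)
                    if m in seen:
                        continue
                    cost = _mst_cost(nodes + [m])
                    if cost < best_cost - 1e-9:
                        best_cost, best_m = cost, m
            if best_m is None:
                break
            nodes.append(best_m)
    elif mode != "msn":
        raise ValueError("mode must be 'mj' or 'msn'")

    edges = _msn_edges(nodes, epsilon)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_weighted_edges_from(edges)

    # prune redundant inferred medians (unsampled, degree <= 2)
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if multiplicity.get(v, 0) > 0:
                continue
            deg = g.degree(v)
            if deg <= 2:
                if deg == 2:
                    a, b = list(g.neighbors(v))
                    w = g[v][a]["weight"] + g[v][b]["weight"]
                    if not g.has_edge(a, b) or g[a][b]["weight"] > w:
                        g.add_edge(a, b, weight=w)
                g.remove_node(v)
                changed = True
    for v in list(g.nodes):
        multiplicity.setdefault(v, 0)
    multiplicity = {v: c for v, c in multiplicity.items() if v in g.nodes}
    return HaplotypeNetwork(graph=g, multiplicity=multiplicity)


def rho_statistic(
    net: HaplotypeNetwork, ancestral: tuple, derived: list[tuple] | None = None
) -> float:
    """Multiplicity-weighted mean mutational distance from the ancestral node
    to the derived sampled haplotypes (shortest network path)."""
    ancestral = tuple(int(x) for x in ancestral)
    if ancestral not in net.graph:
        raise KeyError("ancestral node not in network")
    if derived is None:
        derived = [v for v in net.sampled_nodes if v != ancestral]
    dist = nx.single_source_dijkstra_path_length(net.graph, ancestral, weight="weight")
    total = weight = 0.0
    seen: set[tuple] = set()
    for v in derived:
        v = tuple(int(x) for x in v)
        if v in seen:  # condensed nodes carry their multiplicity already
            continue
        seen.add(v)
        if v not in dist:
            raise ValueError("derived node disconnected from the ancestral node")
        mult = max(net.multiplicity.get(v, 0), 1)
        total += dist[v] * mult
        weight += mult
    if weight == 0:
        raise ValueError("no derived haplotypes to average over")
    return total / weight


@dataclass
class RhoEstimate:
    rho: float
    n_derived: int
    mu: float
    mu_units: str
    L: int
    generation_time: float
    age_years: float


def rho_to_age(
    rho: float,
    L: int,
    mu: float,
    mu_units: str,
    generation_time: float = 20.0,
    n_derived: int = 0,
) -> RhoEstimate:
    """Convert rho to an age in years.

    ``mu_units`` must be ``'per_year'`` (age = rho / (mu L)) or
    ``'per_generation'`` (age = generation_time x rho / (mu L)).
    """
    if L <= 0 or mu <= 0:
        raise ValueError("L and mu must be positive")
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if mu_units == PER_YEAR:
        age = rho / (mu * L)
    elif mu_units == PER_GENERATION:
        age = generation_time * rho / (mu * L)
    else:
        raise ValueError(
            f"mu_units must be {PER_YEAR!r} or {PER_GENERATION!r}, got {mu_units!r}"
        )
    return RhoEstimate(
        rho=rho, n_derived=n_derived, mu=mu, mu_units=mu_units, L=L,
        generation_time=generation_time, age_years=age,
    )
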