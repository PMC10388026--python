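"""Independent brute-force oracles shared by the test modules.

Everything here recomputes quantities from first principles (full rescans,
explicit path enumeration, exact rational arithmetic) and deliberately avoids
the code paths under test.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import networkx as nx
import numpy as np


def random_simple_graph(rng: np.random.Generator, n: int, p: float) -> nx.Graph:
    """Erdos-Renyi-style random simple graph with string node names."""
    g = nx.Graph()
    names = [f"N{i:03d}" for i in range(n)]
    g.add_nodes_from(names)
    for a, b in combinations(names, 2):
        if rng.random() < p:
            g.add_edge(a, b)
    return g


def path_stats_oracle(g: nx.Graph) -> tuple[int, float]:
    """(diameter, mean shortest path) over reachable pairs of the largest
    component, by plain BFS from every node."""
    comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    sub = g.subgraph(comp)
    dists = []
    for s, t in combinations(sorted(sub.nodes()), 2):
        dists.append(nx.shortest_path_length(sub, s, t))
    return max(dists), sum(dists) / len(dists)


def betweenness_oracle(g: nx.Graph, normalized: bool = True) -> dict[str, float]:
    """Betweenness by explicit enumeration of every shortest path."""
    nodes = sorted(g.nodes())
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in combinations(nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    if normalized:
        n = len(nodes)
        if n > 2:
            scale = 2.0 / ((n - 1) * (n - 2))
            bc = {v: x * scale for v, x in bc.items()}
    return bc


def bh_oracle(p_values) -> np.ndarray:
    """Benjamini-Hochberg from the definition: sort, step-up p*(m/i),
    cumulative minimum from the largest rank, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def hypergeom_tail_oracle(N: int, K: int, n: int, x: int) -> Fraction:
    """Exact P(X >= x) by big-integer combinatorial summation."""
    total = math.comb(N, n)
    acc = 0
    for i in range(x, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return Fraction(acc, total)


def core_numbers_oracle(g: nx.Graph) -> dict[str, int]:
    """Core numbers by iterative deletion: the core number of v is the largest
    k such that v survives repeatedly deleting all vertices of degree < k."""
    cores = dict.fromkeys(g.nodes(), 0)
    k = 1
    while True:
        sub = g.copy()
        while True:
            low = [v for v, d in sub.degree() if d < k]
            if not low:
                break
            sub.remove_nodes_from(low)
        if sub.number_of_nodes() == 0:
            break
        for v in sub.nodes():
            cores[v] = k
        k += 1
    return cores


def inverse_normal_upper_oracle(p: float, tol: float = 1e-12) -> float:
    """Phi^-1(1-p) by bisection on the complementary error function
    (math.erfc is libm's implementation, independent of scipy)."""
    def upper_tail(z: float) -> float:  # P(Z > z)
        return 0.5 * math.erfc(z / math.sqrt(2.0))

    lo, hi = -40.0, 40.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if upper_tail(mid) > p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def random_gate_instance(rng: np.random.Generator, n: int, edge_p: float, pass_p: float):
    """A random SPA instance: graph edges, seed set, and a gate predicate."""
    g = random_simple_graph(rng, n, edge_p)
    nodes = sorted(g.nodes())
    n_seeds = int(rng.integers(1, max(2, n // 10) + 1))
    seeds = sorted(rng.choice(nodes, size=n_seeds, replace=False))
    passing = {v for v in nodes if rng.random() < pass_p}
    edges = sorted(tuple(sorted(e)) for e in g.edges())
    return edges, seeds, passing


def annotations_for_pass_set(nodes, seeds, passing):
    """Encode an arbitrary pass set as GO annotations: passing genes carry
    table terms in all three namespaces, failing genes an off-table process
    term.  Returns (AnnotationIndex, AnnotationTable)."""
    from metnet.annotation import AnnotationIndex, SeedSet, build_annotation_table
    from metnet.io_formats import GeneId, GoAnnotationRecord

    on = {"component": "GO:0005737", "function": "GO:0003824", "process": "GO:0006555"}
    off_process = "GO:0099999"
    records = []
    for node in sorted(set(nodes) | set(seeds)):
        passes = node in passing or node in set(seeds)
        for ns, term in on.items():
            if ns == "process" and not passes:
                records.append(GoAnnotationRecord(GeneId(node), off_process, ns))
            else:
                records.append(GoAnnotationRecord(GeneId(node), term, ns))
    index = AnnotationIndex(records)
    table = build_annotation_table(SeedSet.from_names(seeds), index)
    return index, table
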