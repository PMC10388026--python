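"""Topological statistics of the reconstructed network.

Covers the classic small-world / scale-free readouts: diameter and
characteristic (mean shortest) path length on the largest connected component,
per-node degree and betweenness centrality, a least-squares power-law fit to
the degree distribution P(k) ~ k^-gamma, and hub / bottleneck extraction
(top-n by degree and by betweenness, plus their union).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    diameter: int | None
    char_path_length: float | None
    component_size: int
    degree_per_node: dict[str, int]
    bc_per_node: dict[str, float]
    gamma: float | None
    r_squared: float | None
    top_hubs: list[str]
    top_bc: list[str]
    key_union: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "diameter": self.diameter,
            "char_path_length": self.char_path_length,
            "largest_component_size": self.component_size,
            "gamma": self.gamma,
            "r_squared": self.r_squared,
            "top_hubs": self.top_hubs,
            "top_bc": self.top_bc,
            "key_union": self.key_union,
        }

    def node_table(self) -> pd.DataFrame:
        nodes = sorted(self.degree_per_node)
        return pd.DataFrame(
            {
                "node": nodes,
                "degree": [self.degree_per_node[n] for n in nodes],
                "bc": [self.bc_per_node[n] for n in nodes],
            }
        )


def shortest_path_stats(network: nx.Graph) -> tuple[int | None, float | None, int]:
    """(diameter, characteristic path length, component size) on the largest CC.

    The characteristic path length is the mean of d(u, v) over unordered
    reachable pairs.  Undefined (None) when the largest component has < 2
    nodes.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    component = max(nx.connected_components(network), key=lambda c: (len(c), sorted(c)))
    sub = network.subgraph(component)
    n = sub.number_of_nodes()
    if n < 2:
        return None, None, n
    total = 0
    count = 0
    diameter = 0
    for _, lengths in nx.all_pairs_shortest_path_length(sub):
        for d in lengths.values():
            if d > 0:
                total += d
                count += 1
                diameter = max(diameter, d)
    # each unordered pair counted twice; the ratio is unaffected
    return diameter, total / count, n


def betweenness(network: nx.Graph, normalized: bool = True) -> dict[str, float]:
    """Shortest-path betweenness centrality (even split over equal-length paths)."""
    return nx.betweenness_centrality(network, normalized=normalized)


def degree_map(network: nx.Graph) -> dict[str, int]:
    return {n: d for n, d in network.degree()}


def fit_power_law(degree_sequence) -> tuple[float, float]:
    """Least-squares fit of log10 P(k) on log10 k over observed degrees k >= 1.

    P(k) is the fraction of nodes (degree-0 nodes included in the denominator)
    with degree exactly k; no logarithmic binning.  Returns (gamma, r_squared)
    with gamma = -slope.  Raises on a degenerate (single-valued) distribution.
    """
    degrees = np.asarray(list(degree_sequence), dtype=float)
    if degrees.size == 0:
        raise ValueError("empty degree sequence")
    ks, counts = np.unique(degrees[degrees >= 1], return_counts=True)
    if ks.size < 2:
        raise ValueError("degenerate degree distribution: need >= 2 distinct positive degrees")
    pk = counts / degrees.size
    x = np.log10(ks)
    y = np.log10(pk)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(-slope), float(r_squared)


def top_nodes(metric_map: dict[str, float], n: int = 10) -> list[str]:
    """Top-n nodes by metric, descending; ties broken by ascending gene key."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(metric_map.items(), key=lambda kv: (-kv[1], kv[0]))
    return [k for k, _ in ranked[:n]]


def analyze(network: nx.Graph, top_n: int = 10) -> TopologyReport:
    """Full topology report for a reconstructed network."""
    diameter, cpl, comp_size = shortest_path_stats(network)
    degrees = degree_map(network)
    bc = betweenness(network, normalized=True)
    try:
        gamma, r2 = fit_power_law(degrees.values())
    except ValueError:
        gamma, r2 = None, None
    hubs = top_nodes(degrees, top_n) if degrees else []
    bottlenecks = top_nodes(bc, top_n) if bc else []
    return TopologyReport(
        n_nodes=network.number_of_nodes(),
        n_edges=network.number_of_edges(),
        diameter=diameter,
        char_path_length=cpl,
        component_size=comp_size,
        degree_per_node=degrees,
        bc_per_node=bc,
        gamma=gamma,
        r_squared=r2,
        top_hubs=hubs,
        top_bc=bottlenecks,
        key_union=sorted(set(hubs) | set(bottlenecks)),
    )
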