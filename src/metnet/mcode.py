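"""Dense-module (protein-complex-like) detection by core-clustering.

The procedure follows the classic molecular-complex-detection scheme:

1. *Vertex weighting* — each vertex v with degree >= ``degree_cutoff`` is
   weighted by the highest k-core of its closed neighborhood (v plus its
   neighbors): weight = (core number) x (density of that core subgraph).
2. *Complex prediction* — seed from the highest-weight unassigned vertex and
   recursively include unassigned neighbors whose weight is within the vertex
   weight percentage (VWP) of the seed weight, i.e. >= (1 - vwp) x seed
   weight; each vertex joins at most one module.
3. *Post-processing* — "haircut" iteratively removes singly-connected module
   vertices (the module's 2-core); optional "fluff" adds dense neighbors.

A module's score is its induced density times its size; modules below
``score_threshold`` (default 3, the reporting cut used downstream) or with
fewer than 2 nodes are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


@dataclass
class McodeParams:
    degree_cutoff: int = 2
    vwp: float = 0.2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.5
    score_threshold: float = 3.0

    def __post_init__(self) -> None:
        if not (0 <= self.vwp < 1):
            raise ValueError("vwp must lie in [0, 1)")
        if self.degree_cutoff < 1 or self.k_core < 1:
            raise ValueError("cutoffs must be >= 1")


@dataclass(frozen=True)
class DenseModule:
    nodes: frozenset[str]
    density: float
    seed_vertex: str

    @property
    def score(self) -> float:
        return self.density * len(self.nodes)


def graph_density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def vertex_weights(network: nx.Graph, params: McodeParams | None = None) -> dict[str, float]:
    """Core-clustering coefficient weight for every vertex (see module docs)."""
    params = params or McodeParams()
    weights: dict[str, float] = {}
    for v in network.nodes():
        if network.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        neighborhood = list(network.neighbors(v)) + [v]
        sub = network.subgraph(neighborhood)
        core_numbers = nx.core_number(sub)
        kmax = max(core_numbers.values())
        core_sub = sub.subgraph([n for n, c in core_numbers.items() if c >= kmax])
        weights[v] = kmax * graph_density(core_sub)
    return weights


def _haircut(network: nx.Graph, nodes: set[str]) -> set[str]:
    """Iteratively strip degree-1 vertices of the induced module (its 2-core)."""
    sub = network.subgraph(nodes).copy()
    while True:
        leaves = [n for n, d in sub.degree() if d < 2]
        if not leaves:
            break
        sub.remove_nodes_from(leaves)
    return set(sub.nodes())


def predict_complexes(
    network: nx.Graph,
    weights: dict[str, float] | None = None,
    params: McodeParams | None = None,
) -> list[DenseModule]:
    """Seed-and-expand dense modules, highest vertex weight first.

    Deterministic: ties in seed weight and traversal order break on the gene
    key.  Returns modules with score > ``params.score_threshold`` and >= 2
    nodes, sorted by descending score; vertices belong to at most one module.
    """
    params = params or McodeParams()
    if weights is None:
        weights = vertex_weights(network, params)
    assigned: set[str] = set()
    modules: list[DenseModule] = []
    for seed in sorted(weights, key=lambda n: (-weights[n], str(n))):
        if seed in assigned or weights[seed] <= 0:
            continue
        threshold = (1.0 - params.vwp) * weights[seed]
        members = {seed}
        stack = [seed]
        while stack:
            current = stack.pop()
            for nb in sorted(network.neighbors(current), key=str):
                if nb in assigned or nb in members:
                    continue
                if weights[nb] >= threshold:
                    members.add(nb)
                    stack.append(nb)
        if params.haircut:
            members = _haircut(network, members)
        if params.fluff:
            members |= _fluff(network, members, params)
        if len(members) < 2:
            continue
        assigned |= members
        density = graph_density(network.subgraph(members))
        module = DenseModule(nodes=frozenset(members), density=density, seed_vertex=seed)
        if module.score > params.score_threshold:
            modules.append(module)
    modules.sort(key=lambda m: (-m.score, -len(m.nodes), sorted(map(str, m.nodes))))
    return modules


def _fluff(network: nx.Graph, members: set[str], params: McodeParams) -> set[str]:
    extra: set[str] = set()
    for m in sorted(members, key=str):
        for nb in sorted(network.neighbors(m), key=str):
            if nb in members or nb in extra:
                continue
            closed = list(network.neighbors(nb)) + [nb]
            if graph_density(network.subgraph(closed)) > params.fluff_density:
                extra.add(nb)
    return extra


def merge_modules(modules: list[DenseModule], parent_network: nx.Graph) -> nx.Graph:
    """Induced subgraph of the parent on the union of module node sets.

    The result may have several connected components; callers report the
    count (a single component indicates the modules knit into one dense
    responsive network).
    """
    if not modules:
        raise ValueError("no modules to merge")
    union: set[str] = set()
    for m in modules:
        union |= m.nodes
    return parent_network.subgraph(union).copy()
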