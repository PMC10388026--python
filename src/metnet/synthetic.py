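"""Synthetic study generator with recorded ground truth.

Emulates the statistical structure every pipeline stage assumes, so the whole
analysis is testable without any database download: a scale-free PPI backbone,
a GO-coherent planted subnetwork reachable from seed proteins (with decoys
that fail the annotation gate), a planted clique for dense-module detection, a
two-condition replicated log2 expression matrix with planted differential
genes, and per-node p-values with a planted low-p connected module.

Every generator is a pure function of (parameters, seed): the same seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .annotation import SeedSet
from .dge import CONTROL, RESTRICTED, ExpressionMatrix
from .enrichment import TermGeneMap
from .io_formats import GeneId, GoAnnotationRecord

#: Gate-compatible term pools (one per namespace) used when planting a
#: GO-coherent module: seeds carry the full pool, module members one term per
#: namespace, decoys an off-pool namespace so they fail the gate.
DEFAULT_ON_TERMS = {
    "component": ("GO:0005737", "GO:0005829", "GO:0005634"),
    "function": ("GO:0003824", "GO:0016301", "GO:0005524"),
    "process": ("GO:0006555", "GO:0019346", "GO:0009086"),
}
DEFAULT_OFF_TERMS = {
    "component": ("GO:0005576", "GO:0005615"),
    "function": ("GO:0004984", "GO:0005198"),
    "process": ("GO:0007606", "GO:0007155"),
}


@dataclass
class SyntheticTruth:
    """Planted-structure record for recovery tests."""

    rng_seed: int
    seed_genes: list[str] = field(default_factory=list)
    planted_module_nodes: list[str] = field(default_factory=list)
    planted_active_nodes: list[str] = field(default_factory=list)
    planted_clique_nodes: list[str] = field(default_factory=list)
    de_genes_up: list[str] = field(default_factory=list)
    de_genes_down: list[str] = field(default_factory=list)
    true_log2fc: float = 0.0
    enriched_term: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def make_ppi(
    n_nodes: int,
    model: str = "scale_free",
    m: int = 3,
    p: float | None = None,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Simple undirected graph as a sorted canonical edge list.

    ``scale_free`` is preferential attachment with ``m`` edges per new node
    (degree distribution near a power law at these sizes); ``erdos_renyi``
    uses edge probability ``p``.
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    if model == "scale_free":
        if not (1 <= m < n_nodes):
            raise ValueError("need 1 <= m < n_nodes")
        g = nx.barabasi_albert_graph(n_nodes, m, seed=int(seed))
    elif model == "erdos_renyi":
        if p is None or not (0 <= p <= 1):
            raise ValueError("erdos_renyi needs edge probability p in [0, 1]")
        g = nx.gnp_random_graph(n_nodes, p, seed=int(seed))
    else:
        raise ValueError(f"unknown model {model!r}")
    return sorted(
        tuple(sorted((_gene_name(a), _gene_name(b)))) for a, b in g.edges()
    )


def _as_graph(edges, nodes=None) -> nx.Graph:
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


def plant_go_module(
    graph: nx.Graph,
    seeds,
    module_size: int,
    annotation_universe: tuple[dict, dict] | None = None,
    seed: int = 0,
) -> tuple[list[GoAnnotationRecord], SyntheticTruth]:
    """Annotate the graph so seed-based gated expansion recovers exactly
    ``seeds`` plus a connected ``module_size``-node planted module.

    Module nodes are collected breadth-first from the seeds (so every one is
    reachable through gate-passing paths by construction); all remaining
    nodes are decoys given at least one namespace with only off-table terms.
    """
    on_terms, off_terms = annotation_universe or (DEFAULT_ON_TERMS, DEFAULT_OFF_TERMS)
    rng = np.random.default_rng(seed)
    seeds = sorted({s for s in seeds})
    reachable = set()
    frontier = list(seeds)
    visited = set(seeds)
    while frontier and len(reachable) < module_size:
        nxt = []
        for node in frontier:
            for nb in sorted(graph.neighbors(node)):
                if nb in visited:
                    continue
                visited.add(nb)
                reachable.add(nb)
                nxt.append(nb)
                if len(reachable) >= module_size:
                    break
            if len(reachable) >= module_size:
                break
        frontier = nxt
    if len(reachable) < module_size:
        raise ValueError(
            f"graph too small/disconnected for a {module_size}-node module "
            f"(only {len(reachable)} reachable)"
        )
    module = sorted(reachable)
    records: list[GoAnnotationRecord] = []

    def _annotate(gene: str, namespaces_on: set[str]) -> None:
        for ns in ("component", "function", "process"):
            pool = on_terms[ns] if ns in namespaces_on else off_terms[ns]
            term = pool[rng.integers(len(pool))]
            records.append(GoAnnotationRecord(GeneId(gene), term, ns))

    for s in seeds:  # seeds carry the full pool: the pooled table IS the pool
        for ns in ("component", "function", "process"):
            for term in on_terms[ns]:
                records.append(GoAnnotationRecord(GeneId(s), term, ns))
    for node in module:
        _annotate(node, {"component", "function", "process"})
    all_ns = ("component", "function", "process")
    for node in sorted(graph.nodes()):
        if node in reachable or node in set(seeds):
            continue
        n_off = 1 + int(rng.integers(3))  # 1..3 namespaces forced off-table
        off = set(rng.choice(all_ns, size=n_off, replace=False))
        _annotate(node, set(all_ns) - off)
    truth = SyntheticTruth(
        rng_seed=int(seed), seed_genes=list(seeds), planted_module_nodes=module
    )
    return records, truth


def make_expression(
    genes,
    n_up: int = 30,
    n_down: int = 30,
    log2fc: float = 2.0,
    n_reps: int = 3,
    sigma: float = 0.25,
    seed: int = 0,
    up_genes=None,
    down_genes=None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-condition replicated log2 matrix with planted differential genes.

    Per-gene baseline means ~ N(8, 1); planted genes shift by +/- ``log2fc``
    in the restricted condition; replicate noise is iid N(0, sigma).  Planted
    gene identities can be supplied or are drawn uniformly.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    genes = list(genes)
    rng = np.random.default_rng(seed)
    if up_genes is None or down_genes is None:
        if n_up + n_down > len(genes):
            raise ValueError("more planted genes than genes available")
        picked = rng.choice(len(genes), size=n_up + n_down, replace=False)
        up_genes = [genes[i] for i in picked[:n_up]]
        down_genes = [genes[i] for i in picked[n_up:]]
    up_set, down_set = set(up_genes), set(down_genes)
    base = rng.normal(8.0, 1.0, size=len(genes))
    shift = np.array(
        [log2fc if g in up_set else -log2fc if g in down_set else 0.0 for g in genes]
    )
    noise = rng.normal(0.0, sigma, size=(len(genes), 2 * n_reps))
    values = np.empty((len(genes), 2 * n_reps))
    values[:, :n_reps] = base[:, None] + noise[:, :n_reps]
    values[:, n_reps:] = (base + shift)[:, None] + noise[:, n_reps:]
    samples = [f"ctrl_{i+1}" for i in range(n_reps)] + [f"restr_{i+1}" for i in range(n_reps)]
    conditions = [CONTROL] * n_reps + [RESTRICTED] * n_reps
    matrix = ExpressionMatrix(genes=genes, samples=samples, conditions=conditions, values=values)
    truth = SyntheticTruth(
        rng_seed=int(seed),
        de_genes_up=sorted(up_set),
        de_genes_down=sorted(down_set),
        true_log2fc=float(log2fc),
    )
    return matrix, truth


def plant_active_pvalues(
    graph: nx.Graph,
    module_nodes,
    p_in: tuple[float, float] = (1e-6, 1e-4),
    p_out: tuple[float, float] = (0.2, 1.0),
    seed: int = 0,
) -> dict[str, float]:
    """Uniform p-values: low inside a connected planted module, high outside."""
    module = sorted(module_nodes)
    if module:
        sub = graph.subgraph(module)
        if sub.number_of_nodes() != len(module) or not nx.is_connected(sub):
            raise ValueError("planted module must induce a connected subgraph")
    rng = np.random.default_rng(seed)
    module_set = set(module)
    pvals: dict[str, float] = {}
    for node in sorted(graph.nodes()):
        lo, hi = p_in if node in module_set else p_out
        pvals[node] = float(rng.uniform(lo, hi))
    return pvals


def _connected_subset(graph: nx.Graph, within, size: int, start: str) -> list[str]:
    """Deterministic BFS-grown connected subset of ``within`` from ``start``."""
    within = set(within)
    subset = [start]
    seen = {start}
    queue = [start]
    while queue and len(subset) < size:
        node = queue.pop(0)
        for nb in sorted(graph.neighbors(node)):
            if nb in seen or nb not in within:
                continue
            seen.add(nb)
            subset.append(nb)
            queue.append(nb)
            if len(subset) == size:
                break
    if len(subset) < size:
        raise ValueError(f"cannot grow a connected {size}-node subset from {start}")
    return sorted(subset)


@dataclass
class Study:
    """A full synthetic methionine-restriction-style study."""

    genes: list[str]
    ppi_edges: list[tuple[str, str]]
    seeds: SeedSet
    annotations: list[GoAnnotationRecord]
    expression: ExpressionMatrix
    term_map: TermGeneMap
    truth: SyntheticTruth


def make_study(
    seed: int = 0,
    n_network_nodes: int = 300,
    n_genes: int = 1000,
    n_seeds: int = 8,
    go_module_size: int = 100,
    active_module_size: int = 15,
    clique_size: int = 6,
    n_extra_up: int = 15,
    n_down: int = 30,
    log2fc: float = 3.0,
    sigma: float = 0.25,
    n_reps: int = 3,
    n_terms: int = 30,
    ba_m: int = 3,
) -> Study:
    """Compose all generators into one coherent study.

    The planted structures nest the way the analysis expects: the active
    (differentially expressed) module lies inside the GO-coherent planted
    subnetwork, and the planted clique lies inside the active module, so
    expansion -> expression integration -> dense-module detection each has a
    recoverable target.  Defaults follow the experimental design emulated
    here: biological triplicates, log2-scale intensities, and a strongly
    induced regulon (8-fold, i.e. log2 fold change 3) against sigma = 0.25
    replicate noise.
    """
    if clique_size > active_module_size or active_module_size > go_module_size:
        raise ValueError("planted structures must nest: clique <= active <= module")
    rng = np.random.default_rng(seed)
    genes = [_gene_name(i) for i in range(n_genes)]
    network_genes = genes[:n_network_nodes]
    edges = make_ppi(n_network_nodes, "scale_free", m=ba_m, seed=int(rng.integers(2**31 - 1)))
    graph = _as_graph(edges, nodes=network_genes)

    # seeds: the top-degree node plus a random sample (all in one component)
    degree_sorted = sorted(graph.degree(), key=lambda kv: (-kv[1], kv[0]))
    hub = degree_sorted[0][0]
    others = [n for n, _ in degree_sorted[1:]]
    picked = rng.choice(len(others), size=n_seeds - 1, replace=False)
    seed_nodes = sorted([hub] + [others[i] for i in picked])
    seeds = SeedSet.from_names(seed_nodes)

    annotations, go_truth = plant_go_module(
        graph, seed_nodes, go_module_size, seed=int(rng.integers(2**31 - 1))
    )
    member_nodes = sorted(set(seed_nodes) | set(go_truth.planted_module_nodes))

    # active module: connected subset of the reconstructed membership, grown
    # from the seed hub so it is reachable in the expanded network
    active = _connected_subset(graph, member_nodes, active_module_size, hub)
    clique = sorted(active)[:clique_size]
    for i, a in enumerate(clique):  # plant the clique: add any missing edges
        for b in clique[i + 1:]:
            if not graph.has_edge(a, b):
                graph.add_edge(a, b)
    edges = sorted(tuple(sorted(e)) for e in graph.edges())

    non_network = genes[n_network_nodes:]
    picked = rng.choice(len(non_network), size=n_extra_up + n_down, replace=False)
    up_genes = sorted(set(active) | {non_network[i] for i in picked[:n_extra_up]})
    down_genes = sorted(non_network[i] for i in picked[n_extra_up:])
    expression, de_truth = make_expression(
        genes,
        log2fc=log2fc,
        sigma=sigma,
        n_reps=n_reps,
        seed=int(rng.integers(2**31 - 1)),
        up_genes=up_genes,
        down_genes=down_genes,
    )

    terms: dict[str, set[str]] = {"T_PLANTED_DENSE": set(active)}
    for t in range(n_terms):
        size = int(rng.integers(10, 41))
        members = rng.choice(n_genes, size=size, replace=False)
        terms[f"T{t:03d}"] = {genes[i] for i in members}
    term_map = TermGeneMap.from_memberships(terms, background=genes)

    truth = SyntheticTruth(
        rng_seed=int(seed),
        seed_genes=seed_nodes,
        planted_module_nodes=go_truth.planted_module_nodes,
        planted_active_nodes=active,
        planted_clique_nodes=clique,
        de_genes_up=de_truth.de_genes_up,
        de_genes_down=de_truth.de_genes_down,
        true_log2fc=float(log2fc),
        enriched_term="T_PLANTED_DENSE",
    )
    return Study(
        genes=genes,
        ppi_edges=edges,
        seeds=seeds,
        annotations=annotations,
        expression=expression,
        term_map=term_map,
        truth=truth,
    )


def write_study(study: Study, outdir) -> dict[str, Path]:
    """Write a study in the same formats the readers accept (self-hosting)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "seeds": outdir / "seeds.txt",
        "annotations": outdir / "annotations.tsv",
        "ppi": outdir / "ppi.tsv",
        "expression": outdir / "expression.tsv",
        "conditions": outdir / "conditions.tsv",
        "terms": outdir / "terms.gmt",
        "truth": outdir / "truth.json",
    }
    with open(paths["seeds"], "w") as fh:
        for s in study.seeds:
            fh.write(s + "\n")
    with open(paths["annotations"], "w") as fh:
        for rec in study.annotations:
            fh.write(f"{rec.gene.systematic_name}\t{rec.term}\t{rec.namespace}\n")
    with open(paths["ppi"], "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in study.ppi_edges:
            fh.write(f"{a}\t{b}\n")
    expr = study.expression
    with open(paths["expression"], "w") as fh:
        fh.write("gene\t" + "\t".join(expr.samples) + "\n")
        for gene, row in zip(expr.genes, expr.values):
            fh.write(gene + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    with open(paths["conditions"], "w") as fh:
        for sample, cond in zip(expr.samples, expr.conditions):
            fh.write(f"{sample}\t{cond}\n")
    study.term_map.to_gmt(paths["terms"])
    study.truth.to_json(paths["truth"])
    return paths
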