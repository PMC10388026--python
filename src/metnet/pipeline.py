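"""End-to-end orchestration: reconstruct -> topology -> DE -> integrate ->
active modules -> dense modules -> merge -> enrich.

Every stage writes its outputs under the configured directory and the run
ends with a ``summary.json`` carrying all headline counts.  Runs are fully
deterministic under a fixed config (no timestamps in outputs), so a rerun is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import yaml

from . import __version__
from . import active_modules as am
from . import dge as dge_mod
from . import io_formats as iof
from . import mcode as mcode_mod
from . import topology as topo
from .annotation import AnnotationIndex, SeedSet, build_annotation_table
from .enrichment import TermGeneMap, enrich
from .spa import reconstruct

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    seeds: str = ""
    annotations: str = ""
    ppi: str = ""
    expression: str = ""
    conditions: str = ""
    terms: str = ""
    outdir: str = "results"
    gate_mode: str = "any_per_namespace"
    alpha: float = 0.05
    fc_threshold: float = 1.5
    variant: str = "sqrt_k"
    strategy: str = "greedy"
    n_restarts: int = 10
    max_k: int = 250
    n_samples: int = 10000
    seed: int = 0
    top_n: int = 10
    mcode: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    _INPUT_STAGE = {
        "seeds": "reconstruct", "annotations": "reconstruct", "ppi": "reconstruct",
        "expression": "dge", "conditions": "dge", "terms": "enrichment",
    }

    def validate(self) -> None:
        for name, stage in self._INPUT_STAGE.items():
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise PipelineError(
                    f"stage {stage!r}: input {name!r} missing or not found: {p}"
                )


def read_seed_file(path) -> SeedSet:
    with open(path) as fh:
        names = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    return SeedSet.from_names(names)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("reconstruct")
def stage_reconstruct(config: PipelineConfig, outdir: Path):
    seeds = read_seed_file(config.seeds)
    records = iof.read_annotations(config.annotations)
    index = AnnotationIndex(records)
    edges = iof.dedupe_edges(iof.read_interactions(config.ppi))
    table = build_annotation_table(seeds, index)
    network, trace = reconstruct(seeds, table, edges, index, mode=config.gate_mode)
    iof.write_network(network, outdir / "network.graphml")
    trace.to_tsv(outdir / "spa_trace.tsv")
    table.to_tsv(outdir / "annotation_table.tsv")
    log.info(
        "reconstruct: %d nodes, %d edges from %d seeds",
        network.number_of_nodes(), network.number_of_edges(), len(seeds),
    )
    return seeds, table, network, trace


@_stage("topology")
def stage_topology(network: nx.Graph, config: PipelineConfig, outdir: Path):
    report = topo.analyze(network, top_n=config.top_n)
    report.node_table().to_csv(outdir / "topology_nodes.tsv", sep="\t", index=False)
    return report


@_stage("dge")
def stage_dge(config: PipelineConfig, outdir: Path):
    matrix = iof.read_expression_matrix(config.expression, config.conditions)
    table = dge_mod.differential_expression(
        matrix, alpha=config.alpha, fc_threshold=config.fc_threshold
    )
    table.to_csv(outdir / "dge.tsv", sep="\t", index=False, float_format="%.6g")
    up = list(table.loc[table["direction"] == "up", "gene"])
    down = list(table.loc[table["direction"] == "down", "gene"])
    log.info("dge: %d significant (%d up / %d down)", len(up) + len(down), len(up), len(down))
    return table, up, down


@_stage("active_modules")
def stage_active_modules(network: nx.Graph, dge_table, config: PipelineConfig, outdir: Path):
    pvals = dict(zip(dge_table["gene"], dge_table["p_raw"]))
    node_p = {n: pvals[n] for n in network.nodes() if n in pvals}
    score_map = am.NodeScoreMap.from_pvalues(node_p)
    # attach expression statistics to the network nodes
    fc = dict(zip(dge_table["gene"], dge_table["log2fc"]))
    for n in network.nodes():
        if n in pvals:
            network.nodes[n]["p"] = float(pvals[n])
            network.nodes[n]["log2fc"] = float(fc[n])
    modules = am.search_modules(
        network,
        score_map,
        strategy=config.strategy,
        n_restarts=config.n_restarts,
        max_k=config.max_k,
        seed=config.seed,
        variant=config.variant,
        n_samples=config.n_samples,
    )
    with open(outdir / "active_modules.tsv", "w") as fh:
        fh.write("rank\tk\tz_a\ts_a\tnodes\n")
        for rank, mod in enumerate(modules, 1):
            fh.write(
                f"{rank}\t{mod.k}\t{mod.z_a:.6g}\t{mod.s_a:.6g}\t"
                + ",".join(sorted(mod.nodes)) + "\n"
            )
    if modules:
        top = network.subgraph(modules[0].nodes).copy()
        iof.write_network(top, outdir / "top_active_module.graphml")
    return score_map, modules


@_stage("mcode")
def stage_mcode(network: nx.Graph, modules, config: PipelineConfig, outdir: Path):
    if not modules:
        raise PipelineError("stage 'mcode': no active module to analyse")
    responsive = network.subgraph(modules[0].nodes)
    params = mcode_mod.McodeParams(**config.mcode)
    weights = mcode_mod.vertex_weights(responsive, params)
    dense = mcode_mod.predict_complexes(responsive, weights, params)
    with open(outdir / "dense_modules.tsv", "w") as fh:
        fh.write("rank\tsize\tdensity\tscore\tseed_vertex\tnodes\n")
        for rank, mod in enumerate(dense, 1):
            fh.write(
                f"{rank}\t{len(mod.nodes)}\t{mod.density:.6g}\t{mod.score:.6g}\t"
                f"{mod.seed_vertex}\t" + ",".join(sorted(mod.nodes)) + "\n"
            )
    merged = None
    if dense:
        merged = mcode_mod.merge_modules(dense, network)
        iof.write_network(merged, outdir / "dense_network.graphml")
    return dense, merged


@_stage("enrichment")
def stage_enrichment(dense_network, config: PipelineConfig, outdir: Path):
    if dense_network is None or dense_network.number_of_nodes() == 0:
        return None
    term_map = TermGeneMap.from_gmt(config.terms)
    result = enrich(sorted(dense_network.nodes()), term_map, alpha=config.alpha)
    result.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    return result


def run_all(config: PipelineConfig) -> dict:
    """Run the whole analysis; returns the summary dict (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    seeds, table, network, trace = stage_reconstruct(config, outdir)
    report = stage_topology(network, config, outdir)
    dge_table, up, down = stage_dge(config, outdir)
    score_map, modules = stage_active_modules(network, dge_table, config, outdir)
    dense, merged = stage_mcode(network, modules, config, outdir)
    enr = stage_enrichment(merged, config, outdir)

    summary = {
        "version": __version__,
        "config": asdict(config),
        "annotation_table": table.sizes(),
        "n_seeds": len(seeds),
        "network": {
            "n_nodes": network.number_of_nodes(),
            "n_edges": network.number_of_edges(),
            "rounds": len(trace.rounds) - 1,
        },
        "topology": {
            "diameter": report.diameter,
            "char_path_length": report.char_path_length,
            "gamma": report.gamma,
            "r_squared": report.r_squared,
            "top_hubs": report.top_hubs,
            "top_bc": report.top_bc,
            "key_union": report.key_union,
        },
        "dge": {"n_significant": len(up) + len(down), "n_up": len(up), "n_down": len(down)},
        "active_modules": [
            {"k": m.k, "z_a": round(m.z_a, 6), "s_a": round(m.s_a, 6)} for m in modules
        ],
        "dense_modules": [
            {"size": len(m.nodes), "density": round(m.density, 6), "score": round(m.score, 6)}
            for m in dense
        ],
        "dense_network": {
            "n_nodes": merged.number_of_nodes() if merged is not None else 0,
            "n_edges": merged.number_of_edges() if merged is not None else 0,
            "n_components": nx.number_connected_components(merged) if merged is not None else 0,
        },
        "enrichment_top_terms": (
            enr.head(5)[["term", "p_adj"]].round(10).to_dict("records")
            if enr is not None and len(enr)
            else []
        ),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
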