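"""Readers and writers for the external formats the pipeline touches.

Supported inputs: GO annotations (GAF 2.x subset or a 3-column TSV), physical
protein-protein interaction edges (BioGRID TAB3 subset, plain TSV, SIF), and a
log2 expression matrix (TSV with a condition sidecar).  Supported network
outputs: GraphML (Cytoscape-importable), SIF, and a simple edge TSV — all
round-trippable for node set, edge set and scalar node attributes (SIF and
edge TSV carry topology only).

Gene identity is case-insensitive: the canonical key is the upper-cased,
trimmed systematic name (yeast ORF names such as ``YER091C``); standard names
(``MET6``) are display-only.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .dge import ExpressionMatrix

log = logging.getLogger(__name__)

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")
NAMESPACES = ("component", "function", "process")
GAF_ASPECT = {"C": "component", "F": "function", "P": "process"}


def canonical(name: str) -> str:
    """Canonical gene key: trimmed, upper-cased."""
    return name.strip().upper()


@dataclass(frozen=True)
class GeneId:
    """A gene/protein identifier; equality and hashing use the canonical key."""

    systematic_name: str
    standard_name: str | None = None

    def __post_init__(self) -> None:
        if not self.systematic_name or not self.systematic_name.strip():
            raise ValueError("systematic_name must be non-empty")

    @property
    def key(self) -> str:
        return canonical(self.systematic_name)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, GeneId):
            return self.key == other.key
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.key)


@dataclass(frozen=True)
class GoAnnotationRecord:
    gene: GeneId
    term: str
    namespace: str
    evidence: str | None = None

    def __post_init__(self) -> None:
        if not GO_ID_PATTERN.match(self.term):
            raise ValueError(f"not a GO id: {self.term!r}")
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace: {self.namespace!r}")


@dataclass(frozen=True)
class EdgeRecord:
    a: GeneId
    b: GeneId
    provenance: str | None = None


def _sniff_annotation_dialect(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith("!"):
                return "gaf"
            ncols = len(line.rstrip("\n").split("\t"))
            return "gaf" if ncols >= 15 else "tsv"
    return "tsv"


def read_annotations(
    path,
    dialect: str | None = None,
    evidence_exclude: tuple[str, ...] = (),
    stats: dict | None = None,
) -> list[GoAnnotationRecord]:
    """Read GO annotation records from a GAF 2.x file or a 3-column TSV.

    The TSV dialect is ``gene <tab> GO id <tab> namespace``; the GAF dialect
    uses columns 2 (object id), 5 (GO id), 7 (evidence code) and 9 (aspect,
    mapped C/F/P -> component/function/process).  Rows with malformed GO ids
    or unknown namespaces are skipped and counted (``stats['skipped']``);
    input order is preserved.  Evidence-code filtering is off by default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = _sniff_annotation_dialect(path)
    records: list[GoAnnotationRecord] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("!", "#")):
                continue
            cols = line.rstrip("\n").split("\t")
            if dialect == "gaf":
                if len(cols) < 9:
                    skipped += 1
                    continue
                gene_name, term, evidence, aspect = cols[1], cols[4], cols[6], cols[8]
                namespace = GAF_ASPECT.get(aspect.strip())
            else:
                if len(cols) < 3:
                    skipped += 1
                    continue
                gene_name, term, namespace = cols[0], cols[1], cols[2].strip().lower()
                evidence = cols[3] if len(cols) > 3 else None
            term = term.strip()
            if (
                not gene_name.strip()
                or not GO_ID_PATTERN.match(term)
                or namespace not in NAMESPACES
            ):
                skipped += 1
                continue
            if evidence and evidence.strip() in evidence_exclude:
                skipped += 1
                continue
            records.append(
                GoAnnotationRecord(
                    gene=GeneId(gene_name),
                    term=term,
                    namespace=namespace,
                    evidence=evidence.strip() if evidence else None,
                )
            )
    if stats is not None:
        stats["skipped"] = skipped
        stats["read"] = len(records)
    if skipped:
        log.info("read_annotations: skipped %d malformed/filtered rows", skipped)
    if not records:
        raise ValueError(f"no valid annotation records in {path}")
    return records


# BioGRID TAB3 column names we rely on (subset of the full schema).
_BIOGRID_A = "Systematic Name Interactor A"
_BIOGRID_B = "Systematic Name Interactor B"
_BIOGRID_TYPE = "Experimental System Type"


def read_interactions(
    path,
    dialect: str | None = None,
    stats: dict | None = None,
) -> list[EdgeRecord]:
    """Read undirected interaction edges; self-loops are dropped and counted.

    Dialects: ``biogrid_tab3`` (keeps only rows whose experimental system type
    is ``physical``), ``tsv`` (first two columns), ``sif`` (``A <rel> B C ...``
    fans out to A-B, A-C).  Symmetric duplicates are preserved here and
    collapsed by :func:`dedupe_edges`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        with open(path) as fh:
            header = fh.readline()
        if _BIOGRID_A in header:
            dialect = "biogrid_tab3"
        elif path.suffix.lower() == ".sif":
            dialect = "sif"
        else:
            dialect = "tsv"
    records: list[EdgeRecord] = []
    self_loops = 0

    def _add(a: str, b: str, provenance: str | None = None) -> None:
        nonlocal self_loops
        if canonical(a) == canonical(b):
            self_loops += 1
            return
        records.append(EdgeRecord(GeneId(a), GeneId(b), provenance))

    if dialect == "biogrid_tab3":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in (_BIOGRID_A, _BIOGRID_B, _BIOGRID_TYPE):
            if col not in df.columns:
                raise ValueError(f"BioGRID TAB3 file missing column {col!r}")
        df = df[df[_BIOGRID_TYPE].str.strip().str.lower() == "physical"]
        for a, b in zip(df[_BIOGRID_A], df[_BIOGRID_B]):
            if pd.isna(a) or pd.isna(b) or a.strip() == "-" or b.strip() == "-":
                continue
            _add(a, b, "biogrid")
    elif dialect == "sif":
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) == 1:
                    continue  # isolated node; networks carry these separately
                source, _rel, targets = parts[0], parts[1], parts[2:]
                for t in targets:
                    _add(source, t)
    elif dialect == "tsv":
        with open(path) as fh:
            for i, line in enumerate(fh):
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 2 or not cols[0].strip() or not cols[1].strip():
                    continue
                if i == 0 and cols[0].strip().lower() in {"source", "gene_a", "interactor_a"}:
                    continue
                _add(cols[0], cols[1])
    else:
        raise ValueError(f"unknown interaction dialect {dialect!r}")
    if stats is not None:
        stats["self_loops"] = self_loops
        stats["read"] = len(records)
    if self_loops:
        log.info("read_interactions: dropped %d self-loops", self_loops)
    return records


def dedupe_edges(records: list[EdgeRecord]) -> list[tuple[str, str]]:
    """Collapse to unique unordered canonical pairs, sorted for determinism."""
    seen: set[tuple[str, str]] = set()
    for rec in records:
        a, b = sorted((rec.a.key, rec.b.key))
        if a != b:
            seen.add((a, b))
    return sorted(seen)


def build_graph(edges, nodes=None) -> nx.Graph:
    """Undirected simple graph from canonical edge pairs (plus extra nodes)."""
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(canonical(n) for n in nodes)
    g.add_edges_from((canonical(a), canonical(b)) for a, b in edges)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def write_network(network: nx.Graph, path, format: str = "graphml") -> None:
    """Write a network as GraphML, SIF or edge TSV.

    GraphML preserves scalar node attributes; SIF/edge TSV carry topology only
    (isolated nodes are written as single-name lines / single-column rows).
    """
    if network.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty network")
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in network.edges()):
                fh.write(f"{a}\tpp\t{b}\n")
            for n in sorted(network.nodes()):
                if network.degree(n) == 0:
                    fh.write(f"{n}\n")
    elif format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for a, b in sorted(tuple(sorted(e)) for e in network.edges()):
                fh.write(f"{a}\t{b}\n")
            for n in sorted(network.nodes()):
                if network.degree(n) == 0:
                    fh.write(f"{n}\t\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "graphml") -> nx.Graph:
    """Inverse of :func:`write_network`."""
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    g = nx.Graph()
    if format == "sif":
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) == 1:
                    g.add_node(parts[0])
                else:
                    for t in parts[2:]:
                        g.add_edge(parts[0], t)
        return g
    if format == "edge_tsv":
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header and header[0].strip().lower() != "source":
                # no header row: treat it as data
                _consume_edge_row(g, header)
            for row in reader:
                _consume_edge_row(g, row)
        return g
    raise ValueError(f"unknown network format {format!r}")


def _consume_edge_row(g: nx.Graph, row: list[str]) -> None:
    if not row or not row[0].strip():
        return
    if len(row) < 2 or not row[1].strip():
        g.add_node(row[0].strip())
    else:
        g.add_edge(row[0].strip(), row[1].strip())


def read_expression_matrix(
    path,
    conditions,
    stats: dict | None = None,
) -> ExpressionMatrix:
    """Read a genes-by-samples log2 TSV plus a sample->condition mapping.

    ``conditions`` is a dict, or the path of a 2-column TSV / YAML mapping.
    Genes with any non-numeric entry are skipped and counted; duplicate gene
    ids are fatal because per-gene statistics would be ambiguous.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate gene ids in expression matrix: {dups[:5]}")
    if not isinstance(conditions, dict):
        cpath = Path(conditions)
        if cpath.suffix in {".yaml", ".yml"}:
            with open(cpath) as fh:
                conditions = yaml.safe_load(fh)
        else:
            cdf = pd.read_csv(cpath, sep="\t", header=None, names=["sample", "condition"])
            conditions = dict(zip(cdf["sample"], cdf["condition"]))
    missing = [s for s in df.columns if s not in conditions]
    if missing:
        raise ValueError(f"samples without a condition label: {missing}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if stats is not None:
        stats["skipped_genes"] = int(bad.sum())
    if bad.any():
        log.info("read_expression_matrix: skipped %d genes with non-numeric entries", bad.sum())
        numeric = numeric[~bad]
    return ExpressionMatrix(
        genes=[str(g) for g in numeric.index],
        samples=[str(s) for s in numeric.columns],
        conditions=[str(conditions[s]) for s in numeric.columns],
        values=numeric.to_numpy(dtype=float),
    )
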