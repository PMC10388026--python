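"""Selective permissibility expansion of a seed set over a physical PPI graph.

Starting from the seed proteins, the network grows in rounds: a candidate is
admitted when it (i) physically interacts with a current member and (ii)
passes the GO-compatibility gate against the pooled seed annotation table.
Admitted proteins become new expansion fronts; the process runs to the least
fixpoint (no new admissions).  The returned network is the full induced
subgraph of the PPI on the admitted node set, with each node labelled by the
round in which it entered (seeds are generation 0 and are never themselves
gate-checked).

Because admission is monotone, BFS layering and full rescans reach the same
fixpoint; iteration is over sorted gene keys so runs are reproducible and
independent of input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .annotation import AnnotationIndex, AnnotationTable, SeedSet, gene_passes_gate

log = logging.getLogger(__name__)

REASON_FAILED_GATE = "failed-gate"
REASON_NOT_ADJACENT = "not-adjacent"


@dataclass
class SpaTrace:
    """Audit trail: admissions per round and per-gene rejection reasons."""

    rounds: list[list[str]] = field(default_factory=list)  # rounds[0] = seeds
    rejections: dict[str, str] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tstatus\tround\n")
            for rnd, admitted in enumerate(self.rounds):
                for gene in admitted:
                    fh.write(f"{gene}\tadmitted\t{rnd}\n")
            for gene in sorted(self.rejections):
                fh.write(f"{gene}\t{self.rejections[gene]}\t\n")


def _adjacency(ppi_edges) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for a, b in ppi_edges:
        if a == b:
            continue
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def reconstruct(
    seeds: SeedSet,
    table: AnnotationTable,
    ppi_edges,
    annotations: AnnotationIndex,
    mode: str = "any_per_namespace",
) -> tuple[nx.Graph, SpaTrace]:
    """Expand ``seeds`` over ``ppi_edges`` to the gate-closed fixpoint.

    ``ppi_edges`` is a deduplicated list of canonical unordered pairs (see
    ``io_formats.dedupe_edges``).  Returns the induced network (node attribute
    ``generation``) and a :class:`SpaTrace`.  Seeds absent from the PPI stay
    in the network as isolated generation-0 nodes (warned).
    """
    if not isinstance(annotations, AnnotationIndex):
        annotations = AnnotationIndex(annotations)
    adj = _adjacency(ppi_edges)
    members: dict[str, int] = {s: 0 for s in sorted(seeds.members)}
    isolated = [s for s in seeds if s not in adj]
    if isolated:
        log.warning("seeds with no PPI presence (kept as isolated nodes): %s", isolated)

    gate_cache: dict[str, bool] = {}

    def passes(gene: str) -> bool:
        if gene not in gate_cache:
            gate_cache[gene] = gene_passes_gate(gene, annotations, table, mode=mode)
        return gate_cache[gene]

    trace = SpaTrace(rounds=[sorted(seeds.members)])
    frontier = sorted(seeds.members)
    generation = 0
    while frontier:
        generation += 1
        candidates = sorted(
            {n for m in frontier for n in adj.get(m, ()) if n not in members}
        )
        admitted = []
        for gene in candidates:
            if passes(gene):
                admitted.append(gene)
            else:
                trace.rejections[gene] = REASON_FAILED_GATE
        for gene in admitted:
            members[gene] = generation
            trace.rejections.pop(gene, None)
        if admitted:
            trace.rounds.append(admitted)
        frontier = admitted
        log.info("expansion round %d: %d admitted", generation, len(admitted))

    # genes in the PPI never adjacent to a member were never even evaluated
    for gene in adj:
        if gene not in members and gene not in trace.rejections:
            trace.rejections[gene] = REASON_NOT_ADJACENT

    network = nx.Graph()
    for gene, gen in members.items():
        network.add_node(gene, generation=gen)
    member_set = set(members)
    for a, b in ppi_edges:
        if a in member_set and b in member_set and a != b:
            network.add_edge(a, b)
    return network, trace


def closure_oracle(seeds: SeedSet, gate_fn, ppi_edges) -> set[str]:
    """Reference fixpoint by repeated full rescan until stable (tests only).

    ``gate_fn`` maps a gene key to a bool.  Intended for small graphs; the
    production path is :func:`reconstruct`.
    """
    adj = _adjacency(ppi_edges)
    members = set(seeds.members)
    changed = True
    while changed:
        changed = False
        for gene in sorted(adj):
            if gene in members:
                continue
            if any(n in members for n in adj[gene]) and gate_fn(gene):
                members.add(gene)
                changed = True
    return members
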