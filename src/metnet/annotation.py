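"""Pooled annotation table and the GO-compatibility gate for network expansion.

The table pools the component, function and process GO terms of the seed
proteins; during expansion a candidate protein is admitted only if its own
annotations are compatible with that table.  Two readings of "its GO terms are
present in the table" are offered:

``any_per_namespace`` (default)
    in each of the three namespaces the gene has at least one annotated term
    that the table contains — genes carry many terms per namespace, and the
    strict reading would exclude nearly every protein;
``all_terms``
    every annotated term of the gene, in every namespace, is in the table.

Under both modes a gene lacking annotation in some namespace fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import GO_ID_PATTERN, NAMESPACES, GeneId, GoAnnotationRecord, canonical

log = logging.getLogger(__name__)

#: GO namespace root terms; they gate nothing (every annotated gene descends
#: from them) and can optionally be excluded from the pooled table.
ROOT_TERMS = {"GO:0005575", "GO:0003674", "GO:0008150"}

GATE_MODES = ("any_per_namespace", "all_terms")


@dataclass(frozen=True)
class AnnotationTable:
    component_terms: frozenset[str]
    function_terms: frozenset[str]
    process_terms: frozenset[str]

    def __post_init__(self) -> None:
        for terms in (self.component_terms, self.function_terms, self.process_terms):
            bad = [t for t in terms if not GO_ID_PATTERN.match(t)]
            if bad:
                raise ValueError(f"invalid GO ids in annotation table: {bad[:5]}")

    def terms(self, namespace: str) -> frozenset[str]:
        return getattr(self, f"{namespace}_terms")

    def sizes(self) -> dict[str, int]:
        return {ns: len(self.terms(ns)) for ns in NAMESPACES}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("term\tnamespace\n")
            for ns in NAMESPACES:
                for term in sorted(self.terms(ns)):
                    fh.write(f"{term}\t{ns}\n")


@dataclass(frozen=True)
class SeedSet:
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("seed set must be non-empty")

    @classmethod
    def from_names(cls, names) -> "SeedSet":
        return cls(frozenset(canonical(n) for n in names))

    @classmethod
    def from_genes(cls, genes) -> "SeedSet":
        return cls(frozenset(g.key for g in genes))

    def __iter__(self):
        return iter(sorted(self.members))

    def __len__(self) -> int:
        return len(self.members)


class AnnotationIndex:
    """gene key -> namespace -> set of GO terms, for O(1) gate checks."""

    def __init__(self, records: list[GoAnnotationRecord]):
        self._by_gene: dict[str, dict[str, set[str]]] = {}
        for rec in records:
            ns_map = self._by_gene.setdefault(rec.gene.key, {ns: set() for ns in NAMESPACES})
            ns_map[rec.namespace].add(rec.term)

    def genes(self) -> set[str]:
        return set(self._by_gene)

    def terms(self, gene, namespace: str) -> set[str]:
        key = gene.key if isinstance(gene, GeneId) else canonical(gene)
        return self._by_gene.get(key, {}).get(namespace, set())

    def __contains__(self, gene) -> bool:
        key = gene.key if isinstance(gene, GeneId) else canonical(gene)
        return key in self._by_gene


def build_annotation_table(
    seeds: SeedSet,
    annotations: list[GoAnnotationRecord] | AnnotationIndex,
    exclude_roots: bool = False,
) -> AnnotationTable:
    """Pool each namespace's terms over all seed proteins (set union).

    Every seed must appear in the annotation records at least once; seeds
    missing annotation in some namespace are reported at warning level (they
    simply contribute nothing there).
    """
    index = annotations if isinstance(annotations, AnnotationIndex) else AnnotationIndex(annotations)
    missing = sorted(s for s in seeds.members if s not in index)
    if missing:
        raise ValueError(f"seeds absent from the annotation records: {missing}")
    pooled: dict[str, set[str]] = {ns: set() for ns in NAMESPACES}
    for seed in seeds:
        for ns in NAMESPACES:
            terms = index.terms(seed, ns)
            if not terms:
                log.warning("seed %s has no %s annotation", seed, ns)
            pooled[ns] |= terms
    if exclude_roots:
        for ns in NAMESPACES:
            pooled[ns] -= ROOT_TERMS
    return AnnotationTable(
        component_terms=frozenset(pooled["component"]),
        function_terms=frozenset(pooled["function"]),
        process_terms=frozenset(pooled["process"]),
    )


def gene_passes_gate(
    gene,
    annotations: AnnotationIndex | list[GoAnnotationRecord],
    table: AnnotationTable,
    mode: str = "any_per_namespace",
) -> bool:
    """GO-compatibility gate used during network expansion (see module docs)."""
    if mode not in GATE_MODES:
        raise ValueError(f"unknown gate mode {mode!r}")
    index = annotations if isinstance(annotations, AnnotationIndex) else AnnotationIndex(annotations)
    if gene not in index:
        log.debug("gate: unknown gene %s", gene)
        return False
    for ns in NAMESPACES:
        terms = index.terms(gene, ns)
        if not terms:
            return False
        table_terms = table.terms(ns)
        if mode == "any_per_namespace":
            if not (terms & table_terms):
                return False
        else:  # all_terms
            if not terms <= table_terms:
                return False
    return True
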