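"""The eight seed proteins of yeast methionine biosynthesis and their pooled
GO annotation table.

These are the Saccharomyces cerevisiae proteins curated to carry the
"methionine biosynthetic process" annotation in SGD (January 2023 curation),
from which the methionine biosynthesis network is expanded, together with the
pooled component / function / process GO term sets of those seeds that form
the expansion gate (7, 31 and 29 terms respectively).

The pooled table records only the union per namespace, not which seed
contributed which term; :func:`annotation_records` therefore distributes the
pooled terms round-robin across the seeds to produce well-formed per-gene
records whose pooled union is exactly the table.
"""

from __future__ import annotations

from itertools import cycle

from .annotation import AnnotationTable, SeedSet, build_annotation_table
from .io_formats import GeneId, GoAnnotationRecord

#: (systematic ORF name, standard gene name)
SEED_PROTEINS: tuple[tuple[str, str], ...] = (
    ("YDR158W", "HOM2"),
    ("YER052C", "HOM3"),
    ("YER091C", "MET6"),
    ("YGL125W", "MET13"),
    ("YGL184C", "STR3"),
    ("YJR139C", "HOM6"),
    ("YNL277W", "MET2"),
    ("YOL064C", "MET22"),
)

COMPONENT_TERMS: tuple[str, ...] = (
    "GO:0005575",
    "GO:0005634",
    "GO:0005737",
    "GO:0005739",
    "GO:0005777",
    "GO:0005829",
    "GO:0005886",
)

FUNCTION_TERMS: tuple[str, ...] = (
    "GO:0000166",
    "GO:0003674",
    "GO:0003824",
    "GO:0003871",
    "GO:0004072",
    "GO:0004073",
    "GO:0004121",
    "GO:0004412",
    "GO:0004414",
    "GO:0004489",
    "GO:0005524",
    "GO:0008168",
    "GO:0008172",
    "GO:0008270",
    "GO:0008441",
    "GO:0016301",
    "GO:0016491",
    "GO:0016620",
    "GO:0016740",
    "GO:0016746",
    "GO:0016747",
    "GO:0016787",
    "GO:0016829",
    "GO:0016846",
    "GO:0030170",
    "GO:0046872",
    "GO:0046983",
    "GO:0047804",
    "GO:0050661",
    "GO:0051287",
    "GO:0071949",
)

PROCESS_TERMS: tuple[str, ...] = (
    "GO:0000096",
    "GO:0000103",
    "GO:0006520",
    "GO:0006555",
    "GO:0006790",
    "GO:0008150",
    "GO:0008652",
    "GO:0009058",
    "GO:0009067",
    "GO:0009082",
    "GO:0009085",
    "GO:0009086",
    "GO:0009088",
    "GO:0009089",
    "GO:0009090",
    "GO:0009092",
    "GO:0009097",
    "GO:0016053",
    "GO:0016078",
    "GO:0016310",
    "GO:0019346",
    "GO:0032259",
    "GO:0035999",
    "GO:0042538",
    "GO:0046854",
    "GO:0046855",
    "GO:0071266",
    "GO:1901566",
    "GO:1901605",
)


def seed_genes() -> list[GeneId]:
    return [GeneId(orf, std) for orf, std in SEED_PROTEINS]


def seed_set() -> SeedSet:
    return SeedSet.from_genes(seed_genes())


def annotation_records() -> list[GoAnnotationRecord]:
    """Per-seed annotation records whose pooled union equals the printed table.

    The attribution of individual pooled terms to individual seeds is not part
    of the curated table; terms are assigned round-robin, which is arbitrary
    but deterministic, and every downstream use pools them again anyway.
    """
    genes = seed_genes()
    records: list[GoAnnotationRecord] = []
    for namespace, terms in (
        ("component", COMPONENT_TERMS),
        ("function", FUNCTION_TERMS),
        ("process", PROCESS_TERMS),
    ):
        for gene, term in zip(cycle(genes), terms):
            records.append(GoAnnotationRecord(gene=gene, term=term, namespace=namespace))
    return records


def annotation_table(exclude_roots: bool = False) -> AnnotationTable:
    """The pooled seed annotation table (7 component / 31 function / 29 process)."""
    return build_annotation_table(seed_set(), annotation_records(), exclude_roots=exclude_roots)
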