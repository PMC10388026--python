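"""Pooled annotation table construction and the expansion gate."""

import numpy as np
import pytest

from metnet import reference
from metnet.annotation import (
    AnnotationIndex,
    SeedSet,
    build_annotation_table,
    gene_passes_gate,
)
from metnet.io_formats import GeneId, GoAnnotationRecord


def _rec(gene, term, ns):
    return GoAnnotationRecord(GeneId(gene), term, ns)


def test_pooled_table_of_curated_seeds():
    """The eight methionine-biosynthesis seeds pool to 7/31/29 terms."""
    table = reference.annotation_table()
    assert len(reference.seed_set()) == 8
    assert table.sizes() == {"component": 7, "function": 31, "process": 29}


def test_single_seed_single_record_per_namespace():
    records = [
        _rec("S1", "GO:0005737", "component"),
        _rec("S1", "GO:0003824", "function"),
        _rec("S1", "GO:0006555", "process"),
    ]
    table = build_annotation_table(SeedSet.from_names(["S1"]), records)
    assert table.sizes() == {"component": 1, "function": 1, "process": 1}


def test_union_is_idempotent_for_shared_terms():
    shared = [
        _rec("S1", "GO:0005737", "component"),
        _rec("S1", "GO:0003824", "function"),
        _rec("S1", "GO:0006555", "process"),
    ]
    doubled = shared + [
        _rec("S2", r.term, r.namespace) for r in shared
    ]
    one = build_annotation_table(SeedSet.from_names(["S1"]), shared)
    two = build_annotation_table(SeedSet.from_names(["S1", "S2"]), doubled)
    assert one == two


def test_missing_seed_listed_in_error():
    records = [_rec("S1", "GO:0005737", "component")]
    with pytest.raises(ValueError, match="S2"):
        build_annotation_table(SeedSet.from_names(["S1", "S2"]), records)


def test_order_independence_of_pooling():
    rng = np.random.default_rng(0)
    records = [
        _rec(f"S{i%3}", f"GO:{1000000+j:07d}", ns)
        for j, (i, ns) in enumerate(
            (int(rng.integers(3)), ["component", "function", "process"][int(rng.integers(3))])
            for _ in range(50)
        )
    ]
    seeds = SeedSet.from_names(["S0", "S1", "S2"])
    shuffled = list(records)
    rng.shuffle(shuffled)
    assert build_annotation_table(seeds, records) == build_annotation_table(seeds, shuffled)


def test_gate_against_curated_table_any_mode():
    """A gene carrying one table term per namespace passes the default gate."""
    table = reference.annotation_table()
    records = [
        _rec("YFG1", "GO:0005737", "component"),
        _rec("YFG1", "GO:0003824", "function"),
        _rec("YFG1", "GO:0006555", "process"),
    ]
    assert gene_passes_gate("YFG1", AnnotationIndex(records), table)


def test_gate_fails_without_process_annotation():
    table = reference.annotation_table()
    records = [
        _rec("YFG1", "GO:0005737", "component"),
        _rec("YFG1", "GO:0003824", "function"),
    ]
    assert not gene_passes_gate("YFG1", AnnotationIndex(records), table)


def test_gate_fails_when_only_function_term_off_table():
    table = reference.annotation_table()
    records = [
        _rec("YFG1", "GO:0005737", "component"),
        _rec("YFG1", "GO:0099999", "function"),
        _rec("YFG1", "GO:0006555", "process"),
    ]
    assert not gene_passes_gate("YFG1", AnnotationIndex(records), table)


def test_all_terms_mode_is_stricter():
    table = reference.annotation_table()
    records = [
        _rec("YFG1", "GO:0005737", "component"),
        _rec("YFG1", "GO:0003824", "function"),
        _rec("YFG1", "GO:0099999", "function"),  # off-table extra term
        _rec("YFG1", "GO:0006555", "process"),
    ]
    index = AnnotationIndex(records)
    assert gene_passes_gate("YFG1", index, table, mode="any_per_namespace")
    assert not gene_passes_gate("YFG1", index, table, mode="all_terms")


def test_unknown_gene_fails_quietly():
    table = reference.annotation_table()
    assert not gene_passes_gate("NOPE1", AnnotationIndex([]), table)


@pytest.mark.parametrize("mode", ["any_per_namespace", "all_terms"])
def test_gate_monotone_in_table(mode):
    """Enlarging the table never flips a gene from pass to fail."""
    rng = np.random.default_rng(1)
    namespaces = ["component", "function", "process"]
    universe = [f"GO:{1000000+i:07d}" for i in range(30)]
    for _ in range(50):
        gene_records = [
            _rec("YFG1", universe[int(rng.integers(30))], ns)
            for ns in namespaces
            for _ in range(int(rng.integers(1, 4)))
        ]
        index = AnnotationIndex(gene_records)
        seed_records = [
            _rec("S1", universe[int(rng.integers(30))], ns)
            for ns in namespaces
            for _ in range(int(rng.integers(1, 6)))
        ]
        small = build_annotation_table(SeedSet.from_names(["S1"]), seed_records)
        extra = seed_records + [
            _rec("S1", universe[int(rng.integers(30))], ns) for ns in namespaces
        ]
        large = build_annotation_table(SeedSet.from_names(["S1"]), extra)
        if gene_passes_gate("YFG1", index, small, mode=mode):
            assert gene_passes_gate("YFG1", index, large, mode=mode)


def test_root_terms_kept_by_default_and_excludable():
    table = reference.annotation_table()
    assert "GO:0008150" in table.process_terms
    trimmed = reference.annotation_table(exclude_roots=True)
    assert "GO:0008150" not in trimmed.process_terms
    assert trimmed.sizes() == {"component": 6, "function": 30, "process": 28}


def test_table_serializes_to_tsv(tmp_path):
    table = reference.annotation_table()
    path = tmp_path / "table.tsv"
    table.to_tsv(path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "term\tnamespace"
    assert len(lines) == 1 + 7 + 31 + 29
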