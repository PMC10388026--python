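"""Synthetic-study generators: determinism and planted-structure contracts."""

import filecmp

import networkx as nx
import numpy as np
import pytest

from metnet import synthetic
from metnet.annotation import AnnotationIndex, build_annotation_table
from metnet.dge import differential_expression
from metnet.io_formats import build_graph
from metnet.spa import reconstruct
from metnet.topology import fit_power_law


def test_make_ppi_deterministic():
    assert synthetic.make_ppi(300, m=3, seed=1) == synthetic.make_ppi(300, m=3, seed=1)
    assert synthetic.make_ppi(300, m=3, seed=1) != synthetic.make_ppi(300, m=3, seed=2)


def test_erdos_renyi_p_zero_has_no_edges():
    assert synthetic.make_ppi(50, model="erdos_renyi", p=0.0, seed=0) == []


def test_make_ppi_validation():
    with pytest.raises(ValueError):
        synthetic.make_ppi(5)
    with pytest.raises(ValueError):
        synthetic.make_ppi(50, model="erdos_renyi")  # p missing


def test_scale_free_degree_distribution_near_power_law():
    r2s = []
    for seed in range(10):
        g = build_graph(synthetic.make_ppi(300, m=3, seed=seed))
        r2s.append(fit_power_law([d for _, d in g.degree()])[1])
    assert float(np.mean(r2s)) > 0.6


def test_plant_go_module_expansion_recovers_exactly_the_module():
    g = build_graph(synthetic.make_ppi(200, m=3, seed=3))
    seeds = sorted(g.nodes())[:5]
    records, truth = synthetic.plant_go_module(g, seeds, 40, seed=4)
    index = AnnotationIndex(records)
    from metnet.annotation import SeedSet

    table = build_annotation_table(SeedSet.from_names(seeds), index)
    network, trace = reconstruct(SeedSet.from_names(seeds), table,
                                 sorted(tuple(sorted(e)) for e in g.edges()), index)
    assert set(network.nodes()) == set(seeds) | set(truth.planted_module_nodes)
    # decoys adjacent to members were rejected by the gate, not by adjacency
    rejected_adjacent = {
        n for n in g.nodes()
        if n not in network and any(m in network for m in g.neighbors(n))
    }
    for n in rejected_adjacent:
        assert trace.rejections[n] == "failed-gate"


def test_plant_go_module_zero_size():
    g = build_graph(synthetic.make_ppi(50, m=2, seed=5))
    seeds = sorted(g.nodes())[:3]
    records, truth = synthetic.plant_go_module(g, seeds, 0, seed=6)
    assert truth.planted_module_nodes == []


def test_plant_go_module_too_large_fatal():
    g = build_graph(synthetic.make_ppi(20, m=2, seed=7))
    with pytest.raises(ValueError, match="reachable"):
        synthetic.plant_go_module(g, sorted(g.nodes())[:2], 50, seed=8)


def test_make_expression_deterministic_and_validated():
    genes = [f"g{i}" for i in range(50)]
    m1, _ = synthetic.make_expression(genes, 5, 5, seed=9)
    m2, _ = synthetic.make_expression(genes, 5, 5, seed=9)
    np.testing.assert_array_equal(m1.values, m2.values)
    with pytest.raises(ValueError, match="sigma"):
        synthetic.make_expression(genes, 5, 5, sigma=0.0, seed=9)
    with pytest.raises(ValueError, match="more planted"):
        synthetic.make_expression(genes, 40, 40, seed=9)


def test_noise_free_limit_recovers_planted_genes_exactly():
    genes = [f"g{i:03d}" for i in range(200)]
    matrix, truth = synthetic.make_expression(
        genes, n_up=10, n_down=10, log2fc=1.0, sigma=1e-9, seed=10
    )
    table = differential_expression(matrix)
    called_up = set(table.loc[table.direction == "up", "gene"])
    called_down = set(table.loc[table.direction == "down", "gene"])
    assert called_up == set(truth.de_genes_up)
    assert called_down == set(truth.de_genes_down)


def test_plant_active_pvalues_connectivity_requirement():
    g = nx.path_graph([f"n{i}" for i in range(10)])
    with pytest.raises(ValueError, match="connected"):
        synthetic.plant_active_pvalues(g, ["n0", "n5"], seed=11)
    pv = synthetic.plant_active_pvalues(g, ["n0", "n1"], seed=11)
    assert pv == synthetic.plant_active_pvalues(g, ["n0", "n1"], seed=11)
    assert all(pv[n] <= 1e-4 for n in ("n0", "n1"))


def test_study_truth_round_trips_through_json(tmp_path):
    study = synthetic.make_study(seed=3, n_network_nodes=100, n_genes=300,
                                 go_module_size=30, active_module_size=10)
    path = tmp_path / "truth.json"
    study.truth.to_json(path)
    assert synthetic.SyntheticTruth.from_json(path) == study.truth


def test_write_study_byte_identical_across_runs(tmp_path):
    a = synthetic.write_study(synthetic.make_study(seed=5, n_network_nodes=100,
                                                   n_genes=300, go_module_size=30,
                                                   active_module_size=10), tmp_path / "a")
    b = synthetic.write_study(synthetic.make_study(seed=5, n_network_nodes=100,
                                                   n_genes=300, go_module_size=30,
                                                   active_module_size=10), tmp_path / "b")
    for key in a:
        assert filecmp.cmp(a[key], b[key], shallow=False), f"{key} differs"


def test_study_planted_structures_nest():
    study = synthetic.make_study(seed=6, n_network_nodes=150, n_genes=400,
                                 go_module_size=40, active_module_size=12, clique_size=5)
    t = study.truth
    members = set(t.seed_genes) | set(t.planted_module_nodes)
    assert set(t.planted_active_nodes) <= members
    assert set(t.planted_clique_nodes) <= set(t.planted_active_nodes)
    assert set(t.planted_active_nodes) <= set(t.de_genes_up)
    g = build_graph(study.ppi_edges)
    assert nx.is_connected(g.subgraph(t.planted_clique_nodes))
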