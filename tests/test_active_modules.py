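"""Active-subnetwork scoring: z-transform, calibration, greedy search."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from helpers import inverse_normal_upper_oracle
from metnet import active_modules as am
from metnet.io_formats import build_graph
from metnet.synthetic import make_ppi, plant_active_pvalues


def _score_map_from_z(zmap: dict[str, float]) -> am.NodeScoreMap:
    return am.NodeScoreMap(p={}, z=dict(zmap))


def test_z_transform_reference_points():
    assert am.z_transform(0.5) == pytest.approx(0.0, abs=1e-12)
    assert am.z_transform(0.0228) == pytest.approx(2.0, abs=0.01)
    assert am.z_transform(0.9772) == pytest.approx(-2.0, abs=0.01)


def test_z_transform_matches_bisection_oracle():
    ps = np.concatenate(
        [10.0 ** np.arange(-10, 0), 1 - 10.0 ** np.arange(-10, -1), [0.5, 0.123]]
    )
    for p in ps:
        assert am.z_transform(float(p)) == pytest.approx(
            inverse_normal_upper_oracle(float(p)), abs=1e-6
        )


def test_z_transform_domain_and_clamping():
    with pytest.raises(ValueError):
        am.z_transform(0.0)
    with pytest.raises(ValueError):
        am.z_transform(1.5)
    assert np.isfinite(am.z_transform(0.0, clamp=True))
    assert am.z_transform(0.0, clamp=True) == pytest.approx(
        am.z_transform(1e-16), abs=1e-9
    )


def test_module_z_algebra():
    sm = _score_map_from_z({f"n{i}": 2.0 for i in range(4)})
    nodes = list(sm.z)
    assert am.module_z(nodes, sm, "sqrt_k") == pytest.approx(4.0)
    assert am.module_z(nodes, sm, "k") == pytest.approx(2.0)
    zero = _score_map_from_z({n: 0.0 for n in nodes})
    assert am.module_z(nodes, zero, "sqrt_k") == 0.0
    assert am.module_z(nodes, zero, "k") == 0.0


def test_calibration_zero_scores_degenerate():
    g = build_graph(make_ppi(30, m=2, seed=0))
    sm = _score_map_from_z({n: 0.0 for n in g.nodes()})
    cal = am.calibrate(g, sm, [1, 5, 10], n_samples=200, seed=0)
    for k in (1, 5, 10):
        assert cal.mean[k] == 0.0 and cal.sd[k] == 0.0
        assert cal.score(0.0, k) == 0.0


def test_calibration_standard_normal_scores():
    """With standard-normal node scores the per-k null is ~ N(0,1); exactly,
    sampling k of n fixed scores without replacement gives mean sqrt(k)*zbar
    and sd sigma*sqrt((n-k)/(n-1)) for z(A) = sum/sqrt(k)."""
    n = 400
    g = build_graph(make_ppi(n, m=3, seed=1))
    rng = np.random.default_rng(2)
    z = rng.normal(size=n)
    sm = _score_map_from_z({node: float(v) for node, v in zip(sorted(g.nodes()), z)})
    cal = am.calibrate(g, sm, [2, 5, 20, 50], n_samples=20000, seed=3)
    for k in (2, 5, 20, 50):
        expected_mean = np.sqrt(k) * z.mean()
        expected_sd = z.std() * np.sqrt((n - k) / (n - 1))
        assert cal.mean[k] == pytest.approx(expected_mean, abs=0.03)
        assert cal.sd[k] == pytest.approx(expected_sd, abs=0.03)
        # the iid N(0,1) idealization holds up to the realized population
        # mean/sd of the finite score set
        assert abs(cal.mean[k]) < 0.2 and abs(cal.sd[k] - 1.0) < 0.1


def test_calibration_k1_matches_enumeration():
    g = build_graph(make_ppi(50, m=2, seed=4))
    rng = np.random.default_rng(5)
    z = {n: float(v) for n, v in zip(sorted(g.nodes()), rng.normal(size=50))}
    sm = _score_map_from_z(z)
    cal = am.calibrate(g, sm, [1], n_samples=50000, seed=6)
    vals = np.array(list(z.values()))
    assert cal.mean[1] == pytest.approx(vals.mean(), abs=0.02)
    assert cal.sd[1] == pytest.approx(vals.std(), abs=0.02)


def test_calibrated_random_subset_scores_are_standard_normal():
    g = build_graph(make_ppi(300, m=3, seed=7))
    rng = np.random.default_rng(8)
    nodes = sorted(g.nodes())
    sm = _score_map_from_z({n: float(v) for n, v in zip(nodes, rng.normal(size=300))})
    cal = am.calibrate(g, sm, [10], n_samples=20000, seed=9)
    # fresh random subsets scored through the calibration
    scores = []
    for _ in range(500):
        subset = rng.choice(nodes, size=10, replace=False)
        scores.append(cal.score(am.module_z(subset, sm), 10))
    assert sps.kstest(scores, "norm").pvalue > 0.01


def test_calibration_k_exceeding_network_fatal():
    g = build_graph(make_ppi(20, m=2, seed=0))
    sm = _score_map_from_z({n: 0.0 for n in g.nodes()})
    with pytest.raises(ValueError, match="exceeds"):
        am.calibrate(g, sm, [25], n_samples=10, seed=0)


def test_singleton_spike_is_its_own_module():
    g = nx.path_graph([f"n{i}" for i in range(10)])
    zmap = {n: -5.0 for n in g.nodes()}
    zmap["n4"] = 5.0
    sm = _score_map_from_z(zmap)
    mods = am.search_modules(g, sm, n_restarts=3, seed=0, n_samples=2000)
    assert mods[0].nodes == frozenset({"n4"})


def test_returned_modules_are_connected_and_disjoint():
    g = build_graph(make_ppi(200, m=3, seed=10))
    pv = plant_active_pvalues(g, [], p_in=(0.01, 1.0), p_out=(0.01, 1.0), seed=11)
    sm = am.NodeScoreMap.from_pvalues(pv)
    mods = am.search_modules(g, sm, seed=12, n_samples=2000)
    seen = set()
    for mod in mods:
        assert nx.is_connected(g.subgraph(mod.nodes))
        assert not (mod.nodes & seen)
        seen |= mod.nodes


def test_search_invariant_under_node_relabeling():
    g = build_graph(make_ppi(60, m=2, seed=13))
    module = sorted(g.nodes())[:0]  # no planted signal needed
    pv = plant_active_pvalues(g, module, p_in=(0.5, 1.0), p_out=(1e-4, 1.0), seed=14)
    sm = am.NodeScoreMap.from_pvalues(pv)
    mods = am.search_modules(g, sm, seed=15, n_samples=2000)
    # relabel: prepend "x" to every name (preserves sort order, so ties
    # break identically and the result must map 1:1)
    relabel = {n: f"x{n}" for n in g.nodes()}
    g2 = nx.relabel_nodes(g, relabel)
    sm2 = am.NodeScoreMap.from_pvalues({relabel[n]: p for n, p in pv.items()})
    mods2 = am.search_modules(g2, sm2, seed=15, n_samples=2000)
    assert [frozenset(relabel[n] for n in m.nodes) for m in mods] == [m.nodes for m in mods2]
    assert [m.s_a for m in mods] == pytest.approx([m.s_a for m in mods2])


def test_planted_module_recovery():
    """Low-p planted 15-node connected modules are found with Jaccard >= 0.8."""
    from metnet.synthetic import _connected_subset

    hits = 0
    for rep in range(10):
        g = build_graph(make_ppi(300, m=3, seed=500 + rep))
        hub = max(g.degree(), key=lambda kv: kv[1])[0]
        module = _connected_subset(g, g.nodes(), 15, hub)
        pv = plant_active_pvalues(g, module, seed=700 + rep)
        sm = am.NodeScoreMap.from_pvalues(pv)
        mods = am.search_modules(g, sm, seed=rep, n_samples=5000)
        best, planted = set(mods[0].nodes), set(module)
        if len(best & planted) / len(best | planted) >= 0.8:
            hits += 1
    assert hits >= 9


def test_annealing_honors_score_contract():
    g = build_graph(make_ppi(100, m=2, seed=20))
    pv = plant_active_pvalues(g, [], p_in=(0.2, 1.0), p_out=(0.2, 1.0), seed=21)
    sm = am.NodeScoreMap.from_pvalues(pv)
    mods = am.search_modules(
        g, sm, strategy="simulated_annealing", n_restarts=3, seed=22, n_samples=2000
    )
    for mod in mods:
        assert nx.is_connected(g.subgraph(mod.nodes))
        assert mod.s_a == pytest.approx(
            am.calibrate(
                g, sm, [mod.k], n_samples=2000, seed=22
            ).score(am.module_z(mod.nodes, sm), mod.k),
            abs=0.2,  # different sampling seeds; same contract
        )


def test_empty_score_map_fatal():
    g = build_graph(make_ppi(20, m=2, seed=0))
    with pytest.raises(ValueError, match="empty score map"):
        am.search_modules(g, am.NodeScoreMap(p={}, z={}), seed=0)
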