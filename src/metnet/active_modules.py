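"""Expression-responsive (active) subnetwork discovery.

Each node carries a p-value from the differential-expression step and is
scored z_i = Phi^-1(1 - p_i).  A candidate subnetwork A with k members gets
the aggregate score

    z(A) = sum_i z_i / sqrt(k)        (default ``sqrt_k`` variant)
    z(A) = sum_i z_i / k              (``k`` variant)

which is calibrated against the Monte-Carlo mean and standard deviation of
z(A) over random k-node groups of the same graph:

    s(A) = (z(A) - mean_k) / sd_k

The sqrt(k) form keeps s(A) comparable across sizes (for iid standard-normal
node scores z(A) is N(0, 1) for every k), which is what the calibration step
presupposes; the 1/k variant is provided for completeness.  Search is a
greedy connected expansion from the highest-scoring nodes, with an optional
seeded simulated-annealing strategy behind the same score contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

P_CLAMP_LOW = 1e-16
P_CLAMP_HIGH = 1.0 - 1e-16

VARIANTS = ("sqrt_k", "k")


def z_transform(p, clamp: bool = False):
    """z = Phi^-1(1 - p), the upper-tail standard-normal quantile of p.

    With ``clamp`` the p-values are pushed into [1e-16, 1 - 1e-16] so the
    transform stays finite; otherwise p outside (0, 1] is fatal.
    """
    arr = np.asarray(p, dtype=float)
    if clamp:
        arr = np.clip(arr, P_CLAMP_LOW, P_CLAMP_HIGH)
    elif np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1] (enable clamping for p=0)")
    out = stats.norm.isf(arr)
    return float(out) if np.isscalar(p) else out


@dataclass
class NodeScoreMap:
    """Per-node p-values and their z-scores; nodes without a p get z = 0."""

    p: dict[str, float]
    z: dict[str, float]

    @classmethod
    def from_pvalues(cls, pvalues: dict[str, float], clamp: bool = True) -> "NodeScoreMap":
        nodes = sorted(pvalues)
        zs = z_transform(np.array([pvalues[n] for n in nodes]), clamp=clamp)
        return cls(p=dict(pvalues), z={n: float(z) for n, z in zip(nodes, zs)})

    def z_for(self, node: str) -> float:
        return self.z.get(node, 0.0)


def module_z(nodes, score_map: NodeScoreMap, variant: str = "sqrt_k") -> float:
    """Aggregate z(A) for a node set under the chosen size normalization."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    nodes = list(nodes)
    if not nodes:
        raise ValueError("module must be non-empty")
    total = sum(score_map.z_for(n) for n in nodes)
    k = len(nodes)
    return total / np.sqrt(k) if variant == "sqrt_k" else total / k


@dataclass
class Calibration:
    """Per-k Monte-Carlo null mean and sd of z(A) over random k-node groups."""

    mean: dict[int, float]
    sd: dict[int, float]
    variant: str
    n_samples: int

    def score(self, z_a: float, k: int) -> float:
        sd = self.sd[k]
        if sd == 0:
            return 0.0
        return (z_a - self.mean[k]) / sd


def calibrate(
    network: nx.Graph,
    score_map: NodeScoreMap,
    k_values,
    n_samples: int = 10000,
    seed: int = 0,
    variant: str = "sqrt_k",
    connected: bool = False,
) -> Calibration:
    """Estimate the null mean/sd of z(A) for each k in ``k_values``.

    The null samples arbitrary k-node groups (without replacement) by default;
    ``connected=True`` instead grows random connected subsets, which is slower
    and only needed when the null should respect graph structure.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    nodes = sorted(network.nodes())
    k_values = sorted(set(int(k) for k in k_values))
    if not k_values or k_values[0] < 1:
        raise ValueError("k values must be >= 1")
    if k_values[-1] > len(nodes):
        raise ValueError(f"k={k_values[-1]} exceeds network size {len(nodes)}")
    rng = np.random.default_rng(seed)
    z = np.array([score_map.z_for(n) for n in nodes])
    mean: dict[int, float] = {}
    sd: dict[int, float] = {}
    if not connected:
        # A random k-prefix of a random permutation is a uniform k-subset, so
        # one cumulative sum per permutation yields every k at once.
        mat = np.tile(z, (n_samples, 1))
        rng.permuted(mat, axis=1, out=mat)
        sums = np.cumsum(mat, axis=1)
        for k in k_values:
            denom = np.sqrt(k) if variant == "sqrt_k" else k
            vals = sums[:, k - 1] / denom
            mean[k] = float(vals.mean())
            sd[k] = float(vals.std(ddof=0))
    else:
        adj = {n: sorted(network.neighbors(n)) for n in nodes}
        for k in k_values:
            denom = np.sqrt(k) if variant == "sqrt_k" else k
            vals = np.empty(n_samples)
            for i in range(n_samples):
                vals[i] = _random_connected_sum(adj, nodes, k, rng, score_map) / denom
            mean[k] = float(vals.mean())
            sd[k] = float(vals.std(ddof=0))
    return Calibration(mean=mean, sd=sd, variant=variant, n_samples=n_samples)


def _random_connected_sum(adj, nodes, k, rng, score_map) -> float:
    for _ in range(100):
        start = nodes[rng.integers(len(nodes))]
        subset = {start}
        boundary = set(adj[start])
        while len(subset) < k and boundary:
            pick = sorted(boundary)[rng.integers(len(boundary))]
            subset.add(pick)
            boundary |= set(adj[pick])
            boundary -= subset
        if len(subset) == k:
            return sum(score_map.z_for(n) for n in subset)
    raise RuntimeError(f"could not sample a connected {k}-node subset")


@dataclass(frozen=True)
class ScoredModule:
    nodes: frozenset[str]
    z_a: float
    s_a: float
    formula_variant: str

    @property
    def k(self) -> int:
        return len(self.nodes)


def _greedy_from(start, adj, zmap, calibration, variant, max_k):
    members = [start]
    member_set = {start}
    total = zmap[start]
    denom = np.sqrt(1) if variant == "sqrt_k" else 1
    s_cur = calibration.score(total / denom, 1)
    boundary = dict.fromkeys(adj[start])
    while len(members) < max_k and boundary:
        # s is monotone in the candidate's z at fixed k: the best addition is
        # simply the boundary node with the largest z (ties by gene key)
        best = min(boundary, key=lambda n: (-zmap[n], n))
        k_new = len(members) + 1
        denom = np.sqrt(k_new) if variant == "sqrt_k" else k_new
        s_new = calibration.score((total + zmap[best]) / denom, k_new)
        if not (s_new > s_cur):
            break
        members.append(best)
        member_set.add(best)
        total += zmap[best]
        s_cur = s_new
        del boundary[best]
        for n in adj[best]:
            if n not in member_set:
                boundary[n] = None
    return frozenset(member_set), total, s_cur


def search_modules(
    network: nx.Graph,
    score_map: NodeScoreMap,
    strategy: str = "greedy",
    n_restarts: int = 10,
    max_k: int = 250,
    seed: int = 0,
    variant: str = "sqrt_k",
    calibration: Calibration | None = None,
    n_samples: int = 10000,
    overlap: bool = False,
) -> list[ScoredModule]:
    """Search for high-scoring connected modules.

    Greedy: from each of ``n_restarts`` start nodes (highest z first), add
    the neighboring node that maximizes s(A) until no addition improves the
    score or k reaches ``max_k``.  ``simulated_annealing`` refines each greedy
    module with seeded geometric-cooling moves.  Returned modules are sorted
    by s(A) and mutually trimmed to non-overlapping node sets unless
    ``overlap`` is set.
    """
    if not score_map.z:
        raise ValueError("empty score map")
    nodes = sorted(network.nodes())
    if not nodes:
        raise ValueError("empty network")
    max_k = min(max_k, len(nodes))
    zmap = {n: score_map.z_for(n) for n in nodes}
    if calibration is None:
        calibration = calibrate(
            network, score_map, range(1, max_k + 1), n_samples=n_samples,
            seed=seed, variant=variant,
        )
    adj = {n: sorted(network.neighbors(n)) for n in nodes}
    starts = sorted(nodes, key=lambda n: (-zmap[n], n))[:n_restarts]
    modules: list[ScoredModule] = []
    rng = np.random.default_rng(seed)
    for start in starts:
        member_set, total, s_cur = _greedy_from(start, adj, zmap, calibration, variant, max_k)
        if strategy == "simulated_annealing":
            member_set, total, s_cur = _anneal(
                member_set, total, s_cur, adj, zmap, calibration, variant, max_k, rng
            )
        elif strategy != "greedy":
            raise ValueError(f"unknown strategy {strategy!r}")
        denom = np.sqrt(len(member_set)) if variant == "sqrt_k" else len(member_set)
        modules.append(
            ScoredModule(
                nodes=member_set, z_a=total / denom, s_a=s_cur, formula_variant=variant
            )
        )
    modules.sort(key=lambda m: (-m.s_a, m.k, sorted(m.nodes)))
    if overlap:
        return modules
    kept: list[ScoredModule] = []
    used: set[str] = set()
    for mod in modules:
        if mod.nodes & used:
            continue
        kept.append(mod)
        used |= mod.nodes
    return kept


def _anneal(member_set, total, s_cur, adj, zmap, calibration, variant, max_k, rng,
            n_iter: int = 2000, t0: float = 1.0, cooling: float = 0.997):
    """Seeded Metropolis refinement: add a boundary node or drop a member
    whose removal keeps the module connected and non-empty."""
    members = set(member_set)
    best = (frozenset(members), total, s_cur)
    temp = t0
    for _ in range(n_iter):
        temp *= cooling
        boundary = sorted({n for m in members for n in adj[m] if n not in members})
        removable = sorted(_removable(members, adj)) if len(members) > 1 else []
        moves = []
        if boundary and len(members) < max_k:
            moves.append("add")
        if removable:
            moves.append("remove")
        if not moves:
            break
        move = moves[rng.integers(len(moves))]
        if move == "add":
            cand = boundary[rng.integers(len(boundary))]
            new_members = members | {cand}
            new_total = total + zmap[cand]
        else:
            cand = removable[rng.integers(len(removable))]
            new_members = members - {cand}
            new_total = total - zmap[cand]
        k = len(new_members)
        denom = np.sqrt(k) if variant == "sqrt_k" else k
        s_new = calibration.score(new_total / denom, k)
        if s_new >= s_cur or rng.random() < np.exp((s_new - s_cur) / max(temp, 1e-9)):
            members, total, s_cur = new_members, new_total, s_new
            if s_cur > best[2]:
                best = (frozenset(members), total, s_cur)
    return best


def _removable(members: set[str], adj) -> list[str]:
    sub = nx.Graph()
    sub.add_nodes_from(members)
    for m in members:
        for n in adj[m]:
            if n in members:
                sub.add_edge(m, n)
    cut = set(nx.articulation_points(sub))
    return [m for m in members if m not in cut]
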