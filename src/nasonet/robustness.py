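"""Network stability under node-removal attack, IVI centrality, keystones.

Natural connectivity ln(mean(exp(eigenvalues(A)))) measures the redundancy
of alternative routes in a network; it strictly increases with every added
edge. We normalize by N - ln(N), the natural connectivity of the complete
graph on N nodes, so values are comparable across remaining-network sizes.
Attack robustness is compared between two networks with per-step Wilcoxon
rank-sum tests merged by the weighted Simes rule, weighting each step by
the number of remaining nodes. Keystones are detected by walking down the
IVI (integrated value of influence) ranking and testing each removal prefix
against random-order removals.

All robustness work uses the unsigned skeleton of the network; interaction
signs enter only through ``negative_subnetwork``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .ensemble import SignedNetwork, weighted_simes

__all__ = [
    "AttackTrajectory",
    "IVITable",
    "KeystoneReport",
    "natural_connectivity",
    "normalized_natural_connectivity",
    "random_attack",
    "compare_group_robustness",
    "negative_subnetwork",
    "ivi",
    "keystone_detection",
    "ivi_abundance_correlation",
]


# --------------------------------------------------------------------------
# natural connectivity


def _as_graph(graph: nx.Graph | SignedNetwork) -> nx.Graph:
    return graph.graph if isinstance(graph, SignedNetwork) else graph


def natural_connectivity(graph: nx.Graph | SignedNetwork) -> float:
    """ln((1/N) sum exp(lambda_i)) over adjacency eigenvalues; 0 for N = 0."""
    g = _as_graph(graph)
    n = g.number_of_nodes()
    if n == 0:
        return 0.0
    if g.number_of_edges() == 0:
        return 0.0
    a = nx.to_numpy_array(g, weight=None)
    eigs = np.linalg.eigvalsh(a)
    # shift by the max eigenvalue for overflow-safe logsumexp
    m = eigs.max()
    return float(m + np.log(np.exp(eigs - m).sum() / n))


def normalized_natural_connectivity(graph: nx.Graph | SignedNetwork) -> float:
    """Natural connectivity divided by N - ln(N) (the complete graph's value)."""
    g = _as_graph(graph)
    n = g.number_of_nodes()
    if n <= 1:
        return 0.0
    return natural_connectivity(g) / (n - np.log(n))


# --------------------------------------------------------------------------
# attacks


@dataclass
class AttackTrajectory:
    """Normalized natural connectivity after removing k = 1..N-1 nodes.

    ``connectivity_samples[k]`` holds ``n_attacks`` values in random mode and
    a single value per k in targeted mode.
    """

    removal_counts: list[int]
    connectivity_samples: dict[int, np.ndarray]
    attack_mode: str
    n_nodes: int
    seed: int | None = None


def random_attack(
    graph: nx.Graph | SignedNetwork, n_attacks: int = 1000, seed: int = 0
) -> AttackTrajectory:
    """Repeated uniform node-subset removal, k = 1 .. N-1 nodes per attack.

    For each removal count k, ``n_attacks`` independent uniformly chosen
    k-subsets are removed and the normalized natural connectivity of each
    remaining induced subgraph is recorded.
    """
    g = _as_graph(graph)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least two nodes to attack")
    if n_attacks < 1:
        raise ValueError("n_attacks must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    samples: dict[int, np.ndarray] = {}
    for k in range(1, n):
        vals = np.empty(n_attacks)
        for t in range(n_attacks):
            keep = rng.permutation(n)[k:]
            vals[t] = _nnc_from_adjacency(a[np.ix_(keep, keep)])
        samples[k] = vals
    return AttackTrajectory(list(range(1, n)), samples, "random", n, seed)


def _nnc_from_adjacency(a: np.ndarray) -> float:
    m = a.shape[0]
    if m <= 1 or not a.any():
        return 0.0
    eigs = np.linalg.eigvalsh(a)
    top = eigs.max()
    nc = top + np.log(np.exp(eigs - top).sum() / m)
    return float(nc / (m - np.log(m)))


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p (normal approximation, tie-corrected)."""
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:  # all values identical: no evidence either way
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(max(res.pvalue, 1e-300))  # guard underflow for the Simes merge


def compare_group_robustness(
    traj_a: AttackTrajectory, traj_b: AttackTrajectory
) -> dict:
    """Compare two random-attack trajectories step by step.

    Per common removal count k a two-sided rank-sum test; the per-k p-values
    are merged by weighted Simes with the number of remaining nodes of the
    larger network as the weight. ``direction`` reports which trajectory has
    the higher median at each k, and ``overall_direction`` the majority call.
    """
    if traj_a.attack_mode != "random" or traj_b.attack_mode != "random":
        raise ValueError("robustness comparison requires random-mode trajectories")
    common = sorted(set(traj_a.removal_counts) & set(traj_b.removal_counts))
    if not common:
        raise ValueError("trajectories share no removal counts")
    n_big = max(traj_a.n_nodes, traj_b.n_nodes)
    per_k_p, weights, direction = [], [], []
    for k in common:
        x, y = traj_a.connectivity_samples[k], traj_b.connectivity_samples[k]
        per_k_p.append(_ranksum_p(x, y))
        weights.append(n_big - k)
        med_a, med_b = np.median(x), np.median(y)
        direction.append("a" if med_a > med_b else ("b" if med_b > med_a else "tie"))
    merged = weighted_simes(per_k_p, weights)
    calls = [d for d in direction if d != "tie"]
    overall = max(("a", "b"), key=calls.count) if calls else "tie"
    return {
        "removal_counts": common,
        "per_k_p": per_k_p,
        "weights": weights,
        "direction": direction,
        "merged_p": merged,
        "overall_direction": overall,
    }


def negative_subnetwork(net: SignedNetwork) -> nx.Graph:
    """Subgraph on sign = -1 edges; nodes without negative edges are dropped."""
    g = nx.Graph()
    for a, b, d in net.graph.edges(data=True):
        if d.get("sign") == -1:
            g.add_edge(a, b, **d)
            g.nodes[a].update(net.graph.nodes[a])
            g.nodes[b].update(net.graph.nodes[b])
    return g


# --------------------------------------------------------------------------
# IVI


@dataclass
class IVITable:
    """Per-node influence components, each min-max scaled to [1, 100]."""

    nodes: list[str]
    components: dict[str, np.ndarray]
    ivi: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.nodes, self.ivi))

    def ranking(self) -> list[str]:
        # descending IVI, ties broken lexicographically by node id
        order = sorted(range(len(self.nodes)), key=lambda i: (-self.ivi[i], self.nodes[i]))
        return [self.nodes[i] for i in order]


def _scale_1_100(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:  # constant component: every node equally influential
        return np.full_like(x, 100.0)
    return 1.0 + 99.0 * (x - lo) / (hi - lo)


def _h_index(values: list[int]) -> int:
    values = sorted(values, reverse=True)
    h = 0
    for rank, v in enumerate(values, start=1):
        if v >= rank:
            h = rank
        else:
            break
    return h


def ivi(graph: nx.Graph | SignedNetwork) -> IVITable:
    """Integrated value of influence of every node, scaled to [1, 100].

    Components: degree; ClusterRank 10^(-c_i) * sum_{j in N(i)} (deg_j + 1);
    neighborhood connectivity (mean neighbor degree); local H-index
    h(i) + sum of neighbors' h; betweenness; collective influence
    (deg_i - 1) * sum over distance-2 nodes of (deg_j - 1). Hubness =
    scaled degree + scaled local H-index; spreading = (scaled ClusterRank +
    scaled neighborhood connectivity) * (scaled betweenness + scaled
    collective influence); IVI = min-max(hubness * spreading) into [1, 100].
    """
    g = _as_graph(graph)
    nodes = list(g.nodes)
    n = len(nodes)
    if n < 2:
        raise ValueError("IVI requires at least two nodes")
    deg = dict(g.degree())
    degree = np.array([deg[v] for v in nodes], dtype=float)

    clustering = nx.clustering(g)
    clusterrank = np.array(
        [
            10.0 ** (-clustering[v]) * sum(deg[u] + 1 for u in g.neighbors(v))
            for v in nodes
        ]
    )
    neighborhood = np.array(
        [
            np.mean([deg[u] for u in g.neighbors(v)]) if deg[v] > 0 else 0.0
            for v in nodes
        ]
    )
    h = {v: _h_index([deg[u] for u in g.neighbors(v)]) for v in nodes}
    local_h = np.array([h[v] + sum(h[u] for u in g.neighbors(v)) for v in nodes], dtype=float)
    btw = nx.betweenness_centrality(g, normalized=True)
    betweenness = np.array([btw[v] for v in nodes])
    ci = np.empty(n)
    for idx, v in enumerate(nodes):
        dist2 = {
            w
            for u in g.neighbors(v)
            for w in g.neighbors(u)
            if w != v and w not in g[v]
        }
        ci[idx] = (deg[v] - 1) * sum(deg[w] - 1 for w in dist2)

    comp = {
        "degree": degree,
        "clusterrank": clusterrank,
        "neighborhood_connectivity": neighborhood,
        "local_h_index": local_h,
        "betweenness": betweenness,
        "collective_influence": ci,
    }
    scaled = {k: _scale_1_100(v) for k, v in comp.items()}
    hubness = scaled["degree"] + scaled["local_h_index"]
    spreading = (scaled["clusterrank"] + scaled["neighborhood_connectivity"]) * (
        scaled["betweenness"] + scaled["collective_influence"]
    )
    ivi_vals = _scale_1_100(hubness * spreading)
    comp["hubness"] = hubness
    comp["spreading"] = spreading
    return IVITable(nodes, comp, ivi_vals)


# --------------------------------------------------------------------------
# keystones


@dataclass
class KeystoneReport:
    keystone_nodes: list[str]
    ranking: list[str]
    prefix_p: list[float]
    n_permutations: int
    alpha: float
    ivi_table: IVITable = field(repr=False, default=None)


def keystone_detection(
    net: SignedNetwork | nx.Graph,
    n_permutations: int = 1000,
    alpha: float = 0.001,
    seed: int = 0,
    max_prefix: int | None = None,
) -> KeystoneReport:
    """Permutational keystone test along the descending-IVI removal order.

    The targeted trajectory removes nodes cumulatively in descending IVI
    order (ties broken lexicographically), recording normalized natural
    connectivity at each prefix. The null consists of ``n_permutations``
    random removal orders. Per-prefix p = (1 + #{null <= targeted}) /
    (n_permutations + 1); the keystone set is the maximal initial prefix
    significant at every step (empty if the first step is not).

    Evaluation stops one step after the prefix stops being significant
    (later prefixes cannot extend the maximal significant prefix), or at
    ``max_prefix``.
    """
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n < 3 or g.number_of_edges() == 0:
        raise ValueError("keystone detection needs >= 3 nodes with edges")
    if n_permutations < 1 / alpha - 1:
        raise ValueError(
            f"{n_permutations} permutations cannot reach alpha={alpha}; "
            f"need at least {int(np.ceil(1 / alpha - 1))}"
        )
    ivi_table = ivi(g)
    ranking = ivi_table.ranking()
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    pos = {v: i for i, v in enumerate(nodes)}
    rng = np.random.default_rng(seed)
    null_orders = [rng.permutation(n) for _ in range(n_permutations)]
    targeted_order = np.array([pos[v] for v in ranking])

    limit = n - 1 if max_prefix is None else min(max_prefix, n - 1)
    prefix_p: list[float] = []
    keystones: list[str] = []
    for m in range(1, limit + 1):
        keep_t = np.setdiff1d(np.arange(n), targeted_order[:m])
        targeted_val = _nnc_from_adjacency(a[np.ix_(keep_t, keep_t)])
        count = 0
        for order in null_orders:
            keep = order[m:]
            if _nnc_from_adjacency(a[np.ix_(keep, keep)]) <= targeted_val:
                count += 1
        p = (1 + count) / (n_permutations + 1)
        prefix_p.append(p)
        if p < alpha:
            keystones.append(ranking[m - 1])
        else:
            break
    return KeystoneReport(keystones, ranking, prefix_p, n_permutations, alpha, ivi_table)


def ivi_abundance_correlation(
    ivi_table: IVITable, mean_abundances: dict[str, float]
) -> tuple[float, float]:
    """Spearman correlation between node IVI and mean relative abundance."""
    common = [v for v in ivi_table.nodes if v in mean_abundances]
    if len(common) < 3:
        raise ValueError("need at least three taxa in common")
    ivi_vals = [ivi_table.as_dict()[v] for v in common]
    ab = [mean_abundances[v] for v in common]
    rho, p = stats.spearmanr(ivi_vals, ab)
    return float(rho), float(p)
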