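"""Binarization and topological characterization of similarity networks.

Networks are thresholded over a sparsity grid with a maximum-spanning-tree
backbone so every binary network is connected, then characterized by the
standard battery: small-world attributes normalized against degree-preserving
rewired nulls, rich-club coefficients, degree-distribution model fits, and
hub identification from z-scored mean nodal degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import curve_fit

from .types import BinaryNetwork, SimilarityNetwork

__all__ = [
    "DEFAULT_SPARSITY_GRID",
    "threshold_sparsity",
    "rewired_null",
    "small_world",
    "rich_club",
    "DegreeFit",
    "fit_degree_distribution",
    "identify_hubs",
    "mean_nodal_degree",
    "topology_report",
]

# consecutive sparsity range [0.09, 0.3] with an interval of 0.02 (11 levels)
DEFAULT_SPARSITY_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(0.09, 0.30 + 1e-9, 0.02), 2)
)


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def _sorted_edges(matrix: np.ndarray) -> list[tuple[int, int]]:
    """Edges sorted by similarity descending, ties by (i, j) ascending."""
    n = matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = matrix[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return [(int(iu[k]), int(ju[k])) for k in order]


def threshold_sparsity(net: SimilarityNetwork, sparsity: float) -> BinaryNetwork:
    """Binarize at a target sparsity with guaranteed connectivity.

    The edge set is the maximum spanning tree of the similarity matrix (so no
    node is isolated and there is a single component) plus the strongest
    remaining edges until round(sparsity * R(R-1)/2) edges are kept. Ties are
    broken deterministically by similarity descending then region-index pair
    ascending.
    """
    if not (0 < sparsity <= 1):
        raise ValueError(f"sparsity must lie in (0, 1], got {sparsity}")
    r = net.n_regions
    target = int(round(sparsity * net.n_edges))
    if target < r - 1:
        raise ValueError(
            f"sparsity {sparsity} keeps {target} edges; {r - 1} needed to connect {r} nodes"
        )
    edges = _sorted_edges(net.matrix)
    uf = _UnionFind(r)
    chosen: list[tuple[int, int]] = []
    in_tree = set()
    for i, j in edges:  # Kruskal on descending similarity = maximum spanning tree
        if uf.union(i, j):
            chosen.append((i, j))
            in_tree.add((i, j))
            if len(chosen) == r - 1:
                break
    for i, j in edges:
        if len(chosen) >= target:
            break
        if (i, j) not in in_tree:
            chosen.append((i, j))
    adj = np.zeros((r, r), dtype=np.int8)
    for i, j in chosen:
        adj[i, j] = adj[j, i] = 1
    return BinaryNetwork(adjacency=adj, sparsity=sparsity, region_ids=net.region_ids)


def _to_graph(bnet: BinaryNetwork) -> nx.Graph:
    return nx.from_numpy_array(np.asarray(bnet.adjacency))


def _require_connected(g: nx.Graph) -> None:
    if g.number_of_nodes() == 0 or not nx.is_connected(g):
        raise ValueError("binary network must be connected")


def rewired_null(bnet: BinaryNetwork, rng: np.random.Generator, swap_factor: int = 10) -> nx.Graph:
    """Degree-preserving rewired null keeping the network connected.

    Performs ``swap_factor * E`` attempted double-edge swaps; each accepted
    swap preserves every node's degree exactly.
    """
    g = _to_graph(bnet)
    n_swap = swap_factor * g.number_of_edges()
    seed = int(rng.integers(0, 2**31 - 1))
    try:
        nx.connected_double_edge_swap(g, nswap=n_swap, seed=seed)
    except nx.NetworkXError:
        # graphs too small/rigid to admit any swap serve as their own null
        pass
    return g


def small_world(
    bnet: BinaryNetwork,
    n_null: int = 100,
    seed: Optional[int] = None,
) -> tuple[float, float, float, float]:
    """Clustering, path length, and their null-normalized ratios.

    Returns (Cp, Lp, gamma, lambda): Cp is the mean local clustering
    coefficient, Lp the characteristic path length (mean shortest-path hop
    count over all pairs), gamma = Cp / <Cp_rand> and lambda = Lp / <Lp_rand>
    over ``n_null`` degree-preserving rewired null networks. A small-world
    network has gamma > 1 with lambda close to 1.
    """
    g = _to_graph(bnet)
    _require_connected(g)
    cp = nx.average_clustering(g)
    lp = nx.average_shortest_path_length(g)
    rng = np.random.default_rng(seed)
    cps, lps = [], []
    for _ in range(n_null):
        gr = rewired_null(bnet, rng)
        cps.append(nx.average_clustering(gr))
        lps.append(nx.average_shortest_path_length(gr))
    cp_rand = float(np.mean(cps))
    lp_rand = float(np.mean(lps))
    gamma = cp / cp_rand if cp_rand > 0 else np.nan
    lam = lp / lp_rand if lp_rand > 0 else np.nan
    return float(cp), float(lp), float(gamma), float(lam)


def _phi_curve(adj: np.ndarray, kmax: int) -> np.ndarray:
    """Rich-club coefficient phi(k) for k = 1..kmax; NaN where undefined."""
    deg = adj.sum(axis=0)
    out = np.full(kmax, np.nan)
    for k in range(1, kmax + 1):
        keep = deg > k
        n_keep = int(keep.sum())
        if n_keep < 2:
            continue
        sub = adj[np.ix_(keep, keep)]
        e_keep = sub.sum() / 2.0
        out[k - 1] = 2.0 * e_keep / (n_keep * (n_keep - 1))
    return out


def rich_club(
    bnet: BinaryNetwork,
    n_null: int = 100,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rich-club curve and its null-normalized version.

    Returns (k_values, phi, phi_norm) for k = 1 .. max degree - 1. phi(k) is
    the edge density among nodes with degree > k; entries are NaN where fewer
    than two such nodes exist. phi_norm divides by the mean curve of
    degree-preserving rewired nulls; values > 1 over a consecutive range of k
    indicate rich-club organization.
    """
    g = _to_graph(bnet)
    _require_connected(g)
    adj = np.asarray(bnet.adjacency, dtype=float)
    kmax = int(adj.sum(axis=0).max()) - 1
    if kmax < 1:
        return np.array([], dtype=int), np.array([]), np.array([])
    phi = _phi_curve(adj, kmax)
    rng = np.random.default_rng(seed)
    null_curves = np.full((n_null, kmax), np.nan)
    for b in range(n_null):
        gr = rewired_null(bnet, rng)
        null_curves[b] = _phi_curve(nx.to_numpy_array(gr), kmax)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        phi_rand = np.nanmean(null_curves, axis=0)
        phi_norm = phi / phi_rand
    return np.arange(1, kmax + 1), phi, phi_norm


def _ccdf(degrees: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Complementary cumulative distribution P(K >= k) at distinct degrees."""
    ks = np.unique(degrees)
    p = np.array([(degrees >= k).mean() for k in ks], dtype=float)
    return ks.astype(float), p


@dataclass
class DegreeFit:
    """Degree-distribution model comparison on the CCDF."""

    best_model: str
    params: dict[str, dict[str, float]] = field(default_factory=dict)
    aic: dict[str, float] = field(default_factory=dict)
    failed: list[str] = field(default_factory=list)


_MODELS = {
    "power-law": (
        lambda k, c, a: c * k ** (-a),
        {"c": (1.0, 1.0), "a": (1.0, 1.0)},
    ),
    "exponential": (
        lambda k, c, kc: c * np.exp(-k / kc),
        {"c": (1.0, 1.0), "kc": (5.0, 5.0)},
    ),
    "truncated power-law": (
        lambda k, c, a, kc: c * k ** (a - 1.0) * np.exp(-k / kc),
        {"c": (1.0, 1.0), "a": (1.0, 1.0), "kc": (5.0, 5.0)},
    ),
}


def fit_degree_distribution(mean_degrees: Sequence[float]) -> DegreeFit:
    """Fit the CCDF of mean nodal degree under three candidate models.

    Power law, exponential and exponentially truncated power law are fitted
    by nonlinear least squares; the reported best model minimizes AIC
    (n log(RSS/n) + 2 n_params). At least 5 distinct degree values are
    required.
    """
    degrees = np.asarray(mean_degrees, dtype=float)
    if np.unique(degrees).size < 5:
        raise ValueError("need at least 5 distinct degree values to fit models")
    k, p = _ccdf(degrees)
    if np.any(k <= 0):
        k = k + 1e-9  # power-law form requires positive support
    fit = DegreeFit(best_model="")
    n = k.size
    for name, (func, p0_map) in _MODELS.items():
        p0 = [v[0] for v in p0_map.values()]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(func, k, p, p0=p0, maxfev=20000)
            rss = float(np.sum((p - func(k, *popt)) ** 2))
            # floor the RSS at solver tolerance so nested models that both
            # fit exactly are separated by the parameter-count penalty
            aic = n * np.log(max(rss, 1e-12) / n) + 2 * len(popt)
            fit.params[name] = dict(zip(p0_map.keys(), (float(v) for v in popt)))
            fit.aic[name] = float(aic)
        except RuntimeError:
            fit.failed.append(name)
    if not fit.aic:
        raise RuntimeError("all degree-distribution fits failed to converge")
    fit.best_model = min(fit.aic, key=fit.aic.get)
    return fit


def identify_hubs(
    mean_degrees: Sequence[float], region_ids: Sequence[int]
) -> list[int]:
    """Regions whose z-scored mean nodal degree strictly exceeds 1."""
    degrees = np.asarray(mean_degrees, dtype=float)
    ids = list(region_ids)
    if degrees.size != len(ids) or degrees.size < 2:
        raise ValueError("need >= 2 regions with matching ids")
    sd = float(np.std(degrees, ddof=1))
    if sd == 0:
        warnings.warn("zero variance in mean degrees; no hubs identified")
        return []
    z = (degrees - degrees.mean()) / sd
    return [ids[i] for i in np.nonzero(z > 1)[0]]


def mean_nodal_degree(
    networks: Sequence[SimilarityNetwork],
    sparsities: Sequence[float] = DEFAULT_SPARSITY_GRID,
) -> np.ndarray:
    """Nodal degree averaged across subjects and sparsity levels."""
    if not networks:
        raise ValueError("need at least one network")
    acc = np.zeros(networks[0].n_regions)
    count = 0
    for net in networks:
        for s in sparsities:
            acc += threshold_sparsity(net, s).degrees()
            count += 1
    return acc / count


def topology_report(
    net: SimilarityNetwork,
    sparsities: Sequence[float] = DEFAULT_SPARSITY_GRID,
    n_null: int = 100,
    seed: Optional[int] = None,
) -> dict:
    """Per-sparsity small-world and rich-club metrics for one network."""
    rows = []
    rng = np.random.default_rng(seed)
    for s in sparsities:
        bnet = threshold_sparsity(net, s)
        sub = int(rng.integers(0, 2**31 - 1))
        cp, lp, gamma, lam = small_world(bnet, n_null=n_null, seed=sub)
        kvals, phi, phi_norm = rich_club(bnet, n_null=n_null, seed=sub)
        rows.append(
            {
                "sparsity": float(s),
                "n_edges": bnet.n_edges,
                "Cp": cp,
                "Lp": lp,
                "gamma": gamma,
                "lambda": lam,
                "rich_club_k": kvals.tolist(),
                "phi": phi.tolist(),
                "phi_norm": phi_norm.tolist(),
                "degrees": bnet.degrees().tolist(),
            }
        )
    mean_deg = mean_nodal_degree([net], sparsities)
    report = {"per_sparsity": rows, "mean_degree": mean_deg.tolist()}
    try:
        fit = fit_degree_distribution(mean_deg)
        report["degree_fit"] = {
            "best_model": fit.best_model,
            "aic": fit.aic,
            "params": fit.params,
        }
    except (ValueError, RuntimeError) as exc:
        report["degree_fit"] = {"error": str(exc)}
    report["hubs"] = identify_hubs(mean_deg, net.region_ids) if net.n_regions > 1 else []
    return report
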