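"""Communication-model prediction of other networks and gradient analysis.

A target network (hamodynamic coherence, metabolic synchronization,
structural connectivity, chemoarchitectonic covariance, gene co-expression)
is predicted from three edgewise predictors: the morphological similarity
itself plus two communication measures computed on the binarized
morphological network -- shortest path length (minimum hop count, a
centralized routing policy) and communicability (the matrix exponential of
the adjacency, a decentralized diffusion policy). Performance is the
adjusted R^2 of a multiple linear regression, at the whole-brain level
(all unique edges) and per node (that node's connection profile), with
significance from spatially constrained Moran-surrogate targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.linalg import expm
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .inference import fdr_bh, moran_surrogates, surrogate_pvalue, _moran_eigenbasis
from .topology import DEFAULT_SPARSITY_GRID, threshold_sparsity
from .types import BinaryNetwork, SimilarityNetwork, upper_triangle

__all__ = [
    "shortest_path_matrix",
    "communicability_matrix",
    "mean_communication_matrices",
    "adjusted_r2",
    "PredictionResult",
    "predict_network",
    "matrix_moran_surrogate",
    "GradientResult",
    "gradients",
    "connected_vs_unconnected",
]


def shortest_path_matrix(bnet: BinaryNetwork) -> np.ndarray:
    """Hop-count shortest paths between all node pairs of a binary network."""
    adj = np.asarray(bnet.adjacency, dtype=float)
    d = _csgraph_shortest_path(adj, method="D", unweighted=True)
    if np.isinf(d).any():
        raise ValueError("binary network must be connected")
    return d.astype(int)


def communicability_matrix(bnet: BinaryNetwork) -> np.ndarray:
    """Communicability: weighted sum over all walks = exp(A)."""
    adj = np.asarray(bnet.adjacency, dtype=float)
    if not np.allclose(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    return expm(adj)


def mean_communication_matrices(
    networks: Sequence[SimilarityNetwork],
    sparsities: Sequence[float] = DEFAULT_SPARSITY_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """Shortest-path and communicability matrices from individual binary
    networks, averaged across subjects and the sparsity grid."""
    spl_acc = None
    com_acc = None
    count = 0
    for net in networks:
        for s in sparsities:
            bnet = threshold_sparsity(net, s)
            spl = shortest_path_matrix(bnet).astype(float)
            com = communicability_matrix(bnet)
            spl_acc = spl if spl_acc is None else spl_acc + spl
            com_acc = com if com_acc is None else com_acc + com
            count += 1
    if count == 0:
        raise ValueError("need at least one network and one sparsity")
    return spl_acc / count, com_acc / count


def adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Adjusted R^2 of an ordinary least-squares fit with intercept.

    AR^2 = 1 - (1 - R^2) (n - 1) / (n - p - 1), p = number of predictors.
    Returns NaN for rank-deficient designs.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1] or n - p - 1 <= 0:
        return np.nan
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return np.nan
    r2 = 1.0 - (resid**2).sum() / tss
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


@dataclass
class PredictionResult:
    ar2_whole: float
    ar2_nodes: np.ndarray
    p_whole: Optional[float]
    p_nodes: Optional[np.ndarray]
    fdr_mask: Optional[np.ndarray]


def _node_profiles(matrix: np.ndarray, node: int) -> np.ndarray:
    """A node's connection profile: its row without the diagonal entry."""
    row = matrix[node]
    return np.delete(row, node)


def matrix_moran_surrogate(
    target: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
    basis: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One spatially constrained surrogate of a symmetric target matrix.

    Moran spectral randomization is applied to each region's connectivity
    profile (rows), then the result is symmetrized; diagonal preserved.
    """
    t = np.asarray(target, dtype=float)
    r = t.shape[0]
    if basis is None:
        basis = _moran_eigenbasis(weights)
    out = np.empty_like(t)
    for i in range(r):
        seed = int(rng.integers(0, 2**31 - 1))
        out[i] = moran_surrogates(t[i], weights, 1, seed=seed, basis=basis)[0]
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, np.diag(t))
    return out


def predict_network(
    target: np.ndarray,
    morph: SimilarityNetwork,
    spl: np.ndarray,
    comm: np.ndarray,
    surrogate_weights: Optional[np.ndarray] = None,
    n_surr: int = 1000,
    seed: Optional[int] = None,
    q: float = 0.05,
) -> PredictionResult:
    """Predict a target network from morphology plus communication measures.

    Whole-brain: the R(R-1)/2 unique target edges are regressed on the three
    predictor edge vectors (morphological similarity, shortest path length,
    communicability). Node-wise: each node's R-1 target profile is regressed
    on its three predictor profiles. Performance is adjusted R^2 (p = 3
    predictors). When ``surrogate_weights`` is given, significance is
    estimated by regenerating the *target* from Moran surrogates and
    recomputing AR^2 (one-tailed, add-one rule); node-wise p-values carry a
    BH-FDR mask.
    """
    t = np.asarray(target, dtype=float)
    m = morph.matrix
    r = morph.n_regions
    for name, mat in (("target", t), ("spl", np.asarray(spl)), ("comm", np.asarray(comm))):
        if np.asarray(mat).shape != (r, r):
            raise ValueError(f"{name} matrix must be {r}x{r} in the same region order")
    spl = np.asarray(spl, dtype=float)
    comm = np.asarray(comm, dtype=float)

    def _whole(tmat: np.ndarray) -> float:
        X = np.column_stack(
            [upper_triangle(m), upper_triangle(spl), upper_triangle(comm)]
        )
        return adjusted_r2(upper_triangle(tmat), X)

    def _nodes(tmat: np.ndarray) -> np.ndarray:
        out = np.empty(r)
        for i in range(r):
            X = np.column_stack(
                [_node_profiles(m, i), _node_profiles(spl, i), _node_profiles(comm, i)]
            )
            out[i] = adjusted_r2(_node_profiles(tmat, i), X)
        return out

    ar2_whole = _whole(t)
    ar2_nodes = _nodes(t)
    if surrogate_weights is None:
        return PredictionResult(ar2_whole, ar2_nodes, None, None, None)
    rng = np.random.default_rng(seed)
    basis = _moran_eigenbasis(surrogate_weights)
    null_whole = np.empty(n_surr)
    null_nodes = np.empty((n_surr, r))
    for b in range(n_surr):
        surr = matrix_moran_surrogate(t, surrogate_weights, rng, basis=basis)
        null_whole[b] = _whole(surr)
        null_nodes[b] = _nodes(surr)
    p_whole = surrogate_pvalue(ar2_whole, null_whole, tail="greater")
    p_nodes = np.array(
        [
            surrogate_pvalue(ar2_nodes[i], null_nodes[:, i], tail="greater")
            for i in range(r)
        ]
    )
    return PredictionResult(ar2_whole, ar2_nodes, p_whole, p_nodes, fdr_bh(p_nodes, q=q))


@dataclass
class GradientResult:
    gradients: np.ndarray  # R x n_components
    explained_variance: np.ndarray  # fractions, non-increasing


def gradients(
    net: np.ndarray,
    n_components: int = 2,
    row_top_fraction: float = 0.10,
    alpha: float = 0.5,
) -> GradientResult:
    """Connectivity gradients by diffusion-map embedding.

    Each row keeps only its top ``row_top_fraction`` entries; the affinity is
    the cosine similarity between thresholded rows; the embedding is the
    diffusion map of the affinity with anisotropic diffusion ``alpha`` = 0.5
    and automatic diffusion time (eigenvalue scaling lambda / (1 - lambda)).
    Explained-variance fractions are the normalized nontrivial eigenvalues.
    """
    w = np.asarray(net, dtype=float)
    r = w.shape[0]
    if w.ndim != 2 or w.shape[1] != r:
        raise ValueError("net must be square")
    if n_components >= r:
        raise ValueError("n_components must be smaller than the number of regions")
    rows = w.copy()
    np.fill_diagonal(rows, 0.0)
    k = max(1, int(round(row_top_fraction * r)))
    thresholded = np.zeros_like(rows)
    for i in range(r):
        top = np.argsort(rows[i])[-k:]
        thresholded[i, top] = rows[i, top]
    if np.any(thresholded < 0):
        raise ValueError("net must be nonnegative after thresholding")
    norms = np.linalg.norm(thresholded, axis=1)
    if np.any(norms == 0):
        raise ValueError("a row vanished after thresholding")
    affinity = (thresholded @ thresholded.T) / np.outer(norms, norms)
    from scipy.sparse.csgraph import connected_components as _cc

    n_comp, _ = _cc(affinity > 0, directed=False)
    if n_comp > 1:
        raise ValueError(
            "affinity graph is disconnected after row thresholding; "
            "increase row_top_fraction or supply a denser network"
        )
    # diffusion map: anisotropic normalization then row-stochastic operator
    d = affinity.sum(axis=1)
    w_alpha = affinity / np.outer(d**alpha, d**alpha)
    d2 = w_alpha.sum(axis=1)
    # symmetric conjugate of the Markov operator for a stable eigenproblem
    s = w_alpha / np.sqrt(np.outer(d2, d2))
    vals, vecs = np.linalg.eigh(s)
    order = np.argsort(-vals)
    vals, vecs = vals[order], vecs[:, order]
    # back-transform to right eigenvectors of the Markov operator
    psi = vecs / np.sqrt(d2)[:, None]
    psi = psi / np.linalg.norm(psi, axis=0)
    lam = np.clip(vals[1 : n_components + 1], None, 1 - 1e-12)
    grads = psi[:, 1 : n_components + 1] * (lam / (1 - lam))
    ev = vals[1 : n_components + 1]
    ev = np.clip(ev, 0, None)
    total = np.clip(vals[1:], 0, None).sum()
    frac = ev / total if total > 0 else np.zeros_like(ev)
    return GradientResult(gradients=grads, explained_variance=frac)


def connected_vs_unconnected(
    morph_networks: Sequence[SimilarityNetwork],
    struct: np.ndarray,
) -> tuple[float, float]:
    """Paired T test of similarity over structurally connected vs
    unconnected region pairs.

    For each subject, the mean morphological similarity over pairs with
    struct > 0 and over pairs with struct == 0 is computed; the two means are
    compared across subjects by a two-tailed paired T test. Returns (T, p)
    with df = n_subjects - 1.
    """
    if not morph_networks:
        raise ValueError("need at least one subject network")
    s = upper_triangle(np.asarray(struct, dtype=float))
    connected = s > 0
    if connected.all() or (~connected).all():
        raise ValueError("structural network must have both connected and unconnected pairs")
    mean_conn = []
    mean_unconn = []
    for net in morph_networks:
        e = net.edges()
        mean_conn.append(e[connected].mean())
        mean_unconn.append(e[~connected].mean())
    diffs = np.asarray(mean_conn) - np.asarray(mean_unconn)
    if np.allclose(diffs, 0.0):
        return 0.0, 1.0  # identical means: no evidence either way
    tstat, p = stats.ttest_rel(mean_conn, mean_unconn)
    return float(tstat), float(p)
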