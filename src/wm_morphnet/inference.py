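"""Permutation and surrogate statistics for edgewise network inference.

This module collects the statistical machinery used downstream of network
construction: spatially constrained surrogate maps by Moran spectral
randomization, threshold-free network-based statistics (TFNBS) for group
differences with max-statistic family-wise error control, partial least
squares and brain-basis-set (PCA + regression) phenotype models, linear SVM
classification, ANCOVA F maps, and Benjamini-Hochberg FDR.

All permutation engines are seeded and use the add-one p-value rule
p = (1 + #{null >= observed}) / (1 + n_perm), which can never return 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from numpy.linalg import qr
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVC

from .types import vector_to_matrix

__all__ = [
    "fdr_bh",
    "inverse_distance_weights",
    "morans_i",
    "moran_surrogates",
    "surrogate_pvalue",
    "ancova_f_map",
    "tfnbs_enhance",
    "tfnbs",
    "TFNBSResult",
    "pls1_association",
    "bbs_predict",
    "svm_classify",
]


# ---------------------------------------------------------------------------
# multiple comparisons
# ---------------------------------------------------------------------------

def fdr_bh(pvals: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean mask of rejected hypotheses."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= q * (np.arange(1, m + 1) / m)
    mask = np.zeros(m, dtype=bool)
    if below.any():
        cutoff = ranked[np.nonzero(below)[0].max()]
        mask = p <= cutoff
    return mask


# ---------------------------------------------------------------------------
# Moran spectral randomization
# ---------------------------------------------------------------------------

def inverse_distance_weights(centroids: np.ndarray) -> np.ndarray:
    """Inverse-Euclidean-distance spatial weights with a zero diagonal."""
    c = np.asarray(centroids, dtype=float)
    d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    if not np.all(np.isfinite(w)):
        raise ValueError("coincident centroids produce infinite weights")
    return w


def _check_weights(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be square")
    if not np.allclose(w, w.T):
        raise ValueError("weights must be symmetric")
    if np.any(w < 0) or np.any(np.diag(w) != 0):
        raise ValueError("weights must be nonnegative with zero diagonal")
    if np.any(w.sum(axis=1) == 0):
        raise ValueError("each region needs at least one positive weight")
    return w


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I spatial autocorrelation of a regional map."""
    w = _check_weights(weights)
    x = np.asarray(values, dtype=float)
    xc = x - x.mean()
    denom = float((xc**2).sum())
    if denom == 0:
        raise ValueError("constant map has undefined Moran's I")
    return float(x.size / w.sum() * (xc @ w @ xc) / denom)


def _moran_eigenbasis(weights: np.ndarray) -> np.ndarray:
    """Orthonormal Moran eigenvector maps: eigenvectors of the doubly
    centered weight matrix spanning the centered subspace (R x R-1)."""
    w = _check_weights(weights)
    r = w.shape[0]
    h = np.eye(r) - np.ones((r, r)) / r
    _, vecs = np.linalg.eigh(h @ w @ h)
    # drop the eigenvector aligned with the constant map
    ones = np.ones(r) / np.sqrt(r)
    align = np.abs(vecs.T @ ones)
    keep = np.argsort(align)[: r - 1]
    basis = vecs[:, np.sort(keep)]
    # re-orthogonalize against the constant to kill round-off leakage
    basis -= ones[:, None] * (ones @ basis)
    basis, _ = np.linalg.qr(basis)
    return basis


def moran_surrogates(
    values: np.ndarray,
    weights: np.ndarray,
    n_surr: int,
    seed: Optional[int] = None,
    basis: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Spatial-autocorrelation-preserving surrogates of a regional map.

    The map is decomposed on the Moran eigenvector basis of the doubly
    centered spatial weight matrix; surrogate maps randomize the sign of each
    eigenvector coefficient (the singleton procedure), which preserves the
    mean, the variance, and each eigenvector's squared loading exactly, hence
    Moran's I of the original map.

    Returns an (n_surr, R) array. Pass a precomputed ``basis`` (from the same
    weights) to amortize the eigendecomposition over many calls.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("values must be a 1D map over at least 3 regions")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if basis is None:
        basis = _moran_eigenbasis(weights)
    coeffs = basis.T @ (x - x.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_surr, coeffs.size))
    return x.mean() + (signs * coeffs) @ basis.T


def surrogate_pvalue(
    observed_stat: float, surrogate_stats: Sequence[float], tail: str = "two-sided"
) -> float:
    """Add-one permutation p-value of an observed statistic against nulls."""
    s = np.asarray(surrogate_stats, dtype=float)
    if s.size < 1:
        raise ValueError("need at least one surrogate statistic")
    if tail == "two-sided":
        count = int((np.abs(s) >= abs(observed_stat)).sum())
    elif tail == "greater":
        count = int((s >= observed_stat).sum())
    elif tail == "less":
        count = int((s <= observed_stat).sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + count) / (1 + s.size)


# ---------------------------------------------------------------------------
# ANCOVA F maps and TFNBS
# ---------------------------------------------------------------------------

def _design_matrices(
    group: np.ndarray, covariates: Optional[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Full and reduced (no group) design matrices for the edgewise GLM."""
    levels, codes = np.unique(group, return_inverse=True)
    n = codes.size
    if levels.size < 2:
        raise ValueError("need at least 2 groups")
    dummies = np.zeros((n, levels.size - 1))
    for g in range(1, levels.size):
        dummies[codes == g, g - 1] = 1.0
    parts = [np.ones((n, 1))]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match subjects")
        parts.append(cov)
    reduced = np.hstack(parts)
    full = np.hstack(parts + [dummies])
    if n <= full.shape[1]:
        raise ValueError("more design columns than subjects")
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("singular design matrix")
    df1 = levels.size - 1
    df2 = n - full.shape[1]
    return full, reduced, df1, df2


def ancova_f_map(
    edges: np.ndarray,
    group: Sequence,
    covariates: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Group-factor F statistic per edge, adjusting for covariates.

    General linear model comparing the full design (intercept + covariates +
    group dummies) against the reduced design without the group factor; with
    a single factor this equals the type-III test.
    """
    y = np.asarray(edges, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    group = np.asarray(group)
    full, reduced, df1, df2 = _design_matrices(group, covariates)
    if df2 < 1:
        raise ValueError("not enough residual degrees of freedom")
    qf, _ = qr(full, mode="reduced")
    qr_, _ = qr(reduced, mode="reduced")
    total = (y**2).sum(axis=0)
    rss_full = total - ((qf.T @ y) ** 2).sum(axis=0)
    rss_red = total - ((qr_.T @ y) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    return np.clip(f, 0.0, None)


def _edge_endpoints(n_edges: int) -> tuple[np.ndarray, np.ndarray, int]:
    r = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if r * (r - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} edges do not form a complete upper triangle")
    iu, ju = np.triu_indices(r, k=1)
    return iu, ju, r


def tfnbs_enhance(
    f_values: np.ndarray,
    extent_exp: float = 0.5,
    height_exp: float = 2.25,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free enhancement of an edgewise statistic vector.

    For n_steps thresholds h equally spaced in (0, max F], every
    supra-threshold edge accumulates (component extent in edges)^E * h^H * dh,
    where components are the connected node components of the supra-threshold
    edge graph. Thresholds are processed in descending order with an
    incremental union-find, so the whole pass is near linear in edges.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    f = np.asarray(f_values, dtype=float)
    iu, ju, r = _edge_endpoints(f.size)
    enhanced = np.zeros_like(f)
    fmax = f.max() if f.size else 0.0
    if fmax <= 0:
        return enhanced
    dh = fmax / n_steps
    order = np.argsort(-f, kind="stable")
    f_sorted = f[order]
    parent = np.arange(r)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    ptr = 0
    nodes = np.arange(r)
    for step in range(n_steps, 0, -1):
        h = dh * step
        while ptr < f.size and f_sorted[ptr] >= h:
            e = order[ptr]
            ri, rj = find(int(iu[e])), find(int(ju[e]))
            if ri != rj:
                parent[rj] = ri
            ptr += 1
        if ptr == 0:
            continue
        roots = np.array([find(int(v)) for v in nodes])
        supra = order[:ptr]
        comp = roots[iu[supra]]
        counts = np.bincount(comp, minlength=r)
        enhanced[supra] += counts[comp] ** extent_exp * h**height_exp * dh
    return enhanced


@dataclass
class TFNBSResult:
    f_matrix: np.ndarray
    enhanced_matrix: np.ndarray
    p_matrix: np.ndarray
    significant_edges: list[tuple[int, int]]
    f: np.ndarray
    enhanced: np.ndarray
    p: np.ndarray


def tfnbs(
    edges: np.ndarray,
    group: Sequence,
    covariates: Optional[np.ndarray] = None,
    extent_exp: float = 0.5,
    height_exp: float = 2.25,
    n_steps: int = 100,
    n_perm: int = 10000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    stat_fn: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None,
) -> TFNBSResult:
    """Threshold-free network-based statistics with max-stat FWE control.

    An edgewise ANCOVA F map (group factor, optional covariates) is enhanced
    across thresholds (extent exponent E = 0.5, height exponent H = 2.25);
    family-wise-corrected p-values compare each edge's enhanced score against
    the permutation distribution of the maximum enhanced score, with group
    labels shuffled and covariates held fixed.

    ``stat_fn(edges, group) -> statistic per edge`` may replace the ANCOVA F,
    e.g. a two-sample T map for post hoc contrasts (negative statistics are
    enhanced on their absolute value).
    """
    y = np.asarray(edges, dtype=float)
    group = np.asarray(group)

    if stat_fn is None:
        def stat_fn(data, labels):  # noqa: ANN001 - local closure
            return ancova_f_map(data, labels, covariates)

    def enhance(stat: np.ndarray) -> np.ndarray:
        return tfnbs_enhance(np.abs(stat), extent_exp, height_exp, n_steps)

    f_obs = np.asarray(stat_fn(y, group), dtype=float)
    enh_obs = enhance(f_obs)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(enh_obs)
    labels = group.copy()
    for _ in range(n_perm):
        rng.shuffle(labels)
        max_null = enhance(np.asarray(stat_fn(y, labels), dtype=float)).max()
        exceed += max_null >= enh_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    _, _, r = _edge_endpoints(y.shape[1])
    sig = np.nonzero(p < alpha)[0]
    iu, ju, _ = _edge_endpoints(y.shape[1])
    return TFNBSResult(
        f_matrix=vector_to_matrix(f_obs, r),
        enhanced_matrix=vector_to_matrix(enh_obs, r),
        p_matrix=vector_to_matrix(p, r, diagonal=1.0),
        significant_edges=[(int(iu[k]), int(ju[k])) for k in sig],
        f=f_obs,
        enhanced=enh_obs,
        p=p,
    )


# ---------------------------------------------------------------------------
# phenotype models
# ---------------------------------------------------------------------------

def pls1_association(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10000,
    seed: Optional[int] = None,
) -> tuple[float, float, np.ndarray]:
    """First partial-least-squares component of edges against a phenotype.

    Returns (explained variance of y in percent, permutation p, edge
    weights). The explained variance is the squared correlation between the
    PLS1 scores and y; the permutation null shuffles y across subjects.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows must match y length")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 subjects for PLS")
    if np.std(y) == 0:
        raise ValueError("constant phenotype has no PLS association")

    def _explained(yy: np.ndarray) -> tuple[float, np.ndarray]:
        pls = PLSRegression(n_components=1, scale=True)
        pls.fit(X, yy)
        scores = pls.x_scores_[:, 0]
        r = np.corrcoef(scores, yy)[0, 1]
        return float(100.0 * r**2), pls.x_weights_[:, 0].copy()

    ev_obs, weights = _explained(y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _explained(rng.permutation(y))[0]
    p = surrogate_pvalue(ev_obs, null, tail="greater")
    return ev_obs, p, weights


def _pca_to_variance(train: np.ndarray, var_retained: float) -> PCA:
    pca = PCA(n_components=min(train.shape) - 1 or 1)
    pca.fit(train)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_retained) + 1)
    n_comp = min(n_comp, pca.n_components_)
    pca_final = PCA(n_components=n_comp)
    pca_final.fit(train)
    return pca_final


def _bbs_single_cv(
    X: np.ndarray,
    y: np.ndarray,
    var_retained: float,
    folds: int,
    rng: np.random.Generator,
    collect_contrib: bool = False,
) -> tuple[float, Optional[np.ndarray]]:
    n = y.size
    kf = KFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
    pred = np.empty(n)
    contrib = np.zeros(X.shape[1]) if collect_contrib else None
    n_folds = 0
    for train_idx, test_idx in kf.split(X):
        pca = _pca_to_variance(X[train_idx], var_retained)
        scores = pca.transform(X[train_idx])
        reg = LinearRegression().fit(scores, y[train_idx])
        pred[test_idx] = reg.predict(pca.transform(X[test_idx]))
        if collect_contrib:
            contrib += pca.components_.T @ reg.coef_
        n_folds += 1
    if collect_contrib and contrib is not None:
        contrib /= n_folds
    r = np.corrcoef(y, pred)[0, 1]
    return float(r), contrib


def bbs_predict(
    X: np.ndarray,
    y: np.ndarray,
    var_retained: float = 0.80,
    folds: int = 10,
    reps: int = 100,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> tuple[float, float, np.ndarray]:
    """Brain-basis-set prediction of a phenotype from edge features.

    Per fold, a PCA fitted on the training split retains components up to
    ``var_retained`` cumulative variance, a linear regression maps component
    scores to the phenotype, and held-out subjects are predicted; the Pearson
    r(actual, predicted) per repetition of the shuffled ``folds``-fold CV is
    averaged over ``reps`` repetitions. The permutation null reshuffles y and
    repeats the CV. Edge contributions are the mean over folds and reps of
    the PCA loading x regression coefficient products summed over components.

    Returns (mean r, permutation p, edge contributions).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X rows must match y length")
    if folds > n:
        raise ValueError(f"folds ({folds}) cannot exceed subjects ({n})")
    rng = np.random.default_rng(seed)
    rs = np.empty(reps)
    contrib_acc = np.zeros(X.shape[1])
    for rep in range(reps):
        rs[rep], contrib = _bbs_single_cv(X, y, var_retained, folds, rng, True)
        contrib_acc += contrib
    mean_r = float(rs.mean())
    contributions = contrib_acc / reps
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _bbs_single_cv(X, rng.permutation(y), var_retained, folds, rng)[0]
    p = surrogate_pvalue(mean_r, null, tail="greater")
    return mean_r, p, contributions


def _stratified_folds(
    labels: np.ndarray, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Stratified fold assignment that is invariant to relabeling classes.

    Subjects are shuffled once (label-independently); within each class the
    shuffled members are dealt round-robin to folds. Swapping class names
    leaves every subject's fold unchanged, so label inversion is an exact
    symmetry of the cross-validation.
    """
    n = labels.size
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for c in np.unique(labels):
        members = order[np.isin(order, np.nonzero(labels == c)[0])]
        fold_of[members] = np.arange(members.size) % folds
    return [np.nonzero(fold_of == f)[0] for f in range(folds)]


def _svm_single_cv(
    X: np.ndarray,
    labels: np.ndarray,
    var_retained: float,
    folds: int,
    rng: np.random.Generator,
) -> float:
    test_sets = _stratified_folds(labels, folds, rng)
    all_idx = np.arange(labels.size)
    correct = 0
    for test_idx in test_sets:
        train_idx = np.setdiff1d(all_idx, test_idx)
        pca = _pca_to_variance(X[train_idx], var_retained)
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(pca.transform(X[train_idx]), labels[train_idx])
        correct += int((clf.predict(pca.transform(X[test_idx])) == labels[test_idx]).sum())
    return correct / labels.size


def svm_classify(
    X: np.ndarray,
    labels: Sequence,
    var_retained: float = 0.80,
    folds: int = 10,
    reps: int = 100,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Binary linear-SVM classification of edge features under repeated CV.

    PCA to ``var_retained`` variance on each training split, linear
    max-margin classifier, mean accuracy over ``folds``-fold CV repeated
    ``reps`` times; permutation p by reshuffling the group labels.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    if counts.min() < folds:
        raise ValueError("each class needs at least `folds` members")
    rng = np.random.default_rng(seed)
    accs = np.array(
        [_svm_single_cv(X, labels, var_retained, folds, rng) for _ in range(reps)]
    )
    mean_acc = float(accs.mean())
    null = np.empty(n_perm)
    lab = labels.copy()
    for b in range(n_perm):
        lab = rng.permutation(lab)
        null[b] = _svm_single_cv(X, lab, var_retained, folds, rng)
    p = surrogate_pvalue(mean_acc, null, tail="greater")
    return mean_acc, p


def spearman_fdr(
    x_columns: np.ndarray, y: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Columnwise Spearman correlation with y plus a BH-FDR mask."""
    x = np.asarray(x_columns, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    rhos = np.empty(x.shape[1])
    ps = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        rhos[j], ps[j] = stats.spearmanr(x[:, j], y)
    return rhos, ps, fdr_bh(ps, q=q)
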