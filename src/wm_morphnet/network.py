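"""Morphological similarity networks from voxelwise morphometric maps.

The construction pipeline: optionally smooth the map with an isotropic
Gaussian kernel, extract the voxel values of every atlas region, estimate a
regional probability distribution (PD) by Gaussian kernel density estimation
on a fixed number of sample points (2^8 by default), and score every region
pair by the Jensen-Shannon-divergence similarity

    JSDs(P, Q) = 1 - JSD(P || Q),
    JSD(P || Q) = 1/2 sum_i P_i log2(P_i / M_i) + 1/2 sum_i Q_i log2(Q_i / M_i),
    M = (P + Q) / 2,

which is 1 for identical distributions and 0 for distributions with disjoint
support (base-2 logarithm keeps the divergence, hence the similarity, inside
[0, 1]).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .types import (
    Atlas,
    DegenerateDensityError,
    RegionalDensity,
    SimilarityNetwork,
    VoxelMap,
)

__all__ = [
    "smooth_map",
    "silverman_bandwidth",
    "estimate_density",
    "jsd",
    "jsds",
    "extract_region_values",
    "build_network",
    "build_networks",
    "discrete_frechet",
    "frechet_diagnostic",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))
DEFAULT_N_POINTS = 256  # 2^8 sample points for the regional PD


def smooth_map(vmap: VoxelMap, fwhm_mm: float) -> VoxelMap:
    """Smooth a map with a 3D Gaussian kernel of the given FWHM in mm.

    sigma per axis is fwhm / (2 sqrt(2 ln 2)) converted from mm to voxels.
    ``fwhm_mm = 0`` returns the map unchanged. Boundary handling is
    constant-zero padding, the common neuroimaging convention; total mass is
    conserved for interior signal.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be nonnegative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return VoxelMap(vmap.data.copy(), vmap.voxel_size, vmap.mask, vmap.affine)
    sigma_mm = fwhm_mm / _FWHM_TO_SIGMA
    sigma_vox = [sigma_mm / vs for vs in vmap.voxel_size]
    smoothed = ndimage.gaussian_filter(vmap.data, sigma=sigma_vox, mode="constant", cval=0.0)
    return VoxelMap(smoothed, vmap.voxel_size, vmap.mask, vmap.affine)


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a 1D Gaussian KDE.

    bw = sigma_hat * (3 n / 4)^(-1/5), with sigma_hat the sample standard
    deviation (ddof=1).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise DegenerateDensityError("need at least 2 values for a bandwidth")
    sd = float(np.std(values, ddof=1))
    if sd == 0:
        raise DegenerateDensityError("constant-valued input has no bandwidth")
    return sd * (3.0 * n / 4.0) ** (-0.2)


def _kde_on_grid(values: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    """Gaussian kernel sum of ``values`` evaluated at ``grid`` points."""
    z = (grid[:, None] - values[None, :]) / bw
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (values.size * bw * np.sqrt(2.0 * np.pi))
    return dens


def estimate_density(
    values: Sequence[float],
    n_points: int = DEFAULT_N_POINTS,
    grid: Optional[np.ndarray] = None,
) -> RegionalDensity:
    """Estimate the regional PD of a value vector by Gaussian KDE.

    The density is evaluated at ``n_points`` equally spaced grid points over
    [min - 3 bw, max + 3 bw] (Silverman bandwidth) and normalized so the
    masses sum to 1. An explicit ``grid`` overrides the automatic one, which
    is how two regions of a pair are put on a common support.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise DegenerateDensityError(
            f"need at least 2 voxel values, got {values.size}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    bw = silverman_bandwidth(values)  # raises on zero variance
    if grid is None:
        if n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {n_points}")
        grid = np.linspace(values.min() - 3.0 * bw, values.max() + 3.0 * bw, n_points)
    else:
        grid = np.asarray(grid, dtype=float)
    dens = _kde_on_grid(values, grid, bw)
    total = dens.sum()
    if total <= 0:
        raise DegenerateDensityError("density vanished on the requested grid")
    return RegionalDensity(grid=grid, mass=dens / total)


def _check_aligned(p: RegionalDensity, q: RegionalDensity) -> None:
    if p.grid.shape != q.grid.shape or not np.allclose(p.grid, q.grid):
        raise ValueError("densities are on different grids; re-evaluate on a shared grid")


def jsd(p: RegionalDensity, q: RegionalDensity) -> float:
    """Jensen-Shannon divergence (base-2 logarithm) between two aligned PDs.

    Zero-mass terms contribute exactly 0; the result lies in [0, 1].
    """
    _check_aligned(p, q)
    pm, qm = p.mass, q.mass
    m = 0.5 * (pm + qm)
    out = 0.0
    for dist in (pm, qm):
        pos = dist > 0
        out += 0.5 * float(np.sum(dist[pos] * np.log2(dist[pos] / m[pos])))
    # clip tiny negative round-off; true value is within [0, 1]
    return float(min(max(out, 0.0), 1.0))


def jsds(p: RegionalDensity, q: RegionalDensity) -> float:
    """Jensen-Shannon similarity 1 - JSD(P||Q): 1 iff identical, 0 if disjoint."""
    return 1.0 - jsd(p, q)


def extract_region_values(vmap: VoxelMap, atlas: Atlas) -> dict[int, np.ndarray]:
    """Voxel values of each atlas region (respecting the map mask)."""
    if vmap.shape != atlas.labels.shape:
        raise ValueError(
            f"map shape {vmap.shape} does not match atlas shape {atlas.labels.shape}"
        )
    out = {}
    for r in atlas.regions:
        sel = atlas.region_voxels(r.id, vmap.mask)
        out[r.id] = vmap.data[sel]
    return out


def _validate_regions(region_values: dict[int, np.ndarray]) -> None:
    bad = [
        rid
        for rid, vals in region_values.items()
        if vals.size < 2 or float(np.std(vals, ddof=1)) == 0.0
    ]
    if bad:
        raise DegenerateDensityError(
            f"regions with < 2 in-mask voxels or constant values: {sorted(bad)}"
        )


def build_network(
    vmap: VoxelMap,
    atlas: Atlas,
    fwhm_mm: float = 0.0,
    n_points: int = DEFAULT_N_POINTS,
) -> SimilarityNetwork:
    """Build one morphological similarity network from one map.

    Each region pair is scored on a shared grid of ``n_points`` equally
    spaced points spanning the union of the two regions' KDE supports, so the
    divergence sums are well defined.
    """
    if fwhm_mm:
        vmap = smooth_map(vmap, fwhm_mm)
    region_values = extract_region_values(vmap, atlas)
    _validate_regions(region_values)
    ids = atlas.region_ids
    vals = [region_values[rid] for rid in ids]
    bws = [silverman_bandwidth(v) for v in vals]
    lows = [v.min() - 3.0 * b for v, b in zip(vals, bws)]
    highs = [v.max() + 3.0 * b for v, b in zip(vals, bws)]
    r = len(ids)
    mat = np.eye(r)
    for i in range(r):
        for j in range(i + 1, r):
            grid = np.linspace(min(lows[i], lows[j]), max(highs[i], highs[j]), n_points)
            pi = estimate_density(vals[i], grid=grid)
            qj = estimate_density(vals[j], grid=grid)
            mat[i, j] = mat[j, i] = jsds(pi, qj)
    return SimilarityNetwork(matrix=mat, region_ids=ids)


def build_networks(
    maps: Sequence[VoxelMap],
    atlas: Atlas,
    fwhm_mm: float = 0.0,
    n_points: int = DEFAULT_N_POINTS,
) -> list[SimilarityNetwork]:
    """One similarity network per subject map."""
    return [build_network(m, atlas, fwhm_mm=fwhm_mm, n_points=n_points) for m in maps]


def discrete_frechet(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Discrete Frechet distance between two polygonal curves (points x dims).

    Dynamic program over the coupling lattice; O(len_a * len_b).
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    na, nb = d.shape
    ca = np.empty_like(d)
    ca[0, 0] = d[0, 0]
    for j in range(1, nb):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, na):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        row_prev = ca[i - 1]
        row = ca[i]
        for j in range(1, nb):
            row[j] = max(min(row_prev[j], row_prev[j - 1], row[j - 1]), d[i, j])
    return float(ca[-1, -1])


def frechet_diagnostic(
    values: Sequence[float], n_list: Sequence[int]
) -> list[float]:
    """Stability of the regional PD across sampling-point counts.

    For each adjacent pair in ``n_list`` (ascending powers of two), the
    discrete Frechet distance between the two density curves (grid, mass)
    estimated from the same values. Distances shrinking along the list
    indicate the density estimate has stabilized.
    """
    n_list = [int(n) for n in n_list]
    if len(n_list) < 2:
        raise ValueError("need at least two sampling-point counts")
    if any(b <= a for a, b in zip(n_list, n_list[1:])):
        raise ValueError("n_list must be strictly ascending")
    if any(n < 2 or (n & (n - 1)) != 0 for n in n_list):
        raise ValueError("n_list entries must be powers of two >= 2")
    curves = []
    for n in n_list:
        dens = estimate_density(values, n_points=n)
        curves.append(np.column_stack([dens.grid, dens.mass]))
    return [
        discrete_frechet(curves[k], curves[k + 1]) for k in range(len(curves) - 1)
    ]
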