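"""Synthetic fixtures with known ground truth for the whole pipeline.

Every generator is a pure function of its parameters and a mandatory seed:
identical calls return bit-identical data. The generators emulate the study
designs the downstream statistics expect -- a mirrored-hemisphere toy atlas,
per-subject morphometric maps whose homotopic regions share their value
distribution to a controllable degree, balanced multi-session panels with a
target intraclass correlation, MZ/DZ twin panels under an ACE variance
decomposition, and two-group cohorts with a planted connected-component
effect -- using Gaussian noise throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .reliability import SessionPanel, TwinPanel
from .types import Atlas, Region, VoxelMap

__all__ = [
    "GeneratorConfig",
    "make_toy_atlas",
    "simulate_subject_maps",
    "simulate_sessions",
    "simulate_twins",
    "simulate_groups",
]


@dataclass
class GeneratorConfig:
    """Bundle of generator parameters for pipeline runs."""

    seed: int
    n_pairs: int = 21
    n_midline: int = 6
    block_voxels: int = 512
    n_subjects: int = 10
    homotopic_coupling: float = 0.8
    target_icc: float = 0.8
    a2: float = 0.5
    c2: float = 0.2
    e2: float = 0.3
    delta: float = 1.5
    planted_edges: list[tuple[int, int]] = field(default_factory=list)
    noise_sd: float = 1.0


def make_toy_atlas(
    n_pairs: int = 21, n_midline: int = 6, block_voxels: int = 512
) -> Atlas:
    """Toy atlas of mirrored cuboid blocks plus midline blocks.

    Defaults yield 48 regions (21 left/right homotopic pairs = 42
    lateralized regions, plus 6 midline regions), mirroring the structure of
    the 48-region white-matter atlas. Left and right partner blocks are
    mirror images along the x axis, so their voxel counts are exactly equal.
    """
    if n_pairs < 1:
        raise ValueError("need at least one homotopic pair")
    if n_midline < 0:
        raise ValueError("n_midline must be nonnegative")
    if block_voxels < 8:
        raise ValueError(f"block_voxels must be >= 8, got {block_voxels}")
    side = int(np.ceil(block_voxels ** (1.0 / 3.0)))
    ny = int(np.ceil(np.sqrt(max(n_pairs, n_midline))))
    nz = int(np.ceil(max(n_pairs, n_midline) / ny))
    labels = np.zeros((3 * side, ny * side, nz * side), dtype=np.int32)
    regions: list[Region] = []
    for p in range(n_pairs):
        yi, zi = p % ny, p // ny
        ys = slice(yi * side, (yi + 1) * side)
        zs = slice(zi * side, (zi + 1) * side)
        left_id, right_id = 2 * p + 1, 2 * p + 2
        labels[0:side, ys, zs] = left_id
        labels[2 * side : 3 * side, ys, zs] = right_id
        regions.append(Region(left_id, f"pair{p + 1}_L", "L", right_id))
        regions.append(Region(right_id, f"pair{p + 1}_R", "R", left_id))
    for m in range(n_midline):
        yi, zi = m % ny, m // ny
        mid_id = 2 * n_pairs + m + 1
        labels[side : 2 * side, yi * side : (yi + 1) * side, zi * side : (zi + 1) * side] = mid_id
        regions.append(Region(mid_id, f"mid{m + 1}", "M", None))
    return Atlas(labels=labels, regions=regions, voxel_size=(1.0, 1.0, 1.0))


def simulate_subject_maps(
    atlas: Atlas,
    n_subjects: int,
    homotopic_coupling: float = 0.8,
    seed: Optional[int] = None,
    mean_spread: float = 2.0,
    subject_sd: float = 0.3,
    noise_sd: float = 1.0,
) -> list[VoxelMap]:
    """Per-subject voxel maps with controllable homotopic similarity.

    Voxel values in region r of subject s are N(mu_{r,s}, sigma_{r,s}).
    Region base means are spread over [-mean_spread, mean_spread] so that
    unrelated regions carry distinct distributions; homotopic partners blend
    their parameters with weight ``homotopic_coupling`` (1 = identical
    distributions up to sampling noise, 0 = fully independent).
    """
    if not 0 <= homotopic_coupling <= 1:
        raise ValueError("homotopic_coupling must lie in [0, 1]")
    if seed is None:
        raise ValueError("seed is mandatory for generators")
    rng = np.random.default_rng(seed)
    ids = atlas.region_ids
    r = len(ids)
    id_to_idx = {rid: k for k, rid in enumerate(ids)}
    base_mu = rng.uniform(-mean_spread, mean_spread, size=r)
    base_sigma = noise_sd * np.exp(0.2 * rng.standard_normal(r))
    c = homotopic_coupling
    maps = []
    for _ in range(n_subjects):
        mu = base_mu + subject_sd * rng.standard_normal(r)
        sigma = base_sigma * np.exp(0.1 * rng.standard_normal(r))
        for left_id, right_id in atlas.homotopic_pairs():
            li, ri = id_to_idx[left_id], id_to_idx[right_id]
            mu[ri] = c * mu[li] + (1 - c) * mu[ri]
            sigma[ri] = c * sigma[li] + (1 - c) * sigma[ri]
        data = np.zeros(atlas.labels.shape)
        for k, rid in enumerate(ids):
            sel = atlas.labels == rid
            data[sel] = mu[k] + sigma[k] * rng.standard_normal(int(sel.sum()))
        maps.append(VoxelMap(data, atlas.voxel_size))
    return maps


def simulate_sessions(
    n_subjects: int,
    k_sessions: int,
    target_icc: float,
    n_edges: int = 1,
    seed: Optional[int] = None,
) -> SessionPanel:
    """Balanced session panel whose population ICC equals ``target_icc``.

    value = sqrt(ICC) * subject effect + sqrt(1 - ICC) * session noise, both
    standard normal, so the between/(between+within) variance ratio is the
    target. ``target_icc = 1`` (zero session noise) is rejected.
    """
    if not 0 <= target_icc < 1:
        raise ValueError("target_icc must lie in [0, 1)")
    if seed is None:
        raise ValueError("seed is mandatory for generators")
    rng = np.random.default_rng(seed)
    subj = rng.standard_normal((n_subjects, 1, n_edges))
    noise = rng.standard_normal((n_subjects, k_sessions, n_edges))
    values = np.sqrt(target_icc) * subj + np.sqrt(1 - target_icc) * noise
    return SessionPanel(values=values)


def simulate_twins(
    n_mz: int,
    n_dz: int,
    a2: float,
    c2: float,
    e2: float,
    n_edges: int = 1,
    seed: Optional[int] = None,
) -> TwinPanel:
    """Twin panel under an ACE decomposition with unit total variance.

    Member value = sqrt(a2) G + sqrt(c2) C + sqrt(e2) E with the additive
    genetic factor G fully shared within MZ pairs and correlated 1/2 within
    DZ pairs, the common environment C shared within every pair, and the
    unique environment E independent. Population intrapair correlations are
    r_MZ = a2 + c2 and r_DZ = a2/2 + c2.
    """
    if min(a2, c2, e2) < 0 or abs(a2 + c2 + e2 - 1.0) > 1e-9:
        raise ValueError("a2, c2, e2 must be nonnegative and sum to 1")
    if seed is None:
        raise ValueError("seed is mandatory for generators")
    rng = np.random.default_rng(seed)
    n = n_mz + n_dz
    g1 = rng.standard_normal((n, n_edges))
    g_extra = rng.standard_normal((n, n_edges))
    cshare = rng.standard_normal((n, n_edges))
    e_m1 = rng.standard_normal((n, n_edges))
    e_m2 = rng.standard_normal((n, n_edges))
    is_mz = np.zeros(n, dtype=bool)
    is_mz[:n_mz] = True
    g2 = np.where(is_mz[:, None], g1, 0.5 * g1 + np.sqrt(0.75) * g_extra)
    m1 = np.sqrt(a2) * g1 + np.sqrt(c2) * cshare + np.sqrt(e2) * e_m1
    m2 = np.sqrt(a2) * g2 + np.sqrt(c2) * cshare + np.sqrt(e2) * e_m2
    values = np.stack([m1, m2], axis=1)
    zyg = np.where(is_mz, "MZ", "DZ")
    return TwinPanel(values=values, zygosity=zyg)


def simulate_groups(
    n_per_group: int,
    n_regions: int,
    planted_edges: Sequence[tuple[int, int]],
    delta: float,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-group edge panel with a planted connected-component effect.

    All R(R-1)/2 edges are standard normal; the planted edges are shifted by
    ``delta`` (in within-group SD units) in the second group. The planted
    edge set must form a single connected component (a detectable
    network-based-statistic cluster) or be empty for null panels.

    Returns (edges: 2n x E array in upper-triangle order, labels: 2n array
    of 0/1 group codes).
    """
    if seed is None:
        raise ValueError("seed is mandatory for generators")
    planted = [tuple(sorted(e)) for e in planted_edges]
    if delta != 0 and not planted:
        raise ValueError("a nonzero delta needs a nonempty planted edge set")
    if planted:
        g = nx.Graph(planted)
        if g.number_of_nodes() and nx.number_connected_components(g) != 1:
            raise ValueError("planted edges must form one connected component")
        if any(i < 0 or j >= n_regions or i == j for i, j in planted):
            raise ValueError("planted edges out of range")
    iu, ju = np.triu_indices(n_regions, k=1)
    edge_index = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))}
    planted_idx = [edge_index[e] for e in planted]
    rng = np.random.default_rng(seed)
    n_edges = iu.size
    data = rng.standard_normal((2 * n_per_group, n_edges))
    labels = np.repeat([0, 1], n_per_group)
    data[np.ix_(labels == 1, planted_idx)] += delta
    return data, labels
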