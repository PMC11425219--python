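"""Core containers shared across the package.

Everything here is a thin, validated wrapper around numpy arrays: a voxelwise
morphometric map, a labelled atlas with a region table, a discretized regional
probability distribution, and the region-by-region similarity network those
produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VoxelMap",
    "Region",
    "Atlas",
    "RegionalDensity",
    "SimilarityNetwork",
    "BinaryNetwork",
    "upper_triangle",
    "edge_index_pairs",
    "vector_to_matrix",
]


class DegenerateDensityError(ValueError):
    """Raised when a region's values cannot support a density estimate."""


@dataclass
class VoxelMap:
    """A 3D scalar field of one morphometric index (volume or deformation).

    Parameters
    ----------
    data : (X, Y, Z) float array
    voxel_size : length-3 sequence, mm per axis
    mask : optional boolean array of the same shape; voxels outside the mask
        are ignored during regional extraction.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: Optional[np.ndarray] = None
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"VoxelMap expects a 3D array, got {self.data.ndim} axes "
                f"(shape {self.data.shape}); axis {self.data.ndim - 1} is extra"
                if self.data.ndim > 3
                else f"VoxelMap expects a 3D array, got shape {self.data.shape}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be 3 positive lengths in mm")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data shape")
            if not np.all(np.isfinite(self.data[self.mask])):
                raise ValueError("non-finite values inside mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class Region:
    id: int
    name: str
    hemisphere: str  # 'L', 'R' or 'M'
    partner_id: Optional[int] = None


@dataclass
class Atlas:
    """Labelled 3D volume plus its region lookup table.

    ``labels`` uses 0 for background; every nonzero label must appear in the
    region table. Homotopic partnership (left/right mirror regions) is stored
    symmetrically; midline ('M') regions carry no partner.
    """

    labels: np.ndarray
    regions: Sequence[Region]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D integer volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        self.regions = list(self.regions)
        table = {r.id: r for r in self.regions}
        if len(table) != len(self.regions):
            raise ValueError("duplicate region IDs in table")
        present = set(np.unique(self.labels)) - {0}
        missing = sorted(present - set(table))
        if missing:
            raise ValueError(f"labels absent from region table: {missing}")
        for r in self.regions:
            if r.hemisphere not in ("L", "R", "M"):
                raise ValueError(f"region {r.id}: hemisphere must be L/R/M")
            if r.hemisphere == "M" and r.partner_id is not None:
                raise ValueError(f"midline region {r.id} must have no partner")
            if r.partner_id is not None:
                partner = table.get(r.partner_id)
                if partner is None or partner.partner_id != r.id:
                    raise ValueError(
                        f"homotopic partnership of region {r.id} is not symmetric"
                    )

    @property
    def region_ids(self) -> list[int]:
        return [r.id for r in self.regions]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def region_voxels(self, region_id: int, mask: Optional[np.ndarray] = None) -> np.ndarray:
        sel = self.labels == region_id
        if mask is not None:
            sel &= mask
        return sel

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """Unique (left_id, right_id) homotopic pairs."""
        out = []
        for r in self.regions:
            if r.hemisphere == "L" and r.partner_id is not None:
                out.append((r.id, r.partner_id))
        return out

    def centroids(self) -> np.ndarray:
        """Region centroids in mm (voxel index * voxel size), ordered as regions."""
        vs = np.asarray(self.voxel_size)
        cents = np.empty((self.n_regions, 3))
        for k, r in enumerate(self.regions):
            idx = np.argwhere(self.labels == r.id)
            if idx.size == 0:
                raise ValueError(f"region {r.id} has no voxels")
            cents[k] = idx.mean(axis=0) * vs
        return cents


@dataclass
class RegionalDensity:
    """A discretized probability distribution over ``grid``.

    Masses are nonnegative and sum to 1 within 1e-12; the grid is strictly
    ascending. This is the PD that enters the Jensen-Shannon similarity.
    """

    grid: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.mass.shape:
            raise ValueError("grid and mass must be 1D and equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        if np.any(self.mass < -1e-15):
            raise ValueError("mass must be nonnegative")
        if abs(float(self.mass.sum()) - 1.0) > 1e-12:
            raise ValueError("mass must sum to 1 within 1e-12")

    @property
    def n_points(self) -> int:
        return self.grid.size


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a square matrix, row-major order."""
    matrix = np.asarray(matrix)
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def edge_index_pairs(n: int) -> list[tuple[int, int]]:
    """(i, j) index pairs in the strict-upper-triangle row-major order."""
    iu, ju = np.triu_indices(n, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def vector_to_matrix(vec: np.ndarray, n: int, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`upper_triangle` for symmetric matrices."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != n * (n - 1) // 2:
        raise ValueError("edge vector length does not match n")
    out = np.full((n, n), diagonal, dtype=float)
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


@dataclass
class SimilarityNetwork:
    """Symmetric R x R matrix of JSDs values in [0, 1] with unit diagonal."""

    matrix: np.ndarray
    region_ids: Sequence[int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.region_ids = list(self.region_ids)
        r = len(self.region_ids)
        if self.matrix.shape != (r, r):
            raise ValueError("matrix shape must match number of regions")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        off = upper_triangle(self.matrix)
        if off.size and (off.min() < -1e-10 or off.max() > 1 + 1e-10):
            raise ValueError("off-diagonal similarities must lie in [0, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_edges(self) -> int:
        r = self.n_regions
        return r * (r - 1) // 2

    def edges(self) -> np.ndarray:
        return upper_triangle(self.matrix)


@dataclass
class BinaryNetwork:
    """Binarized network at a given sparsity; symmetric, hollow, connected."""

    adjacency: np.ndarray
    sparsity: float
    region_ids: Sequence[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = a.astype(np.int8)
        if not self.region_ids:
            self.region_ids = list(range(1, a.shape[0] + 1))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)
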