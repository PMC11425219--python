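"""File formats: NIfTI volumes, TSV region tables, matrices and edge panels.

Matrices are written with region-ID headers (never positional-only); edge
vectors use the strict upper-triangle row-major order with an explicit
(region_i, region_j) index header.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .types import Atlas, Region, SimilarityNetwork, VoxelMap, edge_index_pairs

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_region_table",
    "write_region_table",
    "read_atlas",
    "write_atlas",
    "write_network_tsv",
    "read_network_tsv",
    "write_edge_list",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_edge_panel",
    "read_edge_panel",
    "file_checksum",
]

PathLike = Union[str, Path]


def read_nifti(path: PathLike, voxel_size: Optional[Sequence[float]] = None) -> VoxelMap:
    """Load a 3D NIfTI-1 volume as a VoxelMap (voxel size from the header)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        extra = data.ndim - 1
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim}D; axis {extra} is extra"
        )
    vs = tuple(float(z) for z in img.header.get_zooms()[:3]) if voxel_size is None else tuple(voxel_size)
    return VoxelMap(data=np.asarray(data, dtype=float), voxel_size=vs, affine=img.affine)


def write_nifti(vmap: VoxelMap, path: PathLike) -> Path:
    """Write a VoxelMap as NIfTI-1; the affine encodes the voxel size."""
    affine = vmap.affine
    if affine is None:
        affine = np.diag(list(vmap.voxel_size) + [1.0])
    img = nib.Nifti1Image(vmap.data.astype(np.float64), affine)
    img.header.set_zooms(vmap.voxel_size)
    path = Path(path)
    nib.save(img, str(path))
    return path


def write_region_table(regions: Sequence[Region], path: PathLike) -> Path:
    df = pd.DataFrame(
        {
            "id": [r.id for r in regions],
            "name": [r.name for r in regions],
            "hemisphere": [r.hemisphere for r in regions],
            "partner_id": [r.partner_id if r.partner_id is not None else "" for r in regions],
        }
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_region_table(path: PathLike) -> list[Region]:
    df = pd.read_csv(path, sep="\t", dtype={"partner_id": "string"})
    regions = []
    for row in df.itertuples(index=False):
        partner = row.partner_id
        partner_id = None if pd.isna(partner) or str(partner).strip() == "" else int(float(partner))
        regions.append(Region(int(row.id), str(row.name), str(row.hemisphere), partner_id))
    return regions


def read_atlas(labels_path: PathLike, table_path: PathLike) -> Atlas:
    """Load atlas labels (NIfTI) and its region table (TSV)."""
    img = nib.load(str(labels_path))
    labels = np.asanyarray(img.dataobj)
    if labels.ndim != 3:
        raise ValueError(f"{labels_path}: atlas labels must be 3D, got {labels.ndim}D")
    labels = np.rint(labels).astype(np.int32)
    regions = read_region_table(table_path)
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Atlas(labels=labels, regions=regions, voxel_size=vs, affine=img.affine)


def write_atlas(atlas: Atlas, labels_path: PathLike, table_path: PathLike) -> None:
    affine = atlas.affine
    if affine is None:
        affine = np.diag(list(atlas.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int32), affine), str(labels_path))
    write_region_table(atlas.regions, table_path)


def write_matrix_tsv(matrix: np.ndarray, region_ids: Sequence[int], path: PathLike) -> Path:
    df = pd.DataFrame(np.asarray(matrix), index=list(region_ids), columns=list(region_ids))
    path = Path(path)
    df.to_csv(path, sep="\t", index_label="region")
    return path


def read_matrix_tsv(path: PathLike) -> tuple[np.ndarray, list[int]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [int(c) for c in df.columns]
    return df.to_numpy(dtype=float), ids


def write_network_tsv(net: SimilarityNetwork, path: PathLike) -> Path:
    return write_matrix_tsv(net.matrix, net.region_ids, path)


def read_network_tsv(path: PathLike) -> SimilarityNetwork:
    matrix, ids = read_matrix_tsv(path)
    return SimilarityNetwork(matrix=matrix, region_ids=ids)


def write_edge_list(net: SimilarityNetwork, path: PathLike) -> Path:
    ids = list(net.region_ids)
    pairs = edge_index_pairs(net.n_regions)
    df = pd.DataFrame(
        {
            "region_i": [ids[i] for i, _ in pairs],
            "region_j": [ids[j] for _, j in pairs],
            "jsds": net.edges(),
        }
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_edge_panel(
    edges: np.ndarray, region_ids: Sequence[int], path: PathLike
) -> Path:
    """Subjects x edges TSV with an (i, j) edge-index header."""
    ids = list(region_ids)
    pairs = edge_index_pairs(len(ids))
    cols = [f"{ids[i]}-{ids[j]}" for i, j in pairs]
    df = pd.DataFrame(np.asarray(edges), columns=cols)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_edge_panel(path: PathLike) -> tuple[np.ndarray, list[tuple[int, int]]]:
    df = pd.read_csv(path, sep="\t")
    pairs = [tuple(int(v) for v in c.split("-")) for c in df.columns]
    return df.to_numpy(dtype=float), pairs


def file_checksum(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: PathLike) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
    return path


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
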