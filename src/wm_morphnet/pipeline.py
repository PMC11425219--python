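"""End-to-end pipeline: build networks, characterize topology, write a manifest.

A run is fully described by a :class:`RunConfig`; deterministic stages are
bit-reproducible across runs and stochastic stages are bit-reproducible for
a fixed seed. Every output file is listed in the manifest with a checksum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as wio
from .network import build_networks
from .synthetic import GeneratorConfig, make_toy_atlas, simulate_subject_maps
from .topology import DEFAULT_SPARSITY_GRID, topology_report
from .types import Atlas, SimilarityNetwork, VoxelMap

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("wm_morphnet")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    map_paths: Sequence[Path] = field(default_factory=list)
    atlas_labels: Optional[Path] = None
    atlas_table: Optional[Path] = None
    index: str = "volume"  # morphological index tag: volume or deformation
    fwhm_mm: float = 8.0
    n_points: int = 256
    sparsities: Sequence[float] = DEFAULT_SPARSITY_GRID
    n_perm: int = 0
    n_null: int = 100
    seed: Optional[int] = None
    simulate: Optional[GeneratorConfig] = None

    def validate(self) -> None:
        if self.index not in ("volume", "deformation"):
            raise ValueError("index must be 'volume' or 'deformation'")
        if any(not (0 < s <= 1) for s in self.sparsities):
            raise ValueError("sparsity grid must lie within (0, 1]")
        if (self.n_perm > 0 or self.n_null > 0) and self.seed is None:
            raise ValueError("a seed is required when permutations are requested")
        if self.simulate is None and (
            not self.map_paths or self.atlas_labels is None or self.atlas_table is None
        ):
            raise ValueError("provide map and atlas paths, or a simulation config")


def _load_inputs(config: RunConfig) -> tuple[list[VoxelMap], Atlas]:
    if config.simulate is not None:
        sim = config.simulate
        atlas = make_toy_atlas(sim.n_pairs, sim.n_midline, sim.block_voxels)
        maps = simulate_subject_maps(
            atlas,
            sim.n_subjects,
            homotopic_coupling=sim.homotopic_coupling,
            seed=sim.seed,
            noise_sd=sim.noise_sd,
        )
        return maps, atlas
    atlas = wio.read_atlas(config.atlas_labels, config.atlas_table)
    maps = [wio.read_nifti(p) for p in config.map_paths]
    for k, m in enumerate(maps):
        if m.shape != atlas.labels.shape:
            raise ValueError(
                f"stage build: map {config.map_paths[k]} shape {m.shape} "
                f"does not match atlas {atlas.labels.shape}"
            )
    return maps, atlas


def run_pipeline(config: RunConfig) -> Path:
    """Execute build -> topology and write all artifacts plus a manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs: list[Path] = []
    try:
        logger.info("stage build: loading inputs")
        try:
            maps, atlas = _load_inputs(config)
        except Exception as exc:
            raise RuntimeError(f"stage build failed: {exc}") from exc
        logger.info("stage build: constructing %d networks", len(maps))
        try:
            nets = build_networks(maps, atlas, fwhm_mm=config.fwhm_mm, n_points=config.n_points)
        except Exception as exc:
            raise RuntimeError(f"stage build failed: {exc}") from exc
        for k, net in enumerate(nets):
            outputs.append(wio.write_network_tsv(net, out / f"network_sub{k:03d}.tsv"))
            outputs.append(wio.write_edge_list(net, out / f"edges_sub{k:03d}.tsv"))
        mean_matrix = np.mean([n.matrix for n in nets], axis=0)
        mean_net = SimilarityNetwork(matrix=mean_matrix, region_ids=atlas.region_ids)
        outputs.append(wio.write_network_tsv(mean_net, out / "network_mean.tsv"))
        logger.info("stage topology: %d sparsity levels", len(config.sparsities))
        try:
            report = topology_report(
                mean_net,
                sparsities=config.sparsities,
                n_null=config.n_null,
                seed=config.seed,
            )
        except Exception as exc:
            raise RuntimeError(f"stage topology failed: {exc}") from exc
        outputs.append(wio.write_json(report, out / "topology.json"))
        manifest = {
            "config": {
                "index": config.index,
                "fwhm_mm": config.fwhm_mm,
                "n_points": config.n_points,
                "sparsities": [float(s) for s in config.sparsities],
                "n_perm": config.n_perm,
                "n_null": config.n_null,
                "seed": config.seed,
                "simulated": config.simulate is not None,
                "inputs": [str(p) for p in config.map_paths],
            },
            "versions": _versions(),
            "outputs": {
                str(p.relative_to(out)): wio.file_checksum(p) for p in outputs
            },
        }
        wio.write_json(manifest, out / "manifest.json")
        logger.info("pipeline complete: %d output files", len(outputs))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _versions() -> dict[str, str]:
    import networkx
    import nibabel
    import scipy
    import sklearn

    from . import __version__

    return {
        "wm_morphnet": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "networkx": networkx.__version__,
        "nibabel": nibabel.__version__,
        "sklearn": sklearn.__version__,
    }
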