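"""Sphere ROIs at named world coordinates and per-subject volume extraction.

Seed-based structural covariance analysis measures, for every subject, the
gray-matter volume inside a small sphere placed at a fixed stereotaxic
coordinate; that scalar then serves as the covariate of interest in
voxel-wise regressions.  The built-in catalog ships the four canonical
network anchors: right entorhinal cortex (medial-temporal default mode
subsystem), left posterior cingulate (midline default mode core), right
frontoinsular cortex (salience network) and right dorsolateral prefrontal
cortex (executive control network), each with a 4-mm radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .image_model import VolumeImage, world_to_voxel

__all__ = [
    "SeedSpec",
    "SphereMask",
    "DEFAULT_SEEDS",
    "sphere_mask",
    "extract_seed_volume",
    "extract_seed_volumes",
    "load_seed_catalog",
    "save_seed_catalog",
]


@dataclass(frozen=True)
class SeedSpec:
    """A named seed: world-space centre (mm), sphere radius and network."""

    name: str
    center: tuple[float, float, float]
    radius_mm: float = 4.0
    network_label: str = ""

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("seed radius must be positive")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


#: The four canonical seeds (MNI mm), one per large-scale network.
DEFAULT_SEEDS: tuple[SeedSpec, ...] = (
    SeedSpec("R_entorhinal", (25.0, -9.0, -28.0), 4.0, "DMN-medial-temporal"),
    SeedSpec("L_posterior_cingulate", (-2.0, -36.0, 35.0), 4.0, "DMN-midline-core"),
    SeedSpec("R_frontoinsular", (38.0, 26.0, -10.0), 4.0, "salience"),
    SeedSpec("R_dlpfc", (44.0, 36.0, 20.0), 4.0, "executive-control"),
)


@dataclass
class SphereMask:
    """Realised voxel set of a :class:`SeedSpec` on a particular grid."""

    mask: np.ndarray
    seed: SeedSpec

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def sphere_mask(image: VolumeImage, seed: SeedSpec) -> SphereMask:
    """Closed-ball sphere mask: voxel centres within ``radius_mm`` of the seed.

    A voxel is included iff the Euclidean distance from its centre (in
    world space) to the seed centre is <= the radius.  The voxel nearest
    the centre is always included, so the mask is never empty.  Raises if
    the centre maps outside the grid.
    """
    ci, cj, ck = world_to_voxel(image, seed.center)  # validates in-grid
    dims = image.voxel_dims_mm
    # bounding box in voxel units, generous by one voxel
    half = np.ceil(seed.radius_mm / dims).astype(int) + 1
    lo = np.maximum([ci, cj, ck] - half, 0)
    hi = np.minimum(np.asarray([ci, cj, ck]) + half + 1, image.shape)
    ii, jj, kk = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    world = idx @ image.affine[:3, :3].T + image.affine[:3, 3]
    dist = np.linalg.norm(world - np.asarray(seed.center), axis=1)
    inside = dist <= seed.radius_mm + 1e-9
    mask = np.zeros(image.shape, dtype=bool)
    sel = idx[inside].astype(int)
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    mask[ci, cj, ck] = True
    return SphereMask(mask=mask, seed=seed)


def extract_seed_volume(
    image: VolumeImage, mask: SphereMask | np.ndarray, aggregate: str = "sum"
) -> float:
    """Gray-matter volume within a sphere for one subject.

    With ``aggregate="sum"`` (default) returns the integral of the
    modulated image over the mask, i.e. sum of voxel values times voxel
    volume in mm^3 — the natural "GM volume" reading of a modulated map.
    ``aggregate="mean"`` returns the mean voxel value (dimensionless GM
    density), useful when a quantity in per-voxel units is required.
    """
    arr = mask.mask if isinstance(mask, SphereMask) else np.asarray(mask, dtype=bool)
    if arr.shape != image.shape:
        raise ValueError(
            f"mask shape {arr.shape} does not match image shape {image.shape}"
        )
    values = image.data[arr]
    if aggregate == "sum":
        return float(values.sum()) * image.voxel_volume_mm3
    if aggregate == "mean":
        return float(values.mean())
    raise ValueError(f"unknown aggregate {aggregate!r}; use 'sum' or 'mean'")


def extract_seed_volumes(
    images: Sequence[VolumeImage],
    mask: SphereMask | np.ndarray,
    aggregate: str = "sum",
) -> np.ndarray:
    """Vector of per-subject seed volumes (one entry per image)."""
    return np.array([extract_seed_volume(img, mask, aggregate) for img in images])


def save_seed_catalog(seeds: Iterable[SeedSpec], path: str | Path) -> None:
    """Write a seed catalog as TSV (name, x, y, z, radius_mm, network)."""
    rows = [
        {
            "name": s.name,
            "x": s.center[0],
            "y": s.center[1],
            "z": s.center[2],
            "radius_mm": s.radius_mm,
            "network": s.network_label,
        }
        for s in seeds
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_seed_catalog(path: str | Path) -> list[SeedSpec]:
    """Read a seed catalog from TSV or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path, sep="\t").to_dict("records")
    return [
        SeedSpec(
            name=str(r["name"]),
            center=(float(r["x"]), float(r["y"]), float(r["z"])),
            radius_mm=float(r.get("radius_mm", 4.0)),
            network_label=str(r.get("network", "") or ""),
        )
        for r in records
    ]
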