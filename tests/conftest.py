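"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from scnmap import SimConfig, VolumeImage


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240117)


@pytest.fixture
def small_image(rng) -> VolumeImage:
    """An 8x8x8 random volume with 2 mm isotropic voxels, origin centered."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -7.0
    return VolumeImage(rng.random((8, 8, 8)), affine)


def tiny_sim(**overrides) -> SimConfig:
    """A fast simulation config on a small grid (used by several modules)."""
    defaults = dict(
        n_per_group={"G": 20, "AA": 12},
        grid_shape=(14, 14, 14),
        seed_center=(0.0, 0.0, 0.0),
        planted_clusters=(
            __import__("scnmap").PlantedCluster(
                center=(9.0, 9.0, 9.0),
                radius_mm=6.0,
                baseline_b0=0.4,
                slope_by_stratum={"G": 0.5, "AA": 1.5},
            ),
        ),
        rng_seed=7,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def flood_fill_components(arr: np.ndarray, connectivity: int) -> set[frozenset]:
    """Independent connected-components oracle: breadth-first flood fill.

    Returns the partition of true voxels as a set of frozensets of index
    tuples; implemented with explicit neighbour enumeration, no labeling
    library.
    """
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    arr = np.asarray(arr, dtype=bool)
    remaining = {tuple(v) for v in np.argwhere(arr)}
    components: set[frozenset] = set()
    while remaining:
        start = remaining.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            i, j, k = frontier.pop()
            for di, dj, dk in offsets:
                nb = (i + di, j + dj, k + dk)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        components.add(frozenset(comp))
    return components


def clusters_as_partition(table) -> set[frozenset]:
    """Convert a ClusterTable to the same partition representation."""
    return {
        frozenset(tuple(v) for v in cl.voxels) for cl in table.clusters
    }
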