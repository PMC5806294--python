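"""Map-level inference: FDR thresholding, clustering, peaks, cluster tables.

Voxel-wise p maps are thresholded with the Benjamini-Hochberg step-up
procedure over the in-mask voxels of each contrast map independently (no
pooling across maps), suprathreshold voxels are partitioned into connected
components (default 18-connectivity, the cluster-forming convention of
standard VBM tooling), components at or below the extent threshold are
dropped (strictly greater-than, i.e. ">100 voxels" keeps 101), and each
survivor is summarized by its peak voxel, world coordinates, extent in
voxels and mm^3, and maximal t — the columns of a conventional cluster
table.  Sub-peaks at least 8 mm apart are reported as same-cluster rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from statsmodels.stats.multitest import multipletests

from .image_model import VolumeImage, voxel_to_world
from .scn_regression import GLMMaps
from .seed_roi import SeedSpec, extract_seed_volume, sphere_mask

__all__ = [
    "ThresholdedMap",
    "Cluster",
    "ClusterTable",
    "bh_fdr",
    "label_clusters",
    "extent_filter",
    "find_peaks",
    "peak_cluster_volumes",
]

_STRUCTURES = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


@dataclass
class ThresholdedMap:
    """Boolean suprathreshold field from FDR thresholding of a p map."""

    supra: np.ndarray
    q: float
    n_rejected: int
    rule: str = "benjamini-hochberg"
    source: GLMMaps | None = None


def bh_fdr(
    maps: GLMMaps | np.ndarray,
    q: float = 0.05,
    mask: np.ndarray | None = None,
) -> ThresholdedMap:
    """Benjamini-Hochberg step-up at level *q* over in-mask p-values.

    Accepts either a :class:`GLMMaps` (its own mask is used) or a raw p
    array with an explicit mask.  NaN p-values inside the mask are an
    error; the offending voxel indices are listed.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if isinstance(maps, GLMMaps):
        p_arr, use_mask, source = maps.p, maps.mask, maps
    else:
        p_arr = np.asarray(maps, dtype=float)
        use_mask = (
            np.asarray(mask, dtype=bool) if mask is not None
            else np.ones(p_arr.shape, dtype=bool)
        )
        source = None
    p_in = p_arr[use_mask]
    if p_in.size == 0:
        raise ValueError("no in-mask p-values")
    if np.any(np.isnan(p_in)):
        bad = np.argwhere(use_mask)[np.isnan(p_in)]
        raise ValueError(f"NaN p-values at voxels {bad[:10].tolist()}")
    reject, *_ = multipletests(p_in, alpha=q, method="fdr_bh")
    supra = np.zeros(use_mask.shape, dtype=bool)
    supra[use_mask] = reject
    return ThresholdedMap(supra=supra, q=q, n_rejected=int(reject.sum()), source=source)


@dataclass
class Cluster:
    """One connected suprathreshold component.

    ``voxels`` are 0-based indices sorted lexicographically; the peak is
    the maximal-t voxel (lexicographically first on ties).  ``subpeaks``
    holds additional local reporting points >= the minimum separation from
    every previously accepted peak, in descending t order.
    """

    label: int
    voxels: np.ndarray
    extent: int
    extent_mm3: float | None = None
    peak_index: tuple[int, int, int] | None = None
    peak_world: tuple[float, float, float] | None = None
    max_t: float | None = None
    subpeaks: list[dict] = field(default_factory=list)
    region_label: str | None = None


@dataclass
class ClusterTable:
    """Ordered clusters for one seed/contrast, sorted by max t descending
    once peaks are computed (label order before that)."""

    clusters: list[Cluster]
    seed_name: str = ""
    contrast_name: str = ""
    connectivity: int = 18

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cl in self.clusters:
            primary = {
                "cluster": cl.label,
                "region": cl.region_label or "",
                "x": cl.peak_world[0] if cl.peak_world else np.nan,
                "y": cl.peak_world[1] if cl.peak_world else np.nan,
                "z": cl.peak_world[2] if cl.peak_world else np.nan,
                "extent_voxels": cl.extent,
                "extent_mm3": cl.extent_mm3,
                "max_t": cl.max_t,
                "subpeak": "",
            }
            rows.append(primary)
            for sp in cl.subpeaks:
                rows.append(
                    {
                        "cluster": cl.label,
                        "region": cl.region_label or "",
                        "x": sp["world"][0],
                        "y": sp["world"][1],
                        "z": sp["world"][2],
                        "extent_voxels": cl.extent,
                        "extent_mm3": cl.extent_mm3,
                        "max_t": sp["t"],
                        "subpeak": "s.c.",
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "cluster", "region", "x", "y", "z",
                "extent_voxels", "extent_mm3", "max_t", "subpeak",
            ],
        )


def label_clusters(
    supra: ThresholdedMap | np.ndarray,
    connectivity: int = 18,
    voxel_volume_mm3: float | None = None,
    seed_name: str = "",
    contrast_name: str = "",
) -> ClusterTable:
    """Connected components of the suprathreshold field.

    Components are numbered 1..n in order of their lexicographically first
    voxel, which makes labeling deterministic and independent of internal
    library label order.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    arr = supra.supra if isinstance(supra, ThresholdedMap) else np.asarray(supra, dtype=bool)
    labeled, n = ndi.label(arr, structure=_STRUCTURES[connectivity])
    clusters: list[Cluster] = []
    if n:
        coords = np.argwhere(arr)  # lexicographic (C) order
        labels_at = labeled[coords[:, 0], coords[:, 1], coords[:, 2]]
        # order labels by first appearance in lexicographic scan
        _, first_pos = np.unique(labels_at, return_index=True)
        order = labels_at[np.sort(first_pos)]
        for new_label, old_label in enumerate(order, start=1):
            vox = coords[labels_at == old_label]
            clusters.append(
                Cluster(
                    label=new_label,
                    voxels=vox,
                    extent=len(vox),
                    extent_mm3=(
                        len(vox) * voxel_volume_mm3
                        if voxel_volume_mm3 is not None else None
                    ),
                )
            )
    return ClusterTable(
        clusters=clusters,
        seed_name=seed_name,
        contrast_name=contrast_name,
        connectivity=connectivity,
    )


def extent_filter(table: ClusterTable, min_voxels: int = 100) -> ClusterTable:
    """Keep only clusters strictly larger than *min_voxels* voxels."""
    if min_voxels < 0:
        raise ValueError("min_voxels must be non-negative")
    kept = [cl for cl in table.clusters if cl.extent > min_voxels]
    return replace(table, clusters=kept)


def find_peaks(
    table: ClusterTable,
    t_map: np.ndarray,
    image: VolumeImage,
    min_peak_separation_mm: float = 8.0,
    max_subpeaks: int = 8,
) -> ClusterTable:
    """Locate each cluster's peak (and same-cluster sub-peaks) on a t map.

    The peak is the argmax of t within the cluster, ties broken by
    lexicographic voxel order.  Additional sub-peaks are accepted greedily
    in descending t order provided they lie at least
    ``min_peak_separation_mm`` (world distance) from every accepted peak.
    The returned table is sorted by max t, descending.
    """
    t_map = np.asarray(t_map, dtype=float)
    out: list[Cluster] = []
    for cl in table.clusters:
        if cl.extent == 0:
            raise ValueError(f"cluster {cl.label} is empty")
        vox = cl.voxels  # already lexicographic
        t_vals = t_map[vox[:, 0], vox[:, 1], vox[:, 2]]
        if np.any(np.isnan(t_vals)):
            raise ValueError(f"t undefined on some voxels of cluster {cl.label}")
        # stable argmax: first (lexicographic) voxel attaining the max
        peak_pos = int(np.argmax(t_vals == t_vals.max()))
        peak_idx = tuple(int(v) for v in vox[peak_pos])
        peak_world = tuple(float(v) for v in voxel_to_world(image, peak_idx))
        accepted_worlds = [np.asarray(peak_world)]
        subpeaks: list[dict] = []
        order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0], -t_vals))
        for pos in order:
            if len(subpeaks) >= max_subpeaks:
                break
            w = voxel_to_world(image, vox[pos])
            if all(
                np.linalg.norm(w - aw) >= min_peak_separation_mm
                for aw in accepted_worlds
            ):
                accepted_worlds.append(np.asarray(w))
                subpeaks.append(
                    {
                        "voxel": tuple(int(v) for v in vox[pos]),
                        "world": tuple(float(v) for v in w),
                        "t": float(t_vals[pos]),
                    }
                )
        out.append(
            replace(
                cl,
                peak_index=peak_idx,
                peak_world=peak_world,
                max_t=float(t_vals[peak_pos]),
                subpeaks=subpeaks,
            )
        )
    out.sort(key=lambda c: (-(c.max_t if c.max_t is not None else -np.inf), c.label))
    return replace(table, clusters=out)


def peak_cluster_volumes(
    images: Sequence[VolumeImage],
    table: ClusterTable,
    radius_mm: float = 4.0,
    aggregate: str = "sum",
    subject_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-subject GM volume in a sphere at each cluster peak.

    Places a ``radius_mm`` sphere on every cluster's peak voxel and
    extracts its volume from each subject's image (delegating to the seed
    ROI machinery); returns a subjects x peaks table ready for clinical
    correlation analysis.
    """
    if not table.clusters:
        return pd.DataFrame(index=subject_ids if subject_ids is not None else range(len(images)))
    cols: dict[str, np.ndarray] = {}
    for cl in table.clusters:
        if cl.peak_world is None:
            raise ValueError(f"cluster {cl.label} has no peak; run find_peaks first")
        spec = SeedSpec(f"peak_{cl.label}", cl.peak_world, radius_mm)
        mask = sphere_mask(images[0], spec)
        cols[spec.name] = np.array(
            [extract_seed_volume(img, mask, aggregate) for img in images]
        )
    index = subject_ids if subject_ids is not None else range(len(images))
    return pd.DataFrame(cols, index=index)
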