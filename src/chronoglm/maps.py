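"""Replicability analysis, winning-model clustering, and atlas-overlap tables.

A winning-model label map is considered replicated at a voxel when two
independent analyses assign it the same model; the replicability percentage
is compared against the chance level 100/K for a K-model space.  Replicable
label maps are decomposed into connected clusters per model, and each cluster
is cross-referenced against atlas parcellations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ReplicabilityReport",
    "replicable_map",
    "within_subject_replicability",
    "cluster_map",
    "atlas_overlap_table",
    "boundary_map",
]


@dataclass
class ReplicabilityReport:
    group_replicability_pct: float
    n_voxels_total: int
    n_voxels_replicable: int
    within_subject_mean_pct: float | None = None
    within_subject_ci95: tuple[float, float] | None = None
    chance_level_pct: float | None = None
    n_boot: int | None = None


def replicable_map(
    winner1: np.ndarray, winner2: np.ndarray, mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Voxels with identical winning model across two analyses.

    Returns the replicable label map (the shared label where the analyses
    agree and the label is nonzero, else 0) and the replicability percentage
    ``100 * agreeing / in-mask``.
    """
    w1 = np.asarray(winner1)
    w2 = np.asarray(winner2)
    if w1.shape != w2.shape:
        raise ValueError("winner maps have different grids")
    if mask is None:
        mask = np.ones(w1.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != w1.shape:
        raise ValueError("mask grid does not match winner maps")
    agree = (w1 == w2) & (w1 != 0) & mask
    out = np.where(agree, w1, 0)
    n_mask = int(mask.sum())
    pct = 100.0 * int(agree.sum()) / n_mask if n_mask else 0.0
    return out, pct


def within_subject_replicability(
    winners_s1: list[np.ndarray],
    winners_s2: list[np.ndarray],
    mask: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
    n_models: int | None = None,
) -> ReplicabilityReport:
    """Average per-subject replicability with a percentile bootstrap 95% CI.

    Per subject, the percentage of in-mask voxels whose subject-level winning
    model agrees across the two sessions; the CI resamples subjects
    ``n_boot`` times (2.5/97.5 percentiles).
    """
    if len(winners_s1) != len(winners_s2) or len(winners_s1) == 0:
        raise ValueError("need the same (nonzero) number of subjects per session")
    mask = np.asarray(mask, dtype=bool)
    per_subject = np.array([
        replicable_map(w1, w2, mask)[1]
        for w1, w2 in zip(winners_s1, winners_s2)
    ])
    rng = np.random.default_rng(seed)
    n = per_subject.size
    boot_means = per_subject[rng.integers(0, n, size=(n_boot, n))].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    n_total = int(mask.sum())
    mean_pct = float(per_subject.mean())
    return ReplicabilityReport(
        group_replicability_pct=mean_pct,
        n_voxels_total=n_total,
        n_voxels_replicable=int(round(mean_pct / 100.0 * n_total)),
        within_subject_mean_pct=mean_pct,
        within_subject_ci95=(float(lo), float(hi)),
        chance_level_pct=100.0 / n_models if n_models else None,
        n_boot=n_boot,
    )


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def cluster_map(
    labels: np.ndarray,
    affine: np.ndarray | None = None,
    connectivity: int = 26,
    min_size: int = 1,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Connected components of a winning-model label map, per model.

    Components are computed separately for each nonzero label value with the
    given 3D neighbourhood (6, 18 or 26).  Returns a table with one row per
    retained cluster (``cluster_index``, ``model_id``, ``size_voxels``,
    centre of mass in mm through ``affine``) and a cluster-index volume.
    Clusters smaller than ``min_size`` voxels are dropped.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("labels must be a 3D volume")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    if affine is None:
        affine = np.eye(4)
    struct = _STRUCTURES[connectivity]
    rows = []
    cluster_vol = np.zeros(labels.shape, dtype=int)
    next_index = 1
    for model_id in np.unique(labels[labels != 0]):
        comp, n_comp = ndimage.label(labels == model_id, structure=struct)
        for c in range(1, n_comp + 1):
            member = comp == c
            size = int(member.sum())
            if size < min_size:
                continue
            ijk = np.argwhere(member)
            com_vox = ijk.mean(axis=0)
            com_mm = (affine @ np.r_[com_vox, 1.0])[:3]
            cluster_vol[member] = next_index
            rows.append({
                "cluster_index": next_index,
                "model_id": int(model_id),
                "size_voxels": size,
                "com_x_mm": float(com_mm[0]),
                "com_y_mm": float(com_mm[1]),
                "com_z_mm": float(com_mm[2]),
            })
            next_index += 1
    table = pd.DataFrame(rows, columns=[
        "cluster_index", "model_id", "size_voxels",
        "com_x_mm", "com_y_mm", "com_z_mm"])
    return table, cluster_vol


def atlas_overlap_table(
    cluster_table: pd.DataFrame,
    cluster_vol: np.ndarray,
    atlas: np.ndarray,
    atlas_labels: dict[int, str],
    roi_mask: np.ndarray | None = None,
    atlas_name: str = "atlas",
) -> pd.DataFrame:
    """Cross-reference clusters with an atlas parcellation.

    One row per (cluster, overlapping region) with: the cluster's index,
    model, size and centre of mass; the atlas/region names; the overlap in
    voxels; the overlap as a percentage of the cluster; the region's size
    inside the ROI and the overlap as a percentage thereof; and the region's
    total size with the corresponding percentage.  Regions with empty ROI
    intersection produce no row.
    """
    atlas = np.asarray(atlas)
    if atlas.shape != np.asarray(cluster_vol).shape:
        raise ValueError("atlas grid does not match the cluster volume "
                         "(resample the atlas with nearest neighbour first)")
    if roi_mask is None:
        roi_mask = np.ones(atlas.shape, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    rows = []
    for _, cl in cluster_table.iterrows():
        member = cluster_vol == cl["cluster_index"]
        regions, counts = np.unique(atlas[member & (atlas != 0)],
                                    return_counts=True)
        for region, overlap in zip(regions, counts):
            region_in_roi = int(((atlas == region) & roi_mask).sum())
            region_total = int((atlas == region).sum())
            if region_in_roi == 0:
                continue
            rows.append({
                "cluster_index": int(cl["cluster_index"]),
                "model_id": int(cl["model_id"]),
                "size_voxels": int(cl["size_voxels"]),
                "com_x_mm": cl["com_x_mm"],
                "com_y_mm": cl["com_y_mm"],
                "com_z_mm": cl["com_z_mm"],
                "atlas_name": atlas_name,
                "region_name": atlas_labels.get(int(region), str(region)),
                "overlap_voxels": int(overlap),
                "pct_of_cluster": 100.0 * overlap / cl["size_voxels"],
                "region_in_roi_voxels": region_in_roi,
                "pct_of_region_in_roi": 100.0 * overlap / region_in_roi,
                "region_total_voxels": region_total,
                "pct_of_region_total": 100.0 * overlap / region_total,
            })
    return pd.DataFrame(rows, columns=[
        "cluster_index", "model_id", "size_voxels",
        "com_x_mm", "com_y_mm", "com_z_mm",
        "atlas_name", "region_name", "overlap_voxels", "pct_of_cluster",
        "region_in_roi_voxels", "pct_of_region_in_roi",
        "region_total_voxels", "pct_of_region_total"])


def boundary_map(labels: np.ndarray) -> np.ndarray:
    """Region-boundary volume: 0 where all 26 neighbours share the voxel's
    label, 1 otherwise (used for drawing parcellation outlines)."""
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("labels must be a 3D volume")
    padded = np.pad(labels, 1, mode="edge")
    boundary = np.zeros(labels.shape, dtype=int)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                shifted = padded[1 + dx:1 + dx + labels.shape[0],
                                 1 + dy:1 + dy + labels.shape[1],
                                 1 + dz:1 + dz + labels.shape[2]]
                boundary |= (shifted != labels).astype(int)
    return boundary
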