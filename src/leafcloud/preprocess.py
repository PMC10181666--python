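"""Branch-cloud preprocessing: denoising, thinning, sampling, normalization.

The stages mirror standard terrestrial-lidar practice for branch samples:

1. statistical outlier removal (SOR) — drop points whose mean k-NN
   distance exceeds the global mean by more than ``std_ratio`` standard
   deviations;
2. voxel-grid thinning at 3 mm to even out the multi-station density;
3. farthest point sampling (FPS) to a fixed budget of 2048 points that
   preserves branch structure;
4. normalization of the sample into an origin-centered 2 m cube, with the
   inverse transform recorded so phenotypes are measured at real scale.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree

from .cloud import CloudError, LabeledCloud, NormalizationTransform

__all__ = [
    "remove_outliers",
    "voxel_thin",
    "farthest_point_sample",
    "normalize",
    "denormalize",
]

log = logging.getLogger(__name__)


def remove_outliers(cloud: LabeledCloud, k: int = 16, std_ratio: float = 1.0) -> LabeledCloud:
    """Statistical outlier removal.

    Keeps exactly the points whose mean distance to their ``k`` nearest
    neighbors is at most ``mean + std_ratio * std`` of the per-point mean
    distances over the whole cloud.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if std_ratio <= 0:
        raise ValueError("std_ratio must be positive")
    if cloud.n <= k:
        raise CloudError(f"need more than k={k} points, got {cloud.n}")
    tree = cKDTree(cloud.coords)
    # k+1 because the query point is its own nearest neighbor
    dists, _ = tree.query(cloud.coords, k=k + 1, workers=-1)
    mean_d = dists[:, 1:].mean(axis=1)
    thresh = mean_d.mean() + std_ratio * mean_d.std()
    keep = mean_d <= thresh
    log.info("SOR: kept %d of %d points", int(keep.sum()), cloud.n)
    return cloud.select(keep)


def voxel_thin(cloud: LabeledCloud, voxel: float = 0.003) -> LabeledCloud:
    """Voxel-grid thinning: one centroid per occupied voxel.

    The grid is axis-aligned and anchored at the coordinate origin. The
    representative point is the centroid of the voxel's points; semantic
    and instance labels are decided by majority vote within the voxel
    (semantic ties go to branch, 0; instance ties to the smallest id).
    """
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    idx = np.floor(cloud.coords / voxel).astype(np.int64)
    _, inverse, counts = np.unique(idx, axis=0, return_inverse=True, return_counts=True)
    nvox = counts.shape[0]
    centroids = np.zeros((nvox, 3))
    np.add.at(centroids, inverse, cloud.coords)
    centroids /= counts[:, None]

    def majority(values: np.ndarray, tie_low: bool) -> np.ndarray:
        out = np.empty(nvox, dtype=np.int64)
        order = np.argsort(inverse, kind="stable")
        bounds = np.searchsorted(inverse[order], np.arange(nvox + 1))
        for v in range(nvox):
            grp = values[order[bounds[v]:bounds[v + 1]]]
            ids, cnt = np.unique(grp, return_counts=True)
            best = ids[cnt == cnt.max()]
            out[v] = best.min() if tie_low else best.max()
        return out

    semantic = None if cloud.semantic is None else majority(cloud.semantic, tie_low=True)
    instance = None if cloud.instance is None else majority(cloud.instance, tie_low=True)
    log.info("voxel_thin(%.4f m): %d -> %d points", voxel, cloud.n, nvox)
    return LabeledCloud(coords=centroids, semantic=semantic, instance=instance)


def farthest_point_sample(cloud: LabeledCloud, m: int = 2048, seed: int = 0) -> LabeledCloud:
    """Farthest point sampling to exactly ``m`` points.

    Starts from a seed-selected point, then repeatedly adds the point
    maximizing its minimum distance to the already-selected set.  If the
    cloud has fewer than ``m`` points it is returned unchanged.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    n = cloud.n
    if n <= m:
        if n < m:
            log.warning("FPS: cloud has %d < m=%d points; returned unchanged", n, m)
        return cloud
    rng = np.random.default_rng(seed)
    start = int(rng.integers(n))
    selected = np.empty(m, dtype=np.int64)
    selected[0] = start
    min_d2 = np.sum((cloud.coords - cloud.coords[start]) ** 2, axis=1)
    for i in range(1, m):
        nxt = int(np.argmax(min_d2))
        selected[i] = nxt
        d2 = np.sum((cloud.coords - cloud.coords[nxt]) ** 2, axis=1)
        np.minimum(min_d2, d2, out=min_d2)
    log.info("FPS: sampled %d of %d points (seed=%d)", m, n, seed)
    return cloud.select(selected)


def normalize(cloud: LabeledCloud, cube_side: float = 2.0):
    """Center the cloud at the origin and scale it isotropically so its
    largest axis-aligned extent equals ``cube_side``.

    Returns the normalized cloud and the recorded
    :class:`NormalizationTransform` (original = normalized * scale + center),
    so :func:`denormalize` restores real-world size exactly.
    """
    if cube_side <= 0:
        raise ValueError("cube_side must be positive")
    center = cloud.coords.mean(axis=0)
    extent = cloud.coords.max(axis=0) - cloud.coords.min(axis=0)
    max_extent = float(extent.max())
    if max_extent <= 0:
        raise CloudError("degenerate cloud: all points coincident")
    scale = max_extent / cube_side  # original meters per normalized unit
    t = NormalizationTransform(center=center, scale=scale)
    return cloud.with_coords(t.forward(cloud.coords)), t


def denormalize(cloud: LabeledCloud, t: NormalizationTransform) -> LabeledCloud:
    """Map a normalized cloud back to original meters."""
    return cloud.with_coords(t.inverse(cloud.coords))
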