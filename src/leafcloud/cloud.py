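"""Core containers for labeled branch-level point clouds.

A branch sample is a set of 3D points in meters, optionally carrying a
binary semantic label per point (0 = branch wood, 1 = leaf lamina) and an
instance id per point (a non-negative leaf id, or -1 for branch /
unassigned points).  Every stage of the pipeline consumes and produces
:class:`LabeledCloud`, so labels survive filtering, thinning and sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = ["LabeledCloud", "NormalizationTransform", "CloudError"]


class CloudError(ValueError):
    """Raised for structurally invalid clouds or transform misuse."""


@dataclass
class LabeledCloud:
    """Points with optional semantic and instance labels.

    Parameters
    ----------
    coords
        ``(n, 3)`` float array, coordinates in meters.
    semantic
        Optional ``(n,)`` integer array with values in ``{0, 1}``
        (0 = branch, 1 = leaf).
    instance
        Optional ``(n,)`` integer array; leaf instances are numbered from
        0, branch/unassigned points carry -1.
    """

    coords: np.ndarray
    semantic: Optional[np.ndarray] = None
    instance: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise CloudError(f"coords must be (n, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise CloudError("cloud must contain at least one point")
        if not np.all(np.isfinite(self.coords)):
            raise CloudError("coords contain non-finite values")
        n = self.coords.shape[0]
        if self.semantic is not None:
            self.semantic = np.asarray(self.semantic, dtype=np.int64)
            if self.semantic.shape != (n,):
                raise CloudError("semantic must have one label per point")
            if not np.isin(self.semantic, (0, 1)).all():
                raise CloudError("semantic labels must be 0 (branch) or 1 (leaf)")
        if self.instance is not None:
            self.instance = np.asarray(self.instance, dtype=np.int64)
            if self.instance.shape != (n,):
                raise CloudError("instance must have one id per point")
            if (self.instance < -1).any():
                raise CloudError("instance ids must be >= -1")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def select(self, index: np.ndarray) -> "LabeledCloud":
        """Subset by boolean mask or integer index array, keeping labels."""
        return LabeledCloud(
            coords=self.coords[index],
            semantic=None if self.semantic is None else self.semantic[index],
            instance=None if self.instance is None else self.instance[index],
        )

    def leaf_points(self) -> "LabeledCloud":
        """The leaf-labeled (semantic == 1) subset."""
        if self.semantic is None:
            raise CloudError("cloud has no semantic labels")
        mask = self.semantic == 1
        if not mask.any():
            raise CloudError("cloud contains no leaf points")
        return self.select(mask)

    def with_coords(self, coords: np.ndarray) -> "LabeledCloud":
        """Same labels, new coordinates (must preserve point count)."""
        coords = np.asarray(coords, dtype=np.float64)
        if coords.shape != self.coords.shape:
            raise CloudError("with_coords must preserve the point count")
        return replace(self, coords=coords)

    def compact_instances(self) -> "LabeledCloud":
        """Renumber instance ids to a contiguous 0..K-1 range (keeps -1)."""
        if self.instance is None:
            return self
        inst = self.instance.copy()
        ids = np.unique(inst[inst >= 0])
        remap = {old: new for new, old in enumerate(ids)}
        for old, new in remap.items():
            inst[self.instance == old] = new
        return replace(self, instance=inst)


@dataclass(frozen=True)
class NormalizationTransform:
    """Invertible mapping between original and normalized coordinates.

    ``original = normalized * scale + center``; ``scale`` is in original
    meters per normalized unit.  Recorded by :func:`normalize` so that
    phenotypes can be measured at real-world scale after processing in the
    normalized frame.
    """

    center: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=np.float64))
        if self.center.shape != (3,):
            raise CloudError("center must be a 3-vector")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise CloudError("scale must be a positive finite real")

    @classmethod
    def identity(cls) -> "NormalizationTransform":
        return cls(center=np.zeros(3), scale=1.0)

    def forward(self, coords: np.ndarray) -> np.ndarray:
        """Original meters -> normalized frame."""
        return (np.asarray(coords, dtype=np.float64) - self.center) / self.scale

    def inverse(self, coords: np.ndarray) -> np.ndarray:
        """Normalized frame -> original meters."""
        return np.asarray(coords, dtype=np.float64) * self.scale + self.center
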