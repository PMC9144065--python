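"""The labelled Hounsfield-unit volume container.

World coordinates are mm.  ``origin`` is the world coordinate of the
minimum grid corner; voxel ``(i, j, k)`` has its center at
``origin + (i+1/2, j+1/2, k+1/2) * spacing`` (0-based indices).  For
phantoms the world origin sits at the body centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regions import OUTSIDE


@dataclass
class HUVolume:
    """A 3-D HU scalar grid with a congruent integer label grid."""

    values: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.values.shape != self.labels.shape:
            raise ValueError("values and labels must be shape-congruent")
        if self.values.ndim != 3:
            raise ValueError("volume must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (mm) of all voxel centers, shape ``(*shape, 3)``."""
        axes = [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def in_body_mask(self) -> np.ndarray:
        return self.labels != OUTSIDE

    def element_order(self) -> np.ndarray:
        """Flat (C-order) indices of in-body voxels — the canonical element
        ordering shared by material fields and meshes."""
        return np.flatnonzero(self.labels.ravel() != OUTSIDE)

    def world_to_index(self, point) -> tuple[int, int, int]:
        """Voxel index whose cell contains the given world point (mm)."""
        p = np.asarray(point, dtype=float)
        idx = np.floor((p - np.asarray(self.origin)) / np.asarray(self.spacing))
        return tuple(int(i) for i in idx)
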