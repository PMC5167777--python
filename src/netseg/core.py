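"""Shared spatial containers: the voxel lattice, subject time series and maps.

Everything downstream (preprocessing, decomposition, selection, metrics)
operates on a single common grid: synthetic cohorts are generated directly
in that space, so no registration step is modelled.  Voxel indexing is
0-based with axis order (x, y, z); the anterior--posterior axis is y
(larger y = more anterior).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "VolumeGrid",
    "SubjectData",
    "SpatialMap",
    "zscore_masked",
]


@dataclass(frozen=True)
class VolumeGrid:
    """A common voxel lattice with an in-brain mask.

    Parameters
    ----------
    dims : tuple of int
        Lattice size per axis (x, y, z); each >= 8.
    voxel_size_mm : tuple of float
        Physical voxel edge length per axis, in mm.
    brain_mask : ndarray of bool, shape ``dims``
        Voxels considered in-brain; all analysis (Z-scoring, correlations,
        ICA) is restricted to these voxels.
    """

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    brain_mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )
        if any(d < 8 for d in dims):
            raise ValueError(f"all grid dims must be >= 8, got {dims}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        mask = np.asarray(self.brain_mask, dtype=bool)
        if mask.shape != dims:
            raise ValueError("brain_mask shape does not match dims")
        # 500-voxel floor for realistic grids; tiny demo lattices only need
        # to be 30% full (a 500-voxel mask cannot exist on e.g. 8x8x8)
        min_voxels = min(500, int(0.3 * np.prod(dims)))
        if mask.sum() < min_voxels:
            raise ValueError(
                f"brain mask has {int(mask.sum())} voxels; need >= {min_voxels}")
        object.__setattr__(self, "brain_mask", mask)

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels."""
        return int(self.brain_mask.sum())

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Flatten a 3D volume (or stack of volumes, last axes = grid) to
        the in-mask voxel vector(s)."""
        volume = np.asarray(volume)
        return volume[..., self.brain_mask] if volume.ndim > 3 else volume[self.brain_mask]

    def embed(self, vec: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place an in-mask voxel vector back into a full 3D volume."""
        vec = np.asarray(vec, dtype=float)
        out = np.full(self.dims, fill, dtype=float)
        out[self.brain_mask] = vec
        return out

    def contains(self, ijk) -> bool:
        """True iff a 0-based voxel index lies inside the lattice."""
        return all(0 <= int(c) < d for c, d in zip(ijk, self.dims))

    def affine(self) -> np.ndarray:
        """A diagonal NIfTI affine from voxel sizes (synthetic space)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff


@dataclass
class SubjectData:
    """One subject's 4D series on the grid.

    ``series`` has shape ``grid.dims + (T,)``.  ``motion``, when present,
    is a (T, 6) table: 3 translations in mm then 3 rotations in radians.
    """

    grid: VolumeGrid
    series: np.ndarray
    tr_s: float
    motion: Optional[np.ndarray] = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.shape[:3] != self.grid.dims:
            raise ValueError("series spatial shape does not match grid")
        if self.series.shape[3] < 2:
            raise ValueError("series must have at least 2 timepoints")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("series contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.ndim != 2 or self.motion.shape[1] != 6:
                raise ValueError("motion table must have 6 columns")

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[3]

    def masked_matrix(self) -> np.ndarray:
        """Return the (T, V) time-by-maskvoxel data matrix."""
        return self.series[self.grid.brain_mask].T


@dataclass
class SpatialMap:
    """A single component/network map over the grid (zero outside mask)."""

    grid: VolumeGrid
    data: np.ndarray
    is_zscored: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.dims:
            raise ValueError("map shape does not match grid")
        inside = self.data[self.grid.brain_mask]
        if not np.all(np.isfinite(inside)):
            raise ValueError("map contains non-finite values inside mask")

    @property
    def masked(self) -> np.ndarray:
        return self.data[self.grid.brain_mask]

    def zscored(self) -> "SpatialMap":
        vec = zscore_masked(self.masked)
        return SpatialMap(self.grid, self.grid.embed(vec), is_zscored=True)


def zscore_masked(vec: np.ndarray) -> np.ndarray:
    """Z-transform a voxel vector to zero mean and unit SD (population SD).

    A constant vector maps to all zeros rather than raising.
    """
    vec = np.asarray(vec, dtype=float)
    sd = vec.std()
    if sd == 0:
        return np.zeros_like(vec)
    return (vec - vec.mean()) / sd
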