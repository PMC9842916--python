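"""Common voxel grid with a diagonal world affine.

All volumes in a cohort live on one :class:`GridSpec`: a toy stand-in for a
standard-space grid.  The affine is diagonal (no rotation/shear), so the world
coordinate of voxel ``v`` is ``origin_offset + v * voxel_size`` (mm).  The
first axis is world x; the midline is world x = 0 and x < 0 is the left
hemisphere (neurological convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D voxel grid with a diagonal affine.

    Parameters
    ----------
    shape
        Voxels per axis (x, y, z); each entry must be >= 8.
    voxel_size
        Voxel edge length per axis in mm; strictly positive.
    origin_offset
        World-mm coordinate of voxel index (0, 0, 0).  The default ``None``
        centres the grid so the midline (world x = 0) falls between the two
        central voxel columns.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin_offset: tuple[float, float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or len(vs) != 3:
            raise ValueError("GridSpec is three-dimensional")
        if any(s < 8 for s in shape):
            raise ValueError(f"all shape entries must be >= 8, got {shape}")
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size entries must be > 0, got {vs}")
        if self.origin_offset is None:
            origin = tuple(-(s - 1) * v / 2.0 for s, v in zip(shape, vs))
        else:
            origin = tuple(float(o) for o in self.origin_offset)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "origin_offset", origin)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal, mm)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        aff[:3, 3] = self.origin_offset
        return aff

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def world_coords(self, voxels: np.ndarray) -> np.ndarray:
        """World-mm coordinates for an (n, 3) array of voxel indices."""
        voxels = np.atleast_2d(np.asarray(voxels, dtype=float))
        return np.asarray(self.origin_offset) + voxels * np.asarray(self.voxel_size)

    def x_world(self) -> np.ndarray:
        """World x coordinate of each voxel column along axis 0."""
        return self.origin_offset[0] + np.arange(self.shape[0]) * self.voxel_size[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin_offset, other.origin_offset)
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.voxel_size, self.origin_offset))


def grid_from_affine(shape: tuple[int, int, int], affine: np.ndarray) -> GridSpec:
    """Build a GridSpec from a NIfTI-style affine; must be diagonal."""
    affine = np.asarray(affine, dtype=float)
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot))):
        raise ValueError("only diagonal affines are supported")
    return GridSpec(
        shape=tuple(int(s) for s in shape),
        voxel_size=tuple(np.diag(rot)),
        origin_offset=tuple(affine[:3, 3]),
    )
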