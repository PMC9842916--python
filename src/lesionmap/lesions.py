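"""Lesion masks: I/O, cohort incidence maps, volume and hemisphere summaries."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

from .grid import GridSpec, grid_from_affine


@dataclass
class LesionMask:
    """Binary lesion mask for one subject on a common grid."""

    grid: GridSpec
    voxels: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} does not match grid {self.grid.shape}"
            )
        uniq = np.unique(self.voxels)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("lesion mask values must be binary (0/1)")
        self.voxels = self.voxels.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class IncidenceMap:
    """Voxelwise count of lesioned subjects across a cohort."""

    grid: GridSpec
    counts: np.ndarray
    n_subjects: int


def incidence_map(masks: Sequence[LesionMask]) -> IncidenceMap:
    """Voxelwise sum of cohort lesion masks (lesion incidence map).

    All masks must share one grid; a mismatch is reported with the offending
    subject id.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("incidence_map needs at least one mask")
    grid = masks[0].grid
    counts = np.zeros(grid.shape, dtype=np.int64)
    for m in masks:
        if m.grid != grid:
            raise ValueError(f"grid mismatch for subject {m.subject_id!r}")
        counts += m.voxels
    return IncidenceMap(grid=grid, counts=counts, n_subjects=len(masks))


def lesion_volume(mask: LesionMask) -> float:
    """Lesion volume in mm^3 (voxel count x voxel volume)."""
    return mask.n_voxels * mask.grid.voxel_volume_mm3


def hemisphere_of(mask: LesionMask) -> str:
    """Side of the lesion: 'left' (all voxels at world x<0), 'right', or 'bilateral'."""
    if mask.n_voxels == 0:
        raise ValueError("hemisphere_of requires a nonempty mask")
    x_world = mask.grid.x_world()
    per_column = mask.voxels.sum(axis=(1, 2))
    left = per_column[x_world < 0].sum() > 0
    right = per_column[x_world > 0].sum() > 0
    if left and right:
        return "bilateral"
    return "left" if left else "right"


def save_mask(mask: LesionMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def load_mask(path: str | Path, subject_id: str | None = None) -> LesionMask:
    img = nib.load(str(path))
    grid = grid_from_affine(img.shape, img.affine)
    sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
    return LesionMask(grid=grid, voxels=np.asarray(img.dataobj), subject_id=sid)


def save_incidence(imap: IncidenceMap, path: str | Path) -> None:
    img = nib.Nifti1Image(imap.counts.astype(np.int32), imap.grid.affine)
    nib.save(img, str(path))


def load_masks(paths: Iterable[str | Path]) -> list[LesionMask]:
    return [load_mask(p) for p in paths]
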