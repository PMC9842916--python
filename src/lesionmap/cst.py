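"""Slice-wise corticospinal-tract impairment scoring.

The CST is decomposed into four fiber subsets by cortical origin — M1
(primary motor), PMC (premotor), SMA (supplementary motor) and S1 (primary
somatosensory) — each a binary volume per hemisphere on the common grid.
For a lesion and one subset, every axial slice with lesion-tract overlap
yields a ratio: overlap area / tract area *in that slice*.  The impairment
percentage is the maximum of these slice ratios, x100.  The slice-wise
denominator (not the whole-tract volume) is the standard lesion-load
convention; a whole-volume alternative is available via ``method``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import GridSpec, grid_from_affine
from .lesions import LesionMask

SUBSET_NAMES = ("M1", "PMC", "SMA", "S1")
HEMISPHERES = ("left", "right")


@dataclass
class FiberAtlas:
    """Four CST fiber subsets (M1/PMC/SMA/S1 origin) per hemisphere."""

    grid: GridSpec
    subsets: dict[tuple[str, str], np.ndarray]  # (subset, hemisphere) -> binary 3D

    def __post_init__(self) -> None:
        for key, vol in self.subsets.items():
            vol = np.asarray(vol).astype(np.uint8)
            if vol.shape != self.grid.shape:
                raise ValueError(f"atlas subset {key} shape mismatch")
            if vol.sum() == 0:
                raise ValueError(f"atlas subset {key} is empty")
            self.subsets[key] = vol

    def subset(self, name: str, hemisphere: str) -> np.ndarray:
        return self.subsets[(name, hemisphere)]


@dataclass
class ImpairmentProfile:
    """Per-subject impairment percentages of the four ipsilesional CST subsets."""

    subject_id: str
    hemisphere: str
    percentages: dict[str, float]
    argmax_slice: dict[str, int | None] = field(default_factory=dict)


def impairment_percentage(
    lesion: LesionMask,
    subset: np.ndarray,
    method: str = "slice_max",
) -> tuple[float, int | None]:
    """Impairment percentage of one CST fiber subset.

    With ``method="slice_max"`` (default), for each axial slice z (third voxel
    axis) where the lesion overlaps the subset, compute
    ``100 * |lesion & subset|_z / |subset|_z`` and return the maximum over
    those slices together with the argmax slice index; (0.0, None) when no
    slice overlaps.  ``method="volume"`` uses a single whole-tract ratio.
    """
    subset = np.asarray(subset)
    if subset.shape != lesion.grid.shape:
        raise ValueError("lesion and fiber subset are on different grids")
    subset = subset.astype(bool)
    if not subset.any():
        raise ValueError("fiber subset is empty")
    les = lesion.voxels.astype(bool)

    if method == "volume":
        ratio = 100.0 * np.count_nonzero(les & subset) / np.count_nonzero(subset)
        return float(ratio), None
    if method != "slice_max":
        raise ValueError(f"unknown method {method!r}")

    overlap_per_slice = np.count_nonzero(les & subset, axis=(0, 1))
    subset_per_slice = np.count_nonzero(subset, axis=(0, 1))
    has_overlap = overlap_per_slice > 0
    if not has_overlap.any():
        return 0.0, None
    ratios = np.zeros(len(overlap_per_slice))
    ratios[has_overlap] = (
        100.0 * overlap_per_slice[has_overlap] / subset_per_slice[has_overlap]
    )
    z = int(np.argmax(ratios))
    return float(ratios[z]), z


def impairment_profile(
    lesion: LesionMask,
    atlas: FiberAtlas,
    hemisphere: str,
    method: str = "slice_max",
) -> ImpairmentProfile:
    """Impairment percentages of the four ipsilesional fiber subsets."""
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {hemisphere!r}")
    if atlas.grid != lesion.grid:
        raise ValueError("lesion and atlas are on different grids")
    percentages: dict[str, float] = {}
    argmax: dict[str, int | None] = {}
    for name in SUBSET_NAMES:
        pct, z = impairment_percentage(lesion, atlas.subset(name, hemisphere), method)
        percentages[name] = pct
        argmax[name] = z
    return ImpairmentProfile(
        subject_id=lesion.subject_id,
        hemisphere=hemisphere,
        percentages=percentages,
        argmax_slice=argmax,
    )


def save_atlas(atlas: FiberAtlas, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for (name, hemi), vol in atlas.subsets.items():
        img = nib.Nifti1Image(vol.astype(np.uint8), atlas.grid.affine)
        nib.save(img, str(out_dir / f"cst_{name}_{hemi}.nii.gz"))


def load_atlas(atlas_dir: str | Path) -> FiberAtlas:
    atlas_dir = Path(atlas_dir)
    subsets: dict[tuple[str, str], np.ndarray] = {}
    grid: GridSpec | None = None
    for name in SUBSET_NAMES:
        for hemi in HEMISPHERES:
            img = nib.load(str(atlas_dir / f"cst_{name}_{hemi}.nii.gz"))
            if grid is None:
                grid = grid_from_affine(img.shape, img.affine)
            subsets[(name, hemi)] = np.asarray(img.dataobj)
    assert grid is not None
    return FiberAtlas(grid=grid, subsets=subsets)
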