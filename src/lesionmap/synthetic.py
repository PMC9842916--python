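"""Seeded synthetic stroke cohorts with known ground truth.

Emulates the data a subcortical-stroke morphometry study would collect,
on a desk-scale grid:

* a fiber atlas with four CST subsets (M1/PMC/SMA/S1 origin) per hemisphere,
  built as tapering columns spanning the inferior-superior extent;
* ellipsoidal subcortical lesions placed near the internal-capsule region,
  so that lesion-tract overlap varies realistically across patients;
* whole-extremity Fugl-Meyer (WE_FM) scores decreasing with M1-fiber
  impairment, with a point mass at 100 that splits patients into partial
  (PR, WE_FM < 100) and complete (CR, WE_FM = 100) recovery strata;
* a long-format table of ROI measures (thickness / area / GMV) over four
  visits, with covariate effects (age, sex, scanner), lesion-triggered
  chronic deficits, per-group longitudinal slopes, a subject random
  intercept, and Gaussian noise;
* optional 2D "surface sheets" per subject carrying the same chronic
  deficits as spatial patches, for mass-univariate group mapping.

Every draw is deterministic given the config seed, and the generator returns
its ground truth (true impairments, true effects, true slopes) so that
downstream parameter-recovery tests are closed-loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .cst import HEMISPHERES, SUBSET_NAMES, FiberAtlas, impairment_profile
from .grid import GridSpec
from .lesions import LesionMask, hemisphere_of, lesion_volume, save_mask

# ---------------------------------------------------------------------------
# fiber atlas


def make_fiber_atlas(grid: GridSpec, seed: int = 0) -> FiberAtlas:
    """Synthetic CST fiber atlas: four tapering columns per hemisphere.

    Each subset is a contiguous column of axial discs spanning at least half
    the inferior-superior (z) extent, mirrored across the midline.  Disc
    radius grows with z, so per-slice areas vary and the slice-wise
    impairment maximum is non-trivial.  Deterministic for a fixed seed.
    """
    nx, ny, nz = grid.shape
    if nx < 16 or ny < 12 or nz < 8:
        raise ValueError(
            f"grid {grid.shape} too small to place four fiber columns per hemisphere"
        )
    rng = np.random.default_rng(seed)
    # base (x, y) offsets of the four columns, in units of grid fraction,
    # relative to the centre of one hemisphere
    base_xy = {
        "M1": (0.0, 0.0),
        "PMC": (0.0, -0.15),
        "SMA": (-0.08, -0.08),
        "S1": (0.0, 0.15),
    }
    z_lo = nz // 8
    z_hi = nz - 1
    zs = np.arange(z_lo, z_hi + 1)
    xw = grid.x_world()
    subsets: dict[tuple[str, str], np.ndarray] = {}
    for hemi in HEMISPHERES:
        side = xw < 0 if hemi == "left" else xw > 0
        side_idx = np.where(side)[0]
        cx = int(round(side_idx.mean()))
        cy = ny // 2
        for name in SUBSET_NAMES:
            dx, dy = base_xy[name]
            px = cx + int(round(dx * nx)) + int(rng.integers(-1, 2))
            py = cy + int(round(dy * ny)) + int(rng.integers(-1, 2))
            vol = np.zeros(grid.shape, dtype=np.uint8)
            for z in zs:
                frac = (z - z_lo) / max(z_hi - z_lo, 1)
                radius = 1.0 + 1.5 * frac + 0.3 * rng.standard_normal()
                radius = max(radius, 0.8)
                r = int(np.ceil(radius))
                for ix in range(max(px - r, 0), min(px + r + 1, nx)):
                    for iy in range(max(py - r, 0), min(py + r + 1, ny)):
                        if (ix - px) ** 2 + (iy - py) ** 2 <= radius**2:
                            if side[ix]:
                                vol[ix, iy, z] = 1
            if vol.sum() == 0:
                raise ValueError(f"could not place fiber column {name}/{hemi}")
            subsets[(name, hemi)] = vol
    return FiberAtlas(grid=grid, subsets=subsets)


# ---------------------------------------------------------------------------
# lesions


def make_lesion(
    grid: GridSpec,
    center: Sequence[int],
    radii_mm: Sequence[float],
    subject_id: str = "",
) -> LesionMask:
    """Binary ellipsoid lesion clipped to the grid.

    Voxel v belongs to the mask iff sum(((v - center) * voxel_size / radii)^2) <= 1.
    """
    center = np.asarray(center, dtype=float)
    radii = np.asarray(radii_mm, dtype=float)
    if np.any(radii <= 0):
        raise ValueError(f"radii must be positive, got {radii_mm}")
    if np.any(center < 0) or np.any(center >= np.asarray(grid.shape)):
        raise ValueError(f"center {center} outside grid {grid.shape}")
    vs = np.asarray(grid.voxel_size)
    # bounding box to avoid scanning the whole grid
    lo = np.maximum(np.floor(center - radii / vs).astype(int), 0)
    hi = np.minimum(np.ceil(center + radii / vs).astype(int) + 1, grid.shape)
    vox = np.zeros(grid.shape, dtype=np.uint8)
    ix, iy, iz = [np.arange(lo[a], hi[a]) for a in range(3)]
    gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
    d = (
        ((gx - center[0]) * vs[0] / radii[0]) ** 2
        + ((gy - center[1]) * vs[1] / radii[1]) ** 2
        + ((gz - center[2]) * vs[2] / radii[2]) ** 2
    )
    inside = d <= 1.0
    vox[gx[inside], gy[inside], gz[inside]] = 1
    if vox.sum() == 0:
        # degenerate ellipsoid smaller than half a voxel: keep the centre voxel
        c = np.round(center).astype(int)
        vox[c[0], c[1], c[2]] = 1
    return LesionMask(grid=grid, voxels=vox, subject_id=subject_id)


# ---------------------------------------------------------------------------
# cohort configuration


@dataclass(frozen=True)
class Effect:
    """One injected chronic deficit.

    ``trigger`` is a CST subset name ("M1"/"PMC"/"SMA"/"S1": contribution is
    ``delta * impairment_pct / 100``, graded), a group label ("PR"/"CR":
    binary, fires for that stratum), or "locus" (binary, fires when the
    lesion covers ``locus`` or its x-mirrored voxel).
    """

    trigger: str
    roi: str
    measure: str
    delta: float
    locus: tuple[int, int, int] | None = None


DEFAULT_BASELINES = {"thickness": 2.5, "area": 1000.0, "gmv": 2000.0}
DEFAULT_NOISE_SD = {"thickness": 0.05, "area": 20.0, "gmv": 50.0}
DEFAULT_COVARIATE_EFFECTS = {
    "thickness": {"age": -0.003, "sex": 0.03, "scanner": 0.02},
    "area": {"age": -1.0, "sex": 15.0, "scanner": 8.0},
    "gmv": {"age": -3.0, "sex": 40.0, "scanner": 20.0},
}

# roi -> measure; the six default ROIs mirror regions commonly reported in
# subcortical-stroke morphometry (ipsilesional IL_*, contralesional CL_*)
DEFAULT_ROI_MEASURES = {
    "IL_precentral": "thickness",
    "IL_postcentral": "thickness",
    "IL_frontal_pole": "thickness",
    "IL_lingual": "thickness",
    "IL_cingulate": "area",
    "CL_rectus": "gmv",
}

# per-group true slopes (measure units / month); defaults realise the four
# longitudinal evolution patterns: 1 decline in both patient groups (PR
# significant), 2 increase in both, 3 increase only in CR, 4 divergent
DEFAULT_SLOPES = {
    "IL_precentral": {"PR": -0.010, "CR": -0.004, "HC": 0.0},  # pattern 1
    "IL_lingual": {"PR": 0.008, "CR": 0.012, "HC": 0.0},  # pattern 2
    "IL_frontal_pole": {"PR": 0.0, "CR": 0.010, "HC": 0.0},  # pattern 3
    "IL_cingulate": {"PR": -2.0, "CR": 2.0, "HC": 0.0},  # pattern 4
    "IL_postcentral": {"PR": -0.008, "CR": -0.003, "HC": 0.0},  # pattern 1
    "CL_rectus": {"PR": 0.0, "CR": 0.0, "HC": 0.0},  # null
}

# deltas chosen so each injected deficit is ~1.5-2 residual SDs at the mean
# impairment of its triggering subset (S1 fibers are hit far less often than
# M1 by internal-capsule lesions, hence the larger per-percent coefficient)
DEFAULT_EFFECTS = (
    Effect("M1", "IL_precentral", "thickness", -0.25),
    Effect("S1", "IL_postcentral", "thickness", -0.80),
    Effect("PR", "IL_cingulate", "area", -40.0),
)

# patch centres (row, col) of each ROI on the 2D surface sheet
DEFAULT_SHEET_LAYOUT = {
    "IL_precentral": (16, 16),
    "IL_postcentral": (16, 44),
    "IL_frontal_pole": (44, 16),
    "IL_lingual": (44, 44),
    "IL_cingulate": (30, 30),
    "CL_rectus": (54, 54),
}


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    n_patients: int = 80
    n_controls: int = 40
    fraction_left_hemisphere: float = 0.5
    lesion_size_range: tuple[int, int] = (80, 400)  # voxels (~0.6-3.2 cm^3)
    roi_measures: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ROI_MEASURES)
    )
    effect_table: tuple[Effect, ...] = DEFAULT_EFFECTS
    slope_table: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SLOPES.items()}
    )
    baselines: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()}
    )
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    intercept_sd: dict[str, float] | None = None  # None -> equal to noise_sd (ICC 0.5)
    visit_months: tuple[float, ...] = (0.25, 1.0, 3.0, 8.0)
    visit_jitter_frac: float = 0.2
    cr_fraction: float = 0.45
    wefm_gain: float = 0.5  # WE_FM points lost per M1 impairment percent
    wefm_noise_sd: float = 6.0
    sheet_shape: tuple[int, int] = (64, 64)
    sheet_layout: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SHEET_LAYOUT)
    )
    sheet_patch_halfsize: int = 3
    sheet_noise_fwhm_px: float = 3.0
    make_sheets: bool = True
    missing_visit_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_left_hemisphere <= 1.0:
            raise ValueError("fraction_left_hemisphere must be in [0, 1]")
        if not 0.0 < self.cr_fraction < 1.0:
            raise ValueError("cr_fraction must be in (0, 1)")
        if any(v <= 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd entries must be > 0")
        if list(self.visit_months) != sorted(set(self.visit_months)):
            raise ValueError("visit_months must be strictly increasing")
        if self.intercept_sd is None:
            self.intercept_sd = dict(self.noise_sd)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # PR / CR / HC
    hemisphere: str  # left / right / none
    age: float
    sex: str  # M / F
    scanner: str
    wefm: float
    lesion_volume: float


@dataclass
class MeasureSheet:
    """Per-subject 2D scalar field (toy stand-in for one surface hemisphere)."""

    subject_id: str
    values: np.ndarray
    measure: str
    global_value: float


@dataclass
class GroundTruth:
    """Everything the generator drew, for closed-loop recovery tests."""

    effects: tuple[Effect, ...]
    slopes: dict[str, dict[str, float]]
    impairments: pd.DataFrame  # subject_id x subset true impairment percentages
    lesion_centers: dict[str, tuple[int, int, int]]
    hemispheres: dict[str, str]
    sheet_layout: dict[str, tuple[int, int]]
    chronic_deficit: pd.DataFrame  # subject_id, roi, total injected chronic delta


@dataclass
class Cohort:
    config: CohortConfig
    grid: GridSpec
    atlas: FiberAtlas
    subjects: list[SubjectRecord]
    lesions: dict[str, LesionMask]
    table: pd.DataFrame
    sheets: dict[tuple[str, str], MeasureSheet]
    truth: GroundTruth

    @property
    def subject_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.subjects])

    def chronic_table(self) -> pd.DataFrame:
        """Rows of the last (chronic, >6 months) visit only."""
        return self.table[self.table["visit"] == self.table["visit"].max()].copy()


# ---------------------------------------------------------------------------
# cohort simulation


def _lesion_center(rng: np.random.Generator, grid: GridSpec, hemisphere: str) -> np.ndarray:
    """Draw a lesion centre near the subcortical internal-capsule region."""
    nx, ny, nz = grid.shape
    xw = grid.x_world()
    side_idx = np.where(xw < 0 if hemisphere == "left" else xw > 0)[0]
    # centred on the posterior limb of the internal-capsule stand-in, where
    # both M1- and S1-originating fibers are commonly transected
    base = np.array([side_idx.mean(), ny * 0.58, nz * 0.3])
    jitter = rng.normal(0.0, [nx * 0.06, ny * 0.10, nz * 0.06])
    c = np.clip(base + jitter, 1, np.asarray(grid.shape) - 2)
    return c


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], fwhm_px: float) -> np.ndarray:
    from .clustermap import smooth_unit_noise

    return smooth_unit_noise(rng, shape, fwhm_px / 2.3548)


def simulate_cohort(
    config: CohortConfig,
    grid: GridSpec | None = None,
    atlas: FiberAtlas | None = None,
) -> Cohort:
    """Generate one full synthetic cohort (patients + controls, all visits).

    Patients get an ellipsoidal subcortical lesion, CST impairment-driven
    WE_FM, chronic deficits per the effect table, and group-specific
    longitudinal slopes; controls get covariate effects and noise only.
    Raises if the PR or CR stratum ends up empty after a retry cap.
    """
    if grid is None:
        grid = GridSpec(shape=(32, 32, 32))
    if atlas is None:
        atlas = make_fiber_atlas(grid, seed=config.seed)
    if atlas.grid != grid:
        raise ValueError("atlas grid does not match cohort grid")

    for attempt in range(5):
        rng = np.random.default_rng((config.seed + 1000003 * attempt) % 2**31)
        cohort = _simulate_once(config, grid, atlas, rng)
        groups = {s.group for s in cohort.subjects}
        if {"PR", "CR"} <= groups or config.n_patients == 0:
            return cohort
    raise RuntimeError(
        "could not populate both PR and CR strata after 5 attempts; "
        "check cr_fraction and n_patients"
    )


def _simulate_once(
    config: CohortConfig, grid: GridSpec, atlas: FiberAtlas, rng: np.random.Generator
) -> Cohort:
    n_p, n_c = config.n_patients, config.n_controls
    n = n_p + n_c
    sids = [f"sub-{i:03d}" for i in range(n)]
    is_patient = np.arange(n) < n_p

    ages = np.round(rng.uniform(40, 70, n), 1)
    sexes = np.where(rng.random(n) < 0.6, "M", "F")
    scanners = np.where(rng.random(n) < 0.5, "A", "B")

    lesions: dict[str, LesionMask] = {}
    centers: dict[str, tuple[int, int, int]] = {}
    hemis: dict[str, str] = {}
    imp_rows = []
    vol_mm3 = np.zeros(n)
    voxvol = grid.voxel_volume_mm3

    for i, sid in enumerate(sids):
        if not is_patient[i]:
            hemis[sid] = "none"
            imp_rows.append({"subject_id": sid, **{s: 0.0 for s in SUBSET_NAMES}})
            continue
        hemi = "left" if rng.random() < config.fraction_left_hemisphere else "right"
        hemis[sid] = hemi
        center = _lesion_center(rng, grid, hemi)
        target_vox = rng.integers(config.lesion_size_range[0], config.lesion_size_range[1] + 1)
        r_iso = (3.0 * target_vox * voxvol / (4.0 * np.pi)) ** (1.0 / 3.0)
        radii = r_iso * rng.uniform(0.8, 1.25, 3)
        lesion = make_lesion(grid, center, radii, subject_id=sid)
        # lesions are unilateral: clip at the midline
        xw = grid.x_world()
        lesion.voxels[(xw > 0) if hemi == "left" else (xw < 0), :, :] = 0
        if lesion.n_voxels == 0:
            c = np.round(center).astype(int)
            lesion.voxels[c[0], c[1], c[2]] = 1
        lesions[sid] = lesion
        centers[sid] = tuple(int(round(c)) for c in center)
        vol_mm3[i] = lesion_volume(lesion)
        profile = impairment_profile(lesion, atlas, hemi)
        imp_rows.append({"subject_id": sid, **profile.percentages})

    impairments = pd.DataFrame(imp_rows).set_index("subject_id")

    # WE_FM: decreasing in M1 impairment; the top cr_fraction of raw scores is
    # snapped to exactly 100 (complete recovery), giving the CR point mass
    wefm = np.full(n, np.nan)
    if n_p > 0:
        m1 = impairments.loc[[sids[i] for i in range(n_p)], "M1"].to_numpy()
        raw = 100.0 - config.wefm_gain * m1 + rng.normal(0, config.wefm_noise_sd, n_p)
        n_cr = int(round(config.cr_fraction * n_p))
        n_cr = min(max(n_cr, 1), n_p - 1)
        order = np.argsort(raw)  # ascending; top n_cr become CR
        w = np.clip(raw, 0.0, 99.0)
        w[order[n_p - n_cr :]] = 100.0
        wefm[:n_p] = np.round(w, 1)

    groups = np.where(is_patient, np.where(wefm >= 100.0, "CR", "PR"), "HC")

    subjects = [
        SubjectRecord(
            subject_id=sids[i],
            group=str(groups[i]),
            hemisphere=hemis[sids[i]],
            age=float(ages[i]),
            sex=str(sexes[i]),
            scanner=str(scanners[i]),
            wefm=float(wefm[i]) if is_patient[i] else float("nan"),
            lesion_volume=float(vol_mm3[i]),
        )
        for i in range(n)
    ]

    # chronic deficit per subject x roi from the effect table
    deficit = {(sid, roi): 0.0 for sid in sids for roi in config.roi_measures}
    for eff in config.effect_table:
        if eff.roi not in config.roi_measures:
            raise ValueError(f"effect targets unknown roi {eff.roi!r}")
        for i, sid in enumerate(sids):
            if not is_patient[i]:
                continue
            if eff.trigger in SUBSET_NAMES:
                contrib = eff.delta * impairments.loc[sid, eff.trigger] / 100.0
            elif eff.trigger in ("PR", "CR"):
                contrib = eff.delta if groups[i] == eff.trigger else 0.0
            elif eff.trigger == "locus":
                if eff.locus is None:
                    raise ValueError("locus trigger requires a locus voxel")
                v = lesions[sid].voxels
                lx, ly, lz = eff.locus
                hit = v[lx, ly, lz] or v[grid.shape[0] - 1 - lx, ly, lz]
                contrib = eff.delta if hit else 0.0
            else:
                raise ValueError(f"unknown effect trigger {eff.trigger!r}")
            deficit[(sid, eff.roi)] += float(contrib)

    # longitudinal measure table
    sex_num = (sexes == "M").astype(float)
    scan_num = (scanners == "B").astype(float)
    rows = []
    intercepts = {
        (sid, roi): rng.normal(0.0, config.intercept_sd[config.roi_measures[roi]])
        for sid in sids
        for roi in config.roi_measures
    }
    visit_times = {}
    for i, sid in enumerate(sids):
        times = np.array(config.visit_months, dtype=float)
        jit = rng.uniform(-config.visit_jitter_frac, config.visit_jitter_frac, len(times))
        times = np.maximum(times * (1.0 + jit), 0.05)
        times = np.sort(times)
        visit_times[sid] = times
    for roi, measure in config.roi_measures.items():
        cov = config.covariate_effects[measure]
        base = config.baselines[measure]
        slopes = config.slope_table.get(roi, {"PR": 0.0, "CR": 0.0, "HC": 0.0})
        for i, sid in enumerate(sids):
            slope = slopes.get(str(groups[i]), 0.0)
            for v, t in enumerate(visit_times[sid]):
                if v < len(config.visit_months) - 1 and rng.random() < config.missing_visit_prob:
                    continue
                val = (
                    base
                    + cov["age"] * (ages[i] - 55.0)
                    + cov["sex"] * sex_num[i]
                    + cov["scanner"] * scan_num[i]
                    + deficit[(sid, roi)]
                    + slope * t
                    + intercepts[(sid, roi)]
                    + rng.normal(0.0, config.noise_sd[measure])
                )
                rows.append(
                    {
                        "subject_id": sid,
                        "roi": roi,
                        "measure": measure,
                        "value": val,
                        "visit": v,
                        "timepoint_months": t,
                        "age": ages[i],
                        "sex": sexes[i],
                        "scanner": scanners[i],
                        "group": groups[i],
                        "wefm": wefm[i],
                        "lesion_volume": vol_mm3[i],
                        **{
                            f"imp_{s}": impairments.loc[sid, s]
                            for s in SUBSET_NAMES
                        },
                    }
                )
    table = pd.DataFrame(rows)

    # chronic surface sheets
    sheets: dict[tuple[str, str], MeasureSheet] = {}
    if config.make_sheets:
        measures = sorted(set(config.roi_measures.values()))
        h = config.sheet_patch_halfsize
        for i, sid in enumerate(sids):
            for measure in measures:
                sheet = config.baselines[measure] + config.noise_sd[
                    measure
                ] * _smooth_noise(rng, config.sheet_shape, config.sheet_noise_fwhm_px)
                for roi, (r, c) in config.sheet_layout.items():
                    if config.roi_measures.get(roi) != measure:
                        continue
                    d = deficit[(sid, roi)]
                    if d != 0.0:
                        sheet[r - h : r + h, c - h : c + h] += d
                sheets[(sid, measure)] = MeasureSheet(
                    subject_id=sid,
                    values=sheet,
                    measure=measure,
                    global_value=float(sheet.mean()),
                )

    truth = GroundTruth(
        effects=tuple(config.effect_table),
        slopes={k: dict(v) for k, v in config.slope_table.items()},
        impairments=impairments,
        lesion_centers=centers,
        hemispheres=hemis,
        sheet_layout=dict(config.sheet_layout),
        chronic_deficit=pd.DataFrame(
            [
                {"subject_id": sid, "roi": roi, "delta": d}
                for (sid, roi), d in deficit.items()
            ]
        ),
    )
    return Cohort(
        config=config,
        grid=grid,
        atlas=atlas,
        subjects=subjects,
        lesions=lesions,
        table=table,
        sheets=sheets,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# on-disk export


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write lesions/atlas as NIfTI, tables as TSV, ground truth as YAML."""
    out = Path(out_dir)
    (out / "lesions").mkdir(parents=True, exist_ok=True)
    from .cst import save_atlas

    save_atlas(cohort.atlas, out / "atlas")
    for sid, mask in cohort.lesions.items():
        save_mask(mask, out / "lesions" / f"{sid}.nii.gz")
    cohort.table.to_csv(out / "measures.tsv", sep="\t", index=False)
    cohort.subject_frame.to_csv(out / "subjects.tsv", sep="\t", index=False)
    truth: dict[str, Any] = {
        "slopes": cohort.truth.slopes,
        "hemispheres": cohort.truth.hemispheres,
        "lesion_centers": {k: list(v) for k, v in cohort.truth.lesion_centers.items()},
        "effects": [
            {
                "trigger": e.trigger,
                "roi": e.roi,
                "measure": e.measure,
                "delta": e.delta,
                "locus": list(e.locus) if e.locus else None,
            }
            for e in cohort.truth.effects
        ],
    }
    with open(out / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh)
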