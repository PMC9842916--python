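"""Seeded calibration and recovery studies for the whole pipeline.

Each function simulates data with known ground truth under the generator's
study conditions, runs the corresponding analysis stage, and returns the
calibration or recovery quantity (a rate, an error, a coverage).  They back
both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clustermap, lmm, stats, vlsm
from .grid import GridSpec
from .synthetic import (
    CohortConfig,
    Effect,
    MeasureSheet,
    make_lesion,
    simulate_cohort,
)


def _seed(base: int, k: int) -> int:
    return int((base * 1_000_003 + k) % 2**31)


# ---------------------------------------------------------------------------
# VLSM


def _draw_lesion_cohort(rng, grid, n):
    """Patient lesions with the generator's subcortical placement."""
    from .synthetic import _lesion_center

    masks = []
    for i in range(n):
        c = _lesion_center(rng, grid, "left")
        target = rng.integers(40, 251)
        r = (3.0 * target * grid.voxel_volume_mm3 / (4 * np.pi)) ** (1 / 3)
        masks.append(
            make_lesion(grid, c, r * rng.uniform(0.8, 1.25, 3), subject_id=f"s{i:03d}")
        )
    return masks


def _covariates(rng, masks):
    n = len(masks)
    return pd.DataFrame(
        {
            "age": rng.uniform(40, 70, n),
            "sex": rng.choice(["M", "F"], n),
            "scanner": rng.choice(["A", "B"], n),
            "lesion_volume": [m.n_voxels * m.grid.voxel_volume_mm3 for m in masks],
        }
    )


def vlsm_null_calibration(
    n_reps: int = 200, n: int = 60, seed: int = 0, q: float = 0.05
) -> float:
    """Mean fraction of FDR-surviving voxels when outcome is independent of
    the lesions (voxel-level false-discovery calibration)."""
    grid = GridSpec(shape=(32, 32, 32))
    fractions = np.zeros(n_reps)
    for rep in range(n_reps):
        rng = np.random.default_rng(_seed(seed, rep))
        masks = _draw_lesion_cohort(rng, grid, n)
        y = 2.5 + rng.normal(0, 0.1, n)
        res = vlsm.vlsm_map(masks, y, _covariates(rng, masks), q=q)
        n_tested = res.tested_mask.sum()
        fractions[rep] = res.significant.sum() / n_tested if n_tested else 0.0
    return float(fractions.mean())


def vlsm_localization(
    n_reps: int = 50, n: int = 60, effect_d: float = 1.0, seed: int = 0
) -> float:
    """Fraction of replicates whose largest reported cluster centres within
    2 voxels of the deficit-carrying lesion locus.

    Two-locus placement: half the patients are lesioned at a posterior
    capsular locus A, half at an anterior locus B eight voxels away; patients
    whose lesion covers A carry an outcome deficit of ``effect_d`` residual
    standard deviations.  With tight placement the lesion status of the
    voxels around A coincides with carrier status, which is the regime where
    the mass-univariate map is informative at this sample size; the
    between-carrier effect is held at d ~ 1.
    """
    grid = GridSpec(shape=(32, 32, 32))
    noise_sd = 0.1
    locus_a = np.array([8, 18, 10])
    locus_b = np.array([8, 10, 10])
    hits = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(_seed(seed + 7, rep))
        masks = []
        for i in range(n):
            base = locus_a if i % 2 == 0 else locus_b
            c = np.clip(base + rng.normal(0, 0.35, 3), 1, np.asarray(grid.shape) - 2)
            radii = rng.uniform(7.0, 10.0, 3)
            masks.append(make_lesion(grid, c, radii, subject_id=f"s{i:03d}"))
        carrier = np.array([bool(m.voxels[tuple(locus_a)]) for m in masks])
        y = 2.5 - effect_d * noise_sd * carrier + rng.normal(0, noise_sd, n)
        res = vlsm.vlsm_map(masks, y, _covariates(rng, masks), min_cluster=10)
        neg = [c for c in res.clusters if c.sign == -1]
        if not neg:
            continue
        main = max(neg, key=lambda c: c.n_voxels)
        center_vox = (np.asarray(main.center_mm) - grid.origin_offset) / np.asarray(
            grid.voxel_size
        )
        if np.linalg.norm(center_vox - locus_a) <= 2.0:
            hits += 1
    return hits / n_reps


# ---------------------------------------------------------------------------
# Monte-Carlo cluster correction


def cluster_fwer(
    n_reps: int = 200,
    n: int = 40,
    n_sims: int = 500,
    shape: tuple[int, int] = (64, 64),
    fwhm_mm: float = 10.0,
    spacing_mm: float = 2.0,
    seed: int = 0,
) -> float:
    """Familywise error of the cluster-corrected group map on null cohorts
    whose sheets share the correction's smoothness."""
    sigma = fwhm_mm / 2.3548 / spacing_mm
    hits = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(_seed(seed + 13, rep))
        sheets = []
        for i in range(n):
            z = clustermap.smooth_unit_noise(rng, shape, sigma)
            sheets.append(MeasureSheet(f"s{i}", z, "thickness", float(z.mean())))
        design = pd.DataFrame(
            {
                "group": np.r_[np.ones(n // 2), np.zeros(n - n // 2)],
                "age": rng.uniform(40, 70, n),
                "sex": rng.choice(["M", "F"], n),
                "scanner": rng.choice(["A", "B"], n),
            }
        )
        stat = clustermap.fit_pointwise_glm(sheets, design)
        stat = clustermap.monte_carlo_cluster_correct(
            stat,
            n_sims=n_sims,
            voxel_p=0.01,
            cluster_p=0.05,
            fwhm_mm=fwhm_mm,
            spacing_mm=spacing_mm,
            seed=_seed(seed + 17, rep),
        )
        hits += bool(stat.clusters)
    return hits / n_reps


# ---------------------------------------------------------------------------
# BY-FDR and ROI inference


def by_fdr_null_rate(
    n_reps: int = 2000, m: int = 20, q: float = 0.05, seed: int = 0
) -> float:
    """Empirical FDR of the BY procedure on fully null independent p-vectors
    (all discoveries are false, so FDP is 1 when anything is rejected)."""
    rng = np.random.default_rng(_seed(seed + 23, 0))
    fdp = 0.0
    for _ in range(n_reps):
        ps = rng.uniform(1e-12, 1.0, m)
        _, reject = stats.by_fdr(ps, q)
        fdp += float(reject.any())
    return fdp / n_reps


def ancova_type1_rate(n_reps: int = 1000, n: int = 90, seed: int = 0) -> float:
    """Rejection rate of covariate-adjusted pairwise contrasts at p < .05
    when the three groups share one distribution."""
    rejections = 0
    total = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(_seed(seed + 29, rep))
        g = rng.choice(["PR", "CR", "HC"], n)
        while min((g == lv).sum() for lv in ("PR", "CR", "HC")) < 3:
            g = rng.choice(["PR", "CR", "HC"], n)
        age = rng.uniform(40, 70, n)
        sex = rng.choice(["M", "F"], n)
        y = 2.5 - 0.003 * (age - 55) + 0.03 * (sex == "M") + rng.normal(0, 0.1, n)
        cov = pd.DataFrame({"age": age, "sex": sex})
        for r in stats.ancova_three_group(y, g, cov):
            rejections += r.raw_p < 0.05
            total += 1
    return rejections / total


def ancova_pr_deficit_recovery(seed: int = 0) -> tuple[float, float]:
    """(estimated PR-HC contrast, true injected deficit) from a cohort where
    only the PR stratum carries a cingulate surface-area deficit."""
    truth = -40.0
    cfg = CohortConfig(
        n_patients=120,
        n_controls=60,
        seed=_seed(seed + 31, 0),
        effect_table=(Effect("PR", "IL_cingulate", "area", truth),),
        slope_table={},
        noise_sd={"thickness": 0.05, "area": 5.0, "gmv": 50.0},
        intercept_sd={"thickness": 0.05, "area": 5.0, "gmv": 50.0},
        make_sheets=False,
    )
    cohort = simulate_cohort(cfg)
    chronic = cohort.chronic_table()
    sub = chronic[(chronic["roi"] == "IL_cingulate")]
    res = {
        r.name: r
        for r in stats.ancova_three_group(
            sub["value"], sub["group"], sub[["age", "sex", "scanner"]]
        )
    }
    return float(res["PR-HC"].estimate), truth


def partial_corr_oracle_error(n_reps: int = 50, seed: int = 0) -> float:
    """Max |difference| between partial_correlation and an independent
    projection-matrix residualization oracle on random confounded data."""
    rng = np.random.default_rng(_seed(seed + 37, 0))
    worst = 0.0
    for _ in range(n_reps):
        n, k = 60, 3
        Z = rng.normal(size=(n, k))
        x = Z @ rng.normal(size=k) + rng.normal(size=n)
        y = Z @ rng.normal(size=k) + rng.normal(size=n)
        r, _, _ = stats.partial_correlation(x, y, Z)
        # oracle: explicit annihilator matrix M = I - Z+(Z+'Z+)^-1 Z+'
        Zi = np.column_stack([np.ones(n), Z])
        M = np.eye(n) - Zi @ np.linalg.inv(Zi.T @ Zi) @ Zi.T
        rx, ry = M @ x, M @ y
        r_oracle = (rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))
        worst = max(worst, abs(r - r_oracle))
    return worst


# ---------------------------------------------------------------------------
# longitudinal LMM


def lmm_slope_coverage(
    n_reps: int = 300, n_subj: int = 40, k: int = 4, seed: int = 0
) -> float:
    """95% CI coverage for the slope over balanced simulated cohorts."""
    times0 = np.array([0.25, 1.0, 3.0, 8.0])[:k]
    beta1 = 0.02
    covered = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(_seed(seed + 41, rep))
        times = np.tile(times0, n_subj)
        subj = np.repeat(np.arange(n_subj), k)
        b = rng.normal(0, 0.05, n_subj)
        y = 2.5 + beta1 * times + b[subj] + rng.normal(0, 0.05, n_subj * k)
        res = lmm.RandomInterceptModel.from_series(times, y, subj).fit()
        lo, hi = res.conf_int()[1]
        covered += lo <= beta1 <= hi
    return covered / n_reps


def pattern4_classification_rate(n_reps: int = 20, seed: int = 0) -> float:
    """Fraction of default-conditions cohorts whose divergent-trajectory ROI
    (cingulate surface area) is labeled pattern 4."""
    correct = 0
    for rep in range(n_reps):
        cfg = CohortConfig(seed=_seed(seed + 43, rep), make_sheets=False)
        cohort = simulate_cohort(cfg)
        fits = [
            lmm.fit_all_groups(sub, roi=roi, measure=measure)
            for (roi, measure), sub in cohort.table.groupby(
                ["roi", "measure"], sort=True
            )
        ]
        lmm.correct_slope_family(fits)
        by_roi = {f.roi: f for f in fits}
        correct += lmm.classify_pattern(by_roi["IL_cingulate"]) == 4
    return correct / n_reps
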