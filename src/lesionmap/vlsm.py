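"""Continuous-outcome voxel-based lesion-symptom mapping (VLSM).

At every voxel damaged in more than a minimum fraction of patients (and with
both lesioned and intact subjects), a GLM relates the binary lesion status to
a chronic ROI measure, adjusting for age, sex, lesion volume and scanner.
Voxel-level p-values are FDR-corrected within each map; surviving voxels are
decomposed into 6-connected clusters, and clusters larger than a minimum
extent are reported with their unweighted centroid and max-|t| peak in
world mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .lesions import LesionMask, incidence_map
from .stats import _design

logger = logging.getLogger(__name__)

SIX_CONNECTED = ndimage.generate_binary_structure(3, 1)


@dataclass
class VlsmCluster:
    voxels: np.ndarray  # (k, 3) voxel indices
    n_voxels: int
    volume_mm3: float
    sign: int
    center_mm: tuple[float, float, float]
    peak_mm: tuple[float, float, float]
    peak_t: float


@dataclass
class VlsmResult:
    roi: str
    measure: str
    tested_mask: np.ndarray
    t_field: np.ndarray
    p_field: np.ndarray
    q_field: np.ndarray
    significant: np.ndarray
    clusters: list[VlsmCluster] = field(default_factory=list)


def build_inclusion_mask(masks: Sequence[LesionMask], fraction: float = 0.10) -> np.ndarray:
    """Voxels damaged in strictly more than ``fraction`` of the patients."""
    imap = incidence_map(masks)
    return imap.counts / imap.n_subjects > fraction


def vlsm_map(
    masks: Sequence[LesionMask],
    outcome: Sequence[float],
    covariates: pd.DataFrame | None = None,
    roi: str = "",
    measure: str = "",
    min_incidence: float = 0.10,
    min_cluster: int = 10,
    q: float = 0.05,
    fdr_method: str = "bh",
) -> VlsmResult:
    """Voxelwise lesion-status GLM against one chronic outcome.

    Uses the Frisch-Waugh-Lovell residualization: outcome and per-voxel
    lesion indicators are residualized on the covariates once, so the t
    statistic for the lesion coefficient of the full model is obtained for
    all voxels in a single vectorized pass.  Voxel p-values are corrected by
    Benjamini-Hochberg (``fdr_method="bh"``, default) or Benjamini-Yekutieli
    (``"by"``); surviving voxels form 6-connected clusters and only clusters
    with strictly more than ``min_cluster`` voxels are reported.
    """
    masks = list(masks)
    y = np.asarray(outcome, dtype=float)
    if len(masks) != y.size:
        raise ValueError("one outcome value per lesion mask is required")
    grid = masks[0].grid
    n = y.size
    Z = _design(covariates, n)
    k = Z.shape[1]
    if n < k + 4:
        raise ValueError(f"need at least rank(design)+3 subjects (n={n}, k={k})")

    include = build_inclusion_mask(masks, min_incidence)
    stack = np.stack([m.voxels for m in masks]).reshape(n, -1).astype(float)
    flat_include = include.ravel()
    # both lesioned and intact subjects required at a tested voxel
    col_sums = stack.sum(axis=0)
    constant = (col_sums == 0) | (col_sums == n)
    n_dropped = int(np.sum(flat_include & constant))
    if n_dropped:
        logger.warning("excluding %d voxels with constant lesion status", n_dropped)
    tested = flat_include & ~constant
    tested_idx = np.where(tested)[0]

    t_field = np.zeros(grid.shape).ravel()
    p_field = np.ones(grid.shape).ravel()
    q_field = np.ones(grid.shape).ravel()
    significant = np.zeros(grid.shape, dtype=bool).ravel()

    if tested_idx.size:
        V = stack[:, tested_idx]
        # residualize outcome and lesion indicators on covariates (FWL)
        coef_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
        ry = y - Z @ coef_y
        coef_v, *_ = np.linalg.lstsq(Z, V, rcond=None)
        rv = V - Z @ coef_v
        df = n - k - 1
        vss = np.einsum("ij,ij->j", rv, rv)
        good = vss > 1e-12
        beta = np.zeros(tested_idx.size)
        tvals = np.zeros(tested_idx.size)
        beta[good] = (rv[:, good].T @ ry) / vss[good]
        rss = ry @ ry - beta**2 * vss
        sigma2 = np.maximum(rss / df, 1e-300)
        tvals[good] = beta[good] / np.sqrt(sigma2[good] / vss[good])
        pvals = 2.0 * sps.t.sf(np.abs(tvals), df)
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
        method = {"bh": "fdr_bh", "by": "fdr_by"}[fdr_method]
        rej, qvals, *_ = multipletests(pvals, alpha=q, method=method)
        t_field[tested_idx] = tvals
        p_field[tested_idx] = pvals
        q_field[tested_idx] = qvals
        significant[tested_idx] = rej

    t_field = t_field.reshape(grid.shape)
    p_field = p_field.reshape(grid.shape)
    q_field = q_field.reshape(grid.shape)
    significant = significant.reshape(grid.shape)

    clusters: list[VlsmCluster] = []
    for sign in (1, -1):
        mask3d = significant & (np.sign(t_field) == sign)
        labels, n_lab = ndimage.label(mask3d, structure=SIX_CONNECTED)
        for lab in range(1, n_lab + 1):
            vox = np.argwhere(labels == lab)
            if vox.shape[0] <= min_cluster:
                continue
            tv = np.abs(t_field[tuple(vox.T)])
            peak_vox = vox[np.argmax(tv)]
            center_mm = tuple(np.round(grid.world_coords(vox).mean(axis=0), 2))
            peak_mm = tuple(np.round(grid.world_coords(peak_vox)[0], 2))
            clusters.append(
                VlsmCluster(
                    voxels=vox,
                    n_voxels=int(vox.shape[0]),
                    volume_mm3=float(vox.shape[0] * grid.voxel_volume_mm3),
                    sign=sign,
                    center_mm=center_mm,
                    peak_mm=peak_mm,
                    peak_t=float(t_field[tuple(peak_vox)]),
                )
            )
    return VlsmResult(
        roi=roi,
        measure=measure,
        tested_mask=tested.reshape(grid.shape),
        t_field=t_field,
        p_field=p_field,
        q_field=q_field,
        significant=significant,
        clusters=clusters,
    )


def vlsm_batch(
    masks: Sequence[LesionMask],
    chronic: pd.DataFrame,
    rois: list[tuple[str, str]],
    covariate_cols: tuple[str, ...] = ("age", "sex", "scanner", "lesion_volume"),
    **kwargs,
) -> list[VlsmResult]:
    """One independent VLSM map per ROI-measure; FDR within each map."""
    masks = list(masks)
    sids = [m.subject_id for m in masks]
    out = []
    for roi, measure in rois:
        sub = chronic[(chronic["roi"] == roi) & (chronic["measure"] == measure)]
        sub = sub.set_index("subject_id").loc[sids]
        out.append(
            vlsm_map(
                masks,
                sub["value"].to_numpy(),
                sub[list(covariate_cols)].reset_index(drop=True),
                roi=roi,
                measure=measure,
                **kwargs,
            )
        )
    return out


def vlsm_cluster_table(results: Sequence[VlsmResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for cl in res.clusters:
            rows.append(
                {
                    "roi": res.roi,
                    "measure": res.measure,
                    "sign": cl.sign,
                    "n_voxels": cl.n_voxels,
                    "volume_mm3": cl.volume_mm3,
                    "center_x": cl.center_mm[0],
                    "center_y": cl.center_mm[1],
                    "center_z": cl.center_mm[2],
                    "peak_x": cl.peak_mm[0],
                    "peak_y": cl.peak_mm[1],
                    "peak_z": cl.peak_mm[2],
                    "peak_t": cl.peak_t,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "roi", "measure", "sign", "n_voxels", "volume_mm3",
            "center_x", "center_y", "center_z", "peak_x", "peak_y", "peak_z", "peak_t",
        ],
    )
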