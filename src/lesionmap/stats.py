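"""ROI-level inference: ANCOVA contrasts, Cohen's d, partial correlation,
CST-impairment correlations, and the Benjamini-Yekutieli FDR procedure.

All tests are two-sided.  Scanner enters models as a dummy-coded categorical
with the lexicographically first level as reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cst import SUBSET_NAMES


# ---------------------------------------------------------------------------
# Benjamini-Yekutieli FDR


def by_fdr(raw_ps, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Yekutieli step-up FDR, valid under arbitrary dependence.

    With m p-values sorted ascending and c(m) = sum_{j<=m} 1/j, rejects the
    largest i with p_(i) <= i*q/(m*c(m)) and all smaller.  Returns
    (corrected_ps, reject_flags) in the input order; corrected p-values are
    min(1, p_(i)*m*c(m)/i) with monotonicity enforced from the largest down.
    """
    p = np.asarray(raw_ps, dtype=float)
    if p.ndim != 1:
        raise ValueError("raw_ps must be one-dimensional")
    m = p.size
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    adj = np.minimum(1.0, p_sorted * m * c_m / ranks)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    passed = p_sorted <= ranks * q / (m * c_m)
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:k] = True
    corrected = np.empty(m)
    reject = np.empty(m, dtype=bool)
    corrected[order] = adj
    reject[order] = reject_sorted
    return corrected, reject


# ---------------------------------------------------------------------------
# effect size


def cohens_d(values_a, values_b) -> float:
    """Cohen's d: (mean_a - mean_b) / pooled SD with (n-1)-weighted pooling."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


# ---------------------------------------------------------------------------
# partial correlation


def _design(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    """Covariates -> numeric design with intercept; categoricals dummy-coded."""
    if covariates is None:
        return np.ones((n, 1))
    if isinstance(covariates, pd.DataFrame):
        num = pd.get_dummies(covariates, drop_first=True, dtype=float)
        z = num.to_numpy(dtype=float)
    else:
        z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if z.shape[0] != n:
            z = z.T
    return np.column_stack([np.ones(n), z])


def partial_correlation(
    x, y, covariates: pd.DataFrame | np.ndarray | None = None
) -> tuple[float, float, int]:
    """Partial Pearson correlation of x and y given covariates.

    Residualizes both variables on the covariates (plus intercept) by OLS and
    correlates the residuals; p from a t reference with df = n - 2 - k where
    k is the number of covariate columns (after dummy coding).  With no
    covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    z = _design(covariates, n)
    k = z.shape[1] - 1
    if n <= k + 3:
        raise ValueError(f"need n > k+3 (n={n}, k={k})")
    beta_x, *_ = np.linalg.lstsq(z, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(z, y, rcond=None)
    rx = x - z @ beta_x
    ry = y - z @ beta_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("constant residuals after covariate adjustment")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_ = np.clip(r, -0.9999999999, 0.9999999999)
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p, df


# ---------------------------------------------------------------------------
# ANCOVA


@dataclass
class TestResult:
    """One contrast or correlation with its (corrected) p-values."""

    name: str
    estimate: float
    raw_p: float
    df: int
    effect_size_d: float | None = None
    corrected_p: float | None = None
    reject: bool | None = None


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify columns involved in the collinearity
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == r:
                bad.append(names[j])
        raise ValueError(f"design is rank-deficient; collinear columns: {bad}")


def ancova_three_group(
    values,
    group,
    covariates: pd.DataFrame | None = None,
    adjusted_d: bool = True,
) -> list[TestResult]:
    """Covariate-adjusted pairwise group contrasts among PR, CR and HC.

    Fits one OLS model value ~ group dummies + covariates and tests the three
    pairwise contrasts PR-CR, PR-HC, CR-HC (two-sided t, unadjusted p).
    Cohen's d is computed on covariate-adjusted values (residuals plus group
    means) by default so that d matches the contrast; set
    ``adjusted_d=False`` for raw-value d.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group)
    levels = ["PR", "CR", "HC"]
    counts = {lv: int(np.sum(g == lv)) for lv in levels}
    if any(c < 3 for c in counts.values()):
        raise ValueError(f"each group needs >= 3 subjects, got {counts}")
    n = y.size
    z = _design(covariates, n)
    d_pr = (g == "PR").astype(float)
    d_cr = (g == "CR").astype(float)
    X = np.column_stack([d_pr, d_cr, z])  # HC is the reference level
    names = ["PR", "CR", "intercept"] + [f"cov{i}" for i in range(z.shape[1] - 1)]
    _check_full_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)

    # adjusted values for Cohen's d: remove covariate (not group) effects
    if adjusted_d:
        y_adj = y - z @ beta[2:]
    else:
        y_adj = y

    contrasts = {
        "PR-CR": np.array([1.0, -1.0] + [0.0] * z.shape[1]),
        "PR-HC": np.array([1.0, 0.0] + [0.0] * z.shape[1]),
        "CR-HC": np.array([0.0, 1.0] + [0.0] * z.shape[1]),
    }
    pair_groups = {"PR-CR": ("PR", "CR"), "PR-HC": ("PR", "HC"), "CR-HC": ("CR", "HC")}
    out = []
    for name, cvec in contrasts.items():
        est = float(cvec @ beta)
        se = float(np.sqrt(sigma2 * cvec @ xtx_inv @ cvec))
        t = est / se
        p = float(2.0 * sps.t.sf(abs(t), dof))
        ga, gb = pair_groups[name]
        d = cohens_d(y_adj[g == ga], y_adj[g == gb])
        out.append(TestResult(name=name, estimate=est, raw_p=p, df=dof, effect_size_d=d))
    return out


# ---------------------------------------------------------------------------
# correlations with motor outcome and CST impairment


def wefm_partial_correlations(
    chronic: pd.DataFrame, q: float = 0.05
) -> pd.DataFrame:
    """Partial correlation of each ROI measure with WE_FM in patients.

    Controls for age, sex and scanner; the family of ROI-measure tests is
    BY-FDR corrected together.
    """
    pat = chronic[chronic["group"].isin(["PR", "CR"])]
    rows = []
    for (roi, measure), sub in pat.groupby(["roi", "measure"], sort=True):
        cov = sub[["age", "sex", "scanner"]]
        pr, p, df = partial_correlation(sub["value"], sub["wefm"], cov)
        rows.append(
            {"roi": roi, "measure": measure, "pr": pr, "raw_p": p, "df": df}
        )
    res = pd.DataFrame(rows)
    if len(res):
        corrected, reject = by_fdr(res["raw_p"].to_numpy(), q)
        res["corrected_p"] = corrected
        res["reject"] = reject
    return res


def cst_correlations(
    chronic: pd.DataFrame,
    rois: list[tuple[str, str]] | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Partial correlation of each CST subset's impairment with ROI measures.

    Patients only.  For subset s, covariates are age, sex, scanner and the
    impairment percentages of the other three subsets.  The whole family
    (ROIs x 4 subsets) is BY-FDR corrected together.  Subsets with constant
    impairment are reported as not testable (NaN) rather than raising.
    """
    pat = chronic[chronic["group"].isin(["PR", "CR"])]
    if pat.empty:
        raise ValueError("cst_correlations requires patients")
    if rois is None:
        rois = sorted({(r, m) for r, m in zip(pat["roi"], pat["measure"])})
    rows = []
    for roi, measure in rois:
        sub = pat[(pat["roi"] == roi) & (pat["measure"] == measure)]
        for s in SUBSET_NAMES:
            others = [f"imp_{o}" for o in SUBSET_NAMES if o != s]
            x = sub[f"imp_{s}"].to_numpy(dtype=float)
            if np.allclose(x, x[0]):
                rows.append(
                    {"roi": roi, "measure": measure, "subset": s, "pr": np.nan,
                     "raw_p": np.nan, "df": 0, "testable": False}
                )
                continue
            cov = pd.concat(
                [sub[["age", "sex", "scanner"]], sub[others]], axis=1
            )
            pr, p, df = partial_correlation(x, sub["value"].to_numpy(), cov)
            rows.append(
                {"roi": roi, "measure": measure, "subset": s, "pr": pr,
                 "raw_p": p, "df": df, "testable": True}
            )
    res = pd.DataFrame(rows)
    testable = res["testable"].to_numpy()
    res["corrected_p"] = np.nan
    res["reject"] = False
    if testable.any():
        corrected, reject = by_fdr(res.loc[testable, "raw_p"].to_numpy(), q)
        res.loc[testable, "corrected_p"] = corrected
        res.loc[testable, "reject"] = reject
    return res


def roi_ancova_table(
    chronic: pd.DataFrame, covariate_cols: tuple[str, ...] = ("age", "sex", "scanner")
) -> pd.DataFrame:
    """Three-group ANCOVA (PR, CR, HC) for every ROI-measure in a chronic table."""
    rows = []
    for (roi, measure), sub in chronic.groupby(["roi", "measure"], sort=True):
        cov = sub[list(covariate_cols)]
        for res in ancova_three_group(sub["value"], sub["group"], cov):
            rows.append(
                {"roi": roi, "measure": measure, "contrast": res.name,
                 "estimate": res.estimate, "d": res.effect_size_d,
                 "raw_p": res.raw_p, "df": res.df}
            )
    return pd.DataFrame(rows)
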