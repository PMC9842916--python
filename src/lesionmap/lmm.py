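"""Random-intercept linear mixed models for longitudinal cortical trajectories.

The model for subject i at visit j is

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma2_b),  e_ij ~ N(0, sigma2_e)

with a common slope per group (fixed effect) and subject-specific intercepts
(random effect) absorbing the within-subject correlation of repeated
measurements.  Missing visits are handled by likelihood: each subject
contributes whatever observations it has.

Estimation is restricted maximum likelihood (REML), profiled down to a 1D
search over the variance ratio lambda = sigma2_b / sigma2_e on the log scale
(the exchangeable covariance of the random-intercept model makes all
per-subject inverses closed-form).  The boundary lambda = 0 (no subject
heterogeneity, plain OLS) is always evaluated and kept when it wins.

Per-group fits are combined into pairwise slope contrasts via a Wald
statistic (beta1_a - beta1_b) / sqrt(SE_a^2 + SE_b^2) referred to the normal
distribution, and slope / slope-difference families are Benjamini-Yekutieli
corrected across ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .stats import by_fdr

GROUPS = ("PR", "CR", "HC")
PAIRS = (("PR", "CR"), ("PR", "HC"), ("CR", "HC"))


class RandomInterceptModel:
    """Random-intercept LMM: endog ~ exog fixed effects + per-group intercept.

    Parameters
    ----------
    endog : (n,) response values.
    exog : (n, p) fixed-effects design; default columns are an intercept and
        the time covariate when constructed via :meth:`from_series`.
    groups : (n,) subject labels defining the random-intercept grouping.
    """

    def __init__(self, endog, exog, groups):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.size:
            self.exog = self.exog.T
        self.groups = np.asarray(groups)
        if self.groups.size != self.endog.size:
            raise ValueError("groups must align with endog")
        self.n, self.p = self.exog.shape
        if np.linalg.matrix_rank(self.exog) < self.p:
            raise ValueError("fixed-effects design is rank-deficient")
        uniq, idx = np.unique(self.groups, return_inverse=True)
        self.subject_ids = uniq
        self._index = idx
        self.n_subjects = uniq.size
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        # per-subject sufficient statistics
        self._blocks = [np.where(idx == g)[0] for g in range(self.n_subjects)]
        self._ni = np.array([b.size for b in self._blocks])

    @classmethod
    def from_series(cls, times, values, subjects) -> "RandomInterceptModel":
        """Intercept + slope model for longitudinal series."""
        t = np.asarray(times, dtype=float)
        X = np.column_stack([np.ones(t.size), t])
        return cls(values, X, subjects)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        value_col: str = "value",
        time_col: str = "timepoint_months",
        subject_col: str = "subject_id",
    ) -> "RandomInterceptModel":
        return cls.from_series(data[time_col], data[value_col], data[subject_col])

    # -- REML machinery ----------------------------------------------------

    def _gls_pieces(self, lam: float):
        """GLS beta and REML profile pieces at variance ratio lam."""
        X, y = self.exog, self.endog
        xtx = np.zeros((self.p, self.p))
        xty = np.zeros(self.p)
        yty = 0.0
        logdet_h = 0.0
        for b, ni in zip(self._blocks, self._ni):
            Xi, yi = X[b], y[b]
            sx = Xi.sum(axis=0)
            sy = yi.sum()
            w = lam / (1.0 + lam * ni)
            xtx += Xi.T @ Xi - w * np.outer(sx, sx)
            xty += Xi.T @ yi - w * sx * sy
            yty += yi @ yi - w * sy * sy
            logdet_h += np.log1p(lam * ni)
        beta = np.linalg.solve(xtx, xty)
        rss = float(yty - 2 * beta @ xty + beta @ xtx @ beta)
        rss = max(rss, 0.0)
        sign, logdet_xhx = np.linalg.slogdet(xtx)
        return beta, xtx, rss, logdet_h, logdet_xhx

    def _criterion(self, lam: float) -> float:
        """Negative profiled REML criterion (up to constants)."""
        _, _, rss, logdet_h, logdet_xhx = self._gls_pieces(lam)
        dfr = self.n - self.p
        if rss <= 0:
            return -np.inf
        return dfr * np.log(rss / dfr) + logdet_h + logdet_xhx

    def reml_loglike(self, sigma2_b: float, sigma2_e: float) -> float:
        """Restricted log-likelihood at the given variance components."""
        if sigma2_e <= 0:
            return -np.inf
        lam = sigma2_b / sigma2_e
        beta, xtx, rss, logdet_h, logdet_xhx = self._gls_pieces(lam)
        dfr = self.n - self.p
        return -0.5 * (
            dfr * np.log(2 * np.pi * sigma2_e)
            + logdet_h
            + logdet_xhx
            + rss / sigma2_e
        )

    def fit(self, tol: float = 1e-10, max_iter: int = 500) -> "RandomInterceptResults":
        # degenerate: exact fit (noiseless data)
        beta0, xtx0, rss0, _, _ = self._gls_pieces(0.0)
        if rss0 < 1e-12 * max(1.0, float(self.endog @ self.endog)):
            return RandomInterceptResults(
                model=self, params=beta0, cov_params=np.zeros((self.p, self.p)),
                sigma2_b=0.0, sigma2_e=0.0, loglike=np.inf, converged=True,
            )
        res = optimize.minimize_scalar(
            lambda th: self._criterion(np.exp(th)),
            bounds=(-25.0, 15.0),
            method="bounded",
            options={"xatol": tol, "maxiter": max_iter},
        )
        lam = float(np.exp(res.x))
        # boundary check: sigma2_b pinned at zero when OLS wins
        if self._criterion(0.0) <= res.fun:
            lam = 0.0
        beta, xtx, rss, _, _ = self._gls_pieces(lam)
        dfr = self.n - self.p
        sigma2_e = rss / dfr
        sigma2_b = lam * sigma2_e
        cov = sigma2_e * np.linalg.inv(xtx)
        ll = self.reml_loglike(sigma2_b, sigma2_e)
        return RandomInterceptResults(
            model=self, params=beta, cov_params=cov,
            sigma2_b=sigma2_b, sigma2_e=sigma2_e, loglike=ll,
            converged=bool(res.success or lam == 0.0),
        )


@dataclass
class RandomInterceptResults:
    """REML fit of a random-intercept LMM."""

    model: RandomInterceptModel
    params: np.ndarray
    cov_params: np.ndarray
    sigma2_b: float
    sigma2_e: float
    loglike: float
    converged: bool

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def pvalues(self) -> np.ndarray:
        """Wald z test per fixed-effect coefficient."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.bse > 0, self.params / self.bse, np.inf)
        return 2.0 * sps.norm.sf(np.abs(z))

    @property
    def icc(self) -> float:
        tot = self.sigma2_b + self.sigma2_e
        return self.sigma2_b / tot if tot > 0 else 0.0

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = sps.norm.isf(alpha / 2.0)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def summary(self) -> str:
        names = [f"x{i}" for i in range(self.params.size)]
        if self.params.size == 2:
            names = ["intercept", "slope"]
        lines = [
            "Random-intercept LMM (REML)",
            f"  n obs = {self.model.n}, n subjects = {self.model.n_subjects}",
            f"  sigma2_b = {self.sigma2_b:.6g}, sigma2_e = {self.sigma2_e:.6g}"
            f" (ICC = {self.icc:.3f})",
            f"  REML loglik = {self.loglike:.4f}, converged = {self.converged}",
            f"  {'coef':<10}{'est':>12}{'se':>12}{'z-p':>12}",
        ]
        for nm, est, se, p in zip(names, self.params, self.bse, self.pvalues):
            lines.append(f"  {nm:<10}{est:>12.5f}{se:>12.5f}{p:>12.3g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# per-ROI group fits and slope comparisons


@dataclass
class LmmFit:
    """Per-ROI trajectory comparison across PR, CR and HC."""

    roi: str
    measure: str
    group_fits: dict[str, RandomInterceptResults]
    slopes: dict[str, float] = field(default_factory=dict)
    slope_se: dict[str, float] = field(default_factory=dict)
    slope_p: dict[str, float] = field(default_factory=dict)
    pair_p: dict[str, float] = field(default_factory=dict)
    slope_p_corrected: dict[str, float] = field(default_factory=dict)
    pair_p_corrected: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for g, res in self.group_fits.items():
            self.slopes[g] = float(res.params[1])
            self.slope_se[g] = float(res.bse[1])
            self.slope_p[g] = float(res.pvalues[1])
        for a, b in PAIRS:
            if a in self.group_fits and b in self.group_fits:
                se = np.hypot(self.slope_se[a], self.slope_se[b])
                z = (self.slopes[a] - self.slopes[b]) / se if se > 0 else np.inf
                self.pair_p[f"{a}vs{b}"] = float(2.0 * sps.norm.sf(abs(z)))


def fit_all_groups(
    roi_data: pd.DataFrame,
    roi: str = "",
    measure: str = "",
    min_obs_per_subject: int = 2,
) -> LmmFit:
    """Fit the random-intercept model separately in PR, CR and HC.

    ``roi_data`` holds one ROI's long series (subject_id, group,
    timepoint_months, value).  Subjects with fewer than
    ``min_obs_per_subject`` observations are dropped.
    """
    fits = {}
    for g in GROUPS:
        sub = roi_data[roi_data["group"] == g]
        counts = sub.groupby("subject_id").size()
        keep = counts[counts >= min_obs_per_subject].index
        sub = sub[sub["subject_id"].isin(keep)]
        if sub["subject_id"].nunique() < 3:
            continue
        fits[g] = RandomInterceptModel.from_dataframe(sub).fit()
    if not fits:
        raise ValueError(f"no group with enough subjects for roi {roi!r}")
    return LmmFit(roi=roi, measure=measure, group_fits=fits)


def correct_slope_family(fits: list[LmmFit], q: float = 0.05) -> list[LmmFit]:
    """BY-FDR across ROIs: slope family (ROI x group) and pairwise family
    (ROI x pair) corrected separately, mirroring raw/corrected report pairs."""
    if not fits:
        raise ValueError("empty fit family")
    slope_keys = [(i, g) for i, f in enumerate(fits) for g in f.slope_p]
    pair_keys = [(i, pr) for i, f in enumerate(fits) for pr in f.pair_p]
    if slope_keys:
        cp, _ = by_fdr(np.array([fits[i].slope_p[g] for i, g in slope_keys]), q)
        for (i, g), c in zip(slope_keys, cp):
            fits[i].slope_p_corrected[g] = float(c)
    if pair_keys:
        cp, _ = by_fdr(np.array([fits[i].pair_p[pr] for i, pr in pair_keys]), q)
        for (i, pr), c in zip(pair_keys, cp):
            fits[i].pair_p_corrected[pr] = float(c)
    return fits


def classify_pattern(fit: LmmFit, q: float = 0.05) -> int | None:
    """Label the ROI's longitudinal evolution pattern.

    1: decline in both patient groups with a significant PR decrease;
    2: increase in both patient groups, both significant;
    3: significant increase only in CR;
    4: divergent trajectories (significant PR-CR slope difference with
    reliably opposite slope signs).  Divergence requires both slope signs to
    be established (raw Wald p <= .05 in each patient group): a flat-PR ROI
    whose only real change is a CR increase can show a significant PR-CR
    contrast with a noise-sign PR estimate, and that is pattern 3, not 4.
    Conversely, a genuinely divergent ROI stays pattern 4 even when one
    slope's family-corrected p slips past the threshold.  None when no rule
    applies.  Group/pair significance uses corrected p-values when
    available, raw otherwise.
    """
    sp = fit.slope_p_corrected or fit.slope_p
    pp = fit.pair_p_corrected or fit.pair_p
    s_pr, s_cr = fit.slopes.get("PR"), fit.slopes.get("CR")
    if s_pr is None or s_cr is None:
        return None
    pr_sig = sp.get("PR", 1.0) <= q
    cr_sig = sp.get("CR", 1.0) <= q
    prcr_sig = pp.get("PRvsCR", 1.0) <= q
    signs_reliable = fit.slope_p.get("PR", 1.0) <= 0.05 and fit.slope_p.get("CR", 1.0) <= 0.05
    if (
        prcr_sig
        and signs_reliable
        and np.sign(s_pr) != np.sign(s_cr)
        and s_pr != 0
        and s_cr != 0
    ):
        return 4
    if s_pr < 0 and s_cr < 0 and pr_sig:
        return 1
    if s_pr > 0 and s_cr > 0 and pr_sig and cr_sig:
        return 2
    if cr_sig and s_cr > 0 and not pr_sig:
        return 3
    return None


def lmm_table(fits: list[LmmFit], q: float = 0.05) -> pd.DataFrame:
    """Tidy per-ROI report: group slopes, pairwise contrasts, patterns."""
    rows = []
    for f in fits:
        row: dict = {"roi": f.roi, "measure": f.measure}
        for g in GROUPS:
            if g in f.slopes:
                row[f"slope_{g}"] = f.slopes[g]
                row[f"p_{g}"] = f.slope_p[g]
                row[f"p_{g}_corr"] = f.slope_p_corrected.get(g)
        for pr in ("PRvsCR", "PRvsHC", "CRvsHC"):
            if pr in f.pair_p:
                row[f"p_{pr}"] = f.pair_p[pr]
                row[f"p_{pr}_corr"] = f.pair_p_corrected.get(pr)
        row["pattern"] = classify_pattern(f, q)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_trajectories(roi_data: pd.DataFrame, fit: LmmFit | None = None, ax=None):
    """Spaghetti plot of per-subject series with fitted group lines."""
    import matplotlib.pyplot as plt

    colors = {"PR": "tab:red", "CR": "tab:blue", "HC": "tab:gray"}
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for (sid, g), sub in roi_data.groupby(["subject_id", "group"]):
        sub = sub.sort_values("timepoint_months")
        ax.plot(
            sub["timepoint_months"], sub["value"],
            color=colors.get(str(g), "k"), alpha=0.2, lw=0.6,
        )
    if fit is not None:
        ts = np.linspace(
            roi_data["timepoint_months"].min(), roi_data["timepoint_months"].max(), 20
        )
        for g, res in fit.group_fits.items():
            ax.plot(ts, res.params[0] + res.params[1] * ts, color=colors[g], lw=2,
                    label=f"{g} slope={res.params[1]:.3g}")
        ax.legend(fontsize=8)
    ax.set_xlabel("months since stroke")
    ax.set_ylabel("measure")
    return ax


def fit_interaction_model(roi_data: pd.DataFrame):
    """Alternative single-model formulation with group x time interaction.

    Uses statsmodels MixedLM (REML) on the pooled data; provided for
    comparison with the separate-models formulation.
    """
    import statsmodels.formula.api as smf

    df = roi_data.copy()
    df["group"] = pd.Categorical(df["group"], categories=list(GROUPS))
    md = smf.mixedlm(
        "value ~ timepoint_months * group", df, groups=df["subject_id"]
    )
    return md.fit(reml=True)
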