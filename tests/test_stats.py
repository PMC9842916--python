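"""ROI-level inference: BY-FDR, Cohen's d, partial correlation, ANCOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from lesionmap import (
    CohortConfig,
    Effect,
    ancova_three_group,
    by_fdr,
    cohens_d,
    cst_correlations,
    partial_correlation,
    simulate_cohort,
)


def oracle_by_rejections(ps: np.ndarray, q: float) -> np.ndarray:
    """Brute-force BY step-up: try every cutoff k explicitly."""
    m = len(ps)
    c_m = sum(1.0 / j for j in range(1, m + 1))
    order = np.argsort(ps, kind="stable")
    k_best = 0
    for k in range(1, m + 1):
        if ps[order[k - 1]] <= k * q / (m * c_m):
            k_best = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_best]] = True
    return reject


class TestByFdr:
    def test_single_p_reduces_to_raw_threshold(self):
        corrected, reject = by_fdr([0.04], q=0.05)
        assert reject[0]
        assert corrected[0] == pytest.approx(0.04)
        assert not by_fdr([0.06], q=0.05)[1][0]

    def test_worked_four_p_case(self):
        # c(4) = 25/12; step-up thresholds i*q/(m*c) = 0.006*i
        ps = [0.001, 0.01, 0.02, 0.2]
        corrected, reject = by_fdr(ps, q=0.05)
        assert list(reject) == [True, True, False, False]
        assert np.all(np.diff(np.sort(corrected)) >= -1e-15)

    def test_matches_bruteforce_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 25))
            ps = rng.uniform(1e-6, 1.0, m)
            if rng.random() < 0.3:  # inject some small p-values
                ps[: max(1, m // 3)] *= 1e-3
            _, reject = by_fdr(ps, q=0.05)
            assert np.array_equal(reject, oracle_by_rejections(ps, 0.05))

    def test_corrected_ps_match_statsmodels(self, rng):
        ps = rng.uniform(1e-5, 1, 40)
        corrected, reject = by_fdr(ps, q=0.05)
        sm_reject, sm_corr, *_ = multipletests(ps, alpha=0.05, method="fdr_by")
        assert np.allclose(corrected, sm_corr)
        assert np.array_equal(reject, sm_reject)

    def test_by_rejects_subset_of_bh(self, rng):
        for _ in range(50):
            ps = rng.uniform(1e-6, 1, 30)
            ps[:5] *= 1e-2
            _, by_rej = by_fdr(ps, q=0.05)
            bh_rej, *_ = multipletests(ps, alpha=0.05, method="fdr_bh")
            assert np.all(~by_rej | bh_rej)

    def test_raw_p_never_exceeds_corrected(self, rng):
        ps = rng.uniform(1e-4, 1, 25)
        corrected, _ = by_fdr(ps)
        assert np.all(corrected >= ps - 1e-15)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_properties_hold_for_arbitrary_p_vectors(self, ps):
        """Step-up output invariants: corrected >= raw, rejections match the
        brute-force oracle, and BY never rejects more than BH."""
        ps = np.asarray(ps)
        corrected, reject = by_fdr(ps, q=0.05)
        assert np.all(corrected >= ps - 1e-15)
        assert np.all(corrected <= 1.0)
        assert np.array_equal(reject, oracle_by_rejections(ps, 0.05))
        bh_rej, *_ = multipletests(ps, alpha=0.05, method="fdr_bh")
        assert np.all(~reject | bh_rej)

    def test_empty_and_invalid_inputs(self):
        corrected, reject = by_fdr([])
        assert corrected.size == 0 and reject.size == 0
        with pytest.raises(ValueError):
            by_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            by_fdr([1.5])


class TestCohensD:
    def test_closed_forms(self, rng):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0
        a = rng.normal(1, 1, 2000)
        b = rng.normal(0, 1, 2000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.1)

    def test_matches_pooled_formula(self, rng):
        a, b = rng.normal(0, 2, 13), rng.normal(1, 3, 7)
        pooled = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        assert cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestPartialCorrelation:
    def test_no_covariates_is_pearson(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, p, df = partial_correlation(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
        assert df == 48

    def test_noise_free_limit_is_one(self, rng):
        z = rng.normal(size=60)
        x = rng.normal(size=60)
        y = x + 3.0 * z
        r, p, _ = partial_correlation(x, y, z)
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_matches_recursive_formula_single_covariate(self, rng):
        x, y, z = rng.normal(size=(3, 80))
        y = y + 0.5 * z
        x = x + 0.7 * z
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        r, _, df = partial_correlation(x, y, z)
        assert r == pytest.approx(expected, abs=1e-10)
        assert df == 77

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=["x", "y", "a", "b"])
        out = pingouin.partial_corr(df, x="x", y="y", covar=["a", "b"])
        r, p, _ = partial_correlation(df["x"], df["y"], df[["a", "b"]])
        assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(out["p_val"].iloc[0]), abs=1e-8)

    def test_categorical_covariates_dummy_coded(self, rng):
        x, y = rng.normal(size=(2, 40))
        cov = pd.DataFrame({"scanner": rng.choice(["A", "B", "C"], 40)})
        r, p, df = partial_correlation(x, y, cov)
        assert df == 40 - 2 - 2

    def test_degenerate_inputs_rejected(self, rng):
        x = rng.normal(size=5)
        with pytest.raises(ValueError, match="n >"):
            partial_correlation(x, x, np.ones((5, 3)) * rng.normal(size=(5, 3)))
        z = rng.normal(size=30)
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(2.0 * z, rng.normal(size=30), z)


class TestAncova:
    @staticmethod
    def _make(rng, n=120, pr_shift=0.0):
        g = rng.choice(["PR", "CR", "HC"], n)
        age = rng.uniform(40, 70, n)
        sex = rng.choice(["M", "F"], n)
        y = 2.5 - 0.003 * (age - 55) + 0.03 * (sex == "M") + rng.normal(0, 0.1, n)
        y = y + pr_shift * (g == "PR")
        cov = pd.DataFrame({"age": age, "sex": sex})
        return y, g, cov

    def test_null_contrasts_near_zero(self, rng):
        y, g, cov = self._make(rng, n=600)
        res = ancova_three_group(y, g, cov)
        for r in res:
            assert abs(r.estimate) < 0.05

    def test_pr_only_deficit_recovered(self, rng):
        y, g, cov = self._make(rng, n=400, pr_shift=-0.3)
        res = {r.name: r for r in ancova_three_group(y, g, cov)}
        assert res["PR-HC"].estimate == pytest.approx(-0.3, abs=0.05)
        assert abs(res["CR-HC"].estimate) < 0.05
        assert res["PR-HC"].raw_p < 1e-6
        assert res["PR-HC"].effect_size_d < -1.0

    def test_permutation_invariance(self, rng):
        y, g, cov = self._make(rng)
        perm = rng.permutation(len(y))
        a = ancova_three_group(y, g, cov)
        b = ancova_three_group(y[perm], g[perm], cov.iloc[perm].reset_index(drop=True))
        for ra, rb in zip(a, b):
            assert ra.estimate == pytest.approx(rb.estimate, abs=1e-10)
            assert ra.raw_p == pytest.approx(rb.raw_p, abs=1e-10)

    def test_collinear_design_names_columns(self, rng):
        y, g, _ = self._make(rng, n=60)
        cov = pd.DataFrame({"a": np.arange(60.0), "b": 2.0 * np.arange(60.0)})
        with pytest.raises(ValueError, match="collinear"):
            ancova_three_group(y, g, cov)

    def test_small_group_rejected(self, rng):
        y = rng.normal(size=10)
        g = np.array(["PR"] * 2 + ["CR"] * 4 + ["HC"] * 4)
        with pytest.raises(ValueError, match=">= 3"):
            ancova_three_group(y, g)

    def test_raw_and_adjusted_d_both_available(self, rng):
        y, g, cov = self._make(rng, n=300, pr_shift=-0.3)
        d_adj = {r.name: r.effect_size_d for r in ancova_three_group(y, g, cov)}
        d_raw = {
            r.name: r.effect_size_d
            for r in ancova_three_group(y, g, cov, adjusted_d=False)
        }
        assert d_adj["PR-HC"] != d_raw["PR-HC"]


class TestCstCorrelations:
    def test_s1_only_coupling_recovered(self, grid, atlas):
        """ROI deficit injected only via S1 impairment: the S1 partial
        correlation is the strongest and survives BY-FDR; the others do not."""
        cfg = CohortConfig(
            n_patients=90,
            n_controls=5,
            seed=77,
            effect_table=(Effect("S1", "IL_postcentral", "thickness", -1.0),),
            slope_table={},
            noise_sd={"thickness": 0.02, "area": 20.0, "gmv": 50.0},
            intercept_sd={"thickness": 0.02, "area": 20.0, "gmv": 50.0},
            make_sheets=False,
        )
        cohort = simulate_cohort(cfg, grid, atlas)
        res = cst_correlations(
            cohort.chronic_table(), rois=[("IL_postcentral", "thickness")]
        )
        res = res.set_index("subset")
        assert res.loc["S1", "reject"]
        assert res.loc["S1", "pr"] < -0.5
        for s in ("M1", "PMC", "SMA"):
            assert not res.loc[s, "reject"]

    def test_controls_only_rejected(self, small_cohort):
        chronic = small_cohort.chronic_table()
        hc_only = chronic[chronic["group"] == "HC"]
        with pytest.raises(ValueError, match="patients"):
            cst_correlations(hc_only)
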