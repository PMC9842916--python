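"""Random-intercept REML: exact reductions, closed-form oracles, slope
comparisons and evolution-pattern labeling."""

import numpy as np
import pandas as pd
import pytest

from lesionmap import (
    RandomInterceptModel,
    classify_pattern,
    correct_slope_family,
    fit_all_groups,
)
from lesionmap.lmm import LmmFit
from lesionmap.stats import by_fdr


def balanced_data(rng, n_subj=20, k=4, beta0=2.0, beta1=0.05, sb=0.1, se=0.05):
    times = np.tile(np.array([0.25, 1.0, 3.0, 8.0])[:k], n_subj)
    subj = np.repeat(np.arange(n_subj), k)
    b = rng.normal(0, sb, n_subj)
    y = beta0 + beta1 * times + b[subj] + rng.normal(0, se, n_subj * k)
    return times, y, subj


class TestRandomInterceptModel:
    def test_noiseless_line_exact(self):
        times = np.tile([0.0, 1.0, 2.0], 5)
        subj = np.repeat(np.arange(5), 3)
        y = 2.0 + 0.5 * times
        res = RandomInterceptModel.from_series(times, y, subj).fit()
        assert res.params[0] == pytest.approx(2.0, abs=1e-10)
        assert res.params[1] == pytest.approx(0.5, abs=1e-10)
        assert res.sigma2_b == 0.0 and res.sigma2_e == 0.0

    def test_balanced_oneway_matches_anova_estimators(self, rng):
        """Intercept-only balanced model: REML variance components equal the
        classical ANOVA estimators sigma2_e = MSW, sigma2_b = (MSB - MSW)/k."""
        n_subj, k = 15, 5
        subj = np.repeat(np.arange(n_subj), k)
        b = rng.normal(0, 0.4, n_subj)
        y = 1.7 + b[subj] + rng.normal(0, 0.2, n_subj * k)
        res = RandomInterceptModel(y, np.ones((y.size, 1)), subj).fit()
        means = np.array([y[subj == i].mean() for i in range(n_subj)])
        msw = sum(((y[subj == i] - means[i]) ** 2).sum() for i in range(n_subj)) / (
            n_subj * (k - 1)
        )
        msb = k * ((means - means.mean()) ** 2).sum() / (n_subj - 1)
        assert res.sigma2_e == pytest.approx(msw, abs=1e-6)
        assert res.sigma2_b == pytest.approx(max((msb - msw) / k, 0.0), abs=1e-6)
        assert res.params[0] == pytest.approx(y.mean(), abs=1e-8)

    def test_boundary_fit_reduces_to_ols(self, rng):
        """Data with no subject clustering pin sigma2_b at 0 and give OLS."""
        n = 40
        times = rng.uniform(0, 8, n)
        subj = np.repeat(np.arange(10), 4)
        # anti-clustered: residuals alternate sign within subject
        y = 1.0 + 0.2 * times + np.tile([1.0, -1.0, 1.0, -1.0], 10)
        res = RandomInterceptModel.from_series(times, y, subj).fit()
        assert res.sigma2_b == 0.0
        X = np.column_stack([np.ones(n), times])
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(res.params, ols, atol=1e-8)

    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.api as sm

        times, y, subj = balanced_data(rng, n_subj=25)
        # unbalance it: drop some observations
        keep = rng.random(y.size) > 0.2
        times, y, subj = times[keep], y[keep], subj[keep]
        res = RandomInterceptModel.from_series(times, y, subj).fit()
        X = np.column_stack([np.ones(y.size), times])
        sm_res = sm.MixedLM(y, X, groups=subj).fit(reml=True)
        assert np.allclose(res.params, sm_res.fe_params, atol=1e-5)
        assert res.sigma2_e == pytest.approx(sm_res.scale, rel=1e-4)
        assert res.sigma2_b == pytest.approx(
            float(np.asarray(sm_res.cov_re)[0, 0]), rel=1e-3, abs=1e-6
        )
        assert np.allclose(res.bse, sm_res.bse_fe, atol=1e-5)

    def test_reml_is_local_optimum(self, rng):
        times, y, subj = balanced_data(rng)
        model = RandomInterceptModel.from_series(times, y, subj)
        res = model.fit()
        ll_hat = model.reml_loglike(res.sigma2_b, res.sigma2_e)
        assert np.isfinite(ll_hat)
        for _ in range(50):
            sb = res.sigma2_b * np.exp(rng.normal(0, 0.3)) + rng.uniform(0, 1e-4)
            se = res.sigma2_e * np.exp(rng.normal(0, 0.3))
            assert model.reml_loglike(sb, se) <= ll_hat + 1e-9

    def test_time_unit_equivariance(self, rng):
        times, y, subj = balanced_data(rng)
        res_m = RandomInterceptModel.from_series(times, y, subj).fit()
        res_d = RandomInterceptModel.from_series(times * 30.44, y, subj).fit()
        z_m = res_m.params[1] / res_m.bse[1]
        z_d = res_d.params[1] / res_d.bse[1]
        assert z_m == pytest.approx(z_d, rel=1e-6)
        assert res_d.params[1] * 30.44 == pytest.approx(res_m.params[1], rel=1e-7)

    def test_intercept_shift_absorbed_by_random_effect(self, rng):
        times, y, subj = balanced_data(rng, sb=0.3)
        res = RandomInterceptModel.from_series(times, y, subj).fit()
        # add a mean-zero per-subject constant: slope estimate barely moves
        shift = rng.normal(0, 0.3, 20)
        shift -= shift.mean()
        y2 = y + shift[subj]
        res2 = RandomInterceptModel.from_series(times, y2, subj).fit()
        assert res2.params[1] == pytest.approx(res.params[1], abs=5e-3)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            RandomInterceptModel.from_series([0, 1, 0, 1], [1, 2, 3, 4], [0, 0, 1, 1])

    def test_summary_mentions_variances(self, rng):
        times, y, subj = balanced_data(rng)
        res = RandomInterceptModel.from_series(times, y, subj).fit()
        s = res.summary()
        assert "sigma2_b" in s and "slope" in s and "REML" in s


def make_group_df(rng, slopes, n_subj=30, sb=0.05, se=0.05):
    rows = []
    sid = 0
    for g, slope in slopes.items():
        for i in range(n_subj):
            b = rng.normal(0, sb)
            for t in (0.25, 1.0, 3.0, 8.0):
                rows.append(
                    {
                        "subject_id": f"s{sid:03d}",
                        "group": g,
                        "timepoint_months": t,
                        "value": 2.5 + slope * t + b + rng.normal(0, se),
                    }
                )
            sid += 1
    return pd.DataFrame(rows)


class TestGroupFits:
    def test_equal_slopes_give_large_pairwise_p(self, rng):
        ps = []
        for rep in range(20):
            df = make_group_df(rng, {"PR": 0.01, "CR": 0.01, "HC": 0.01}, n_subj=15)
            fit = fit_all_groups(df, roi="r", measure="thickness")
            ps.append(fit.pair_p["PRvsCR"])
        # roughly uniform: not all small
        assert np.mean(np.array(ps) < 0.05) <= 0.25

    def test_divergent_slopes_detected(self, rng):
        df = make_group_df(rng, {"PR": -0.01, "CR": 0.01, "HC": 0.0})
        fit = fit_all_groups(df, roi="r", measure="area")
        assert fit.pair_p["PRvsCR"] < 1e-4
        assert fit.slopes["PR"] < 0 < fit.slopes["CR"]

    def test_subjects_with_single_visit_dropped(self, rng):
        df = make_group_df(rng, {"PR": 0.0, "CR": 0.0, "HC": 0.0}, n_subj=10)
        # leave one PR subject with a single observation
        drop = df[(df["subject_id"] == "s000") & (df["timepoint_months"] > 0.5)].index
        df = df.drop(drop)
        fit = fit_all_groups(df, roi="r", measure="thickness")
        assert fit.group_fits["PR"].model.n_subjects == 9


class TestFamilyCorrectionAndPatterns:
    @staticmethod
    def _fake_fit(roi, slopes, slope_p, pair_p):
        fit = LmmFit(roi=roi, measure="thickness", group_fits={})
        fit.slopes = dict(slopes)
        fit.slope_p = dict(slope_p)
        fit.pair_p = dict(pair_p)
        return fit

    def test_single_test_correction_is_identity(self):
        fit = self._fake_fit(
            "r", {"PR": -0.01, "CR": 0.0}, {"PR": 0.03}, {"PRvsCR": 0.2}
        )
        (out,) = correct_slope_family([fit])
        assert out.slope_p_corrected["PR"] == pytest.approx(0.03)
        assert out.pair_p_corrected["PRvsCR"] == pytest.approx(0.2)

    def test_family_matches_by_fdr_oracle(self, rng):
        fits = []
        for i in range(8):
            fits.append(
                self._fake_fit(
                    f"r{i}",
                    {"PR": -0.01, "CR": 0.01, "HC": 0.0},
                    {"PR": rng.uniform(1e-4, 1), "CR": rng.uniform(1e-4, 1),
                     "HC": rng.uniform(1e-4, 1)},
                    {"PRvsCR": rng.uniform(1e-4, 1), "PRvsHC": rng.uniform(1e-4, 1),
                     "CRvsHC": rng.uniform(1e-4, 1)},
                )
            )
        out = correct_slope_family(fits)
        raw = [f.slope_p[g] for f in fits for g in ("PR", "CR", "HC")]
        expected, _ = by_fdr(np.array(raw))
        got = [f.slope_p_corrected[g] for f in out for g in ("PR", "CR", "HC")]
        assert np.allclose(got, expected)

    @pytest.mark.parametrize(
        "slopes,slope_p,pair_p,expected",
        [
            # PR decline significant, CR decline ns -> pattern 1
            ({"PR": -0.01, "CR": -0.004}, {"PR": 0.001, "CR": 0.3}, {"PRvsCR": 0.2}, 1),
            # both increase significantly -> pattern 2
            ({"PR": 0.008, "CR": 0.012}, {"PR": 0.01, "CR": 0.001}, {"PRvsCR": 0.4}, 2),
            # CR-only significant increase -> pattern 3
            ({"PR": 0.001, "CR": 0.01}, {"PR": 0.7, "CR": 0.004}, {"PRvsCR": 0.2}, 3),
            # opposite signs with significant difference -> pattern 4
            ({"PR": -0.01, "CR": 0.01}, {"PR": 0.001, "CR": 0.001}, {"PRvsCR": 1e-6}, 4),
            # nothing significant -> none
            ({"PR": -0.002, "CR": 0.001}, {"PR": 0.5, "CR": 0.6}, {"PRvsCR": 0.7}, None),
        ],
    )
    def test_pattern_rules(self, slopes, slope_p, pair_p, expected):
        fit = self._fake_fit("r", slopes, slope_p, pair_p)
        correct_slope_family([fit])
        assert classify_pattern(fit) == expected
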