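"""Stratified non-linear MR: IV-free strata, LACE, curves and tests."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from repromr.mr import het_between
from repromr.nonlinear import (NonlinearMR, NonlinearMRError, StratumEstimate,
                               fp_fit_and_test, iv_free_strata,
                               iv_heterogeneity_tests, lace_per_stratum,
                               piecewise_fit)
from repromr.simulate import benchmark_suite, simulate_cohort


def make_laces(mid, lace, se, n=100, cases=10):
    return [StratumEstimate(k + 1, mid[k] - 0.5, mid[k] + 0.5, mid[k],
                            lace[k], se[k], n, cases)
            for k in range(len(mid))]


@pytest.fixture(scope="module")
def linear_cohort():
    cfg = replace(benchmark_suite(17)["linear_theta0.25"],
                  n_individuals=50_000, prevalence=0.10, h2=0.1)
    return simulate_cohort(cfg).frame()


class TestStrata:
    def test_equal_count_partition(self, linear_cohort):
        strat = iv_free_strata(linear_cohort.head(10_000), 10)
        counts = strat.data["stratum"].value_counts()
        assert sorted(counts) == [1000] * 10

    def test_assignment_matches_sort_and_split_oracle(self, linear_cohort):
        import statsmodels.api as sm
        df = linear_cohort.head(5_000)
        strat = iv_free_strata(df, 5)
        resid = sm.OLS(df["exposure"],
                       sm.add_constant(df[["score"]])).fit().resid.to_numpy()
        order = np.argsort(resid, kind="stable")
        expect = np.empty(len(df), int)
        for k, idx in enumerate(np.array_split(order, 5)):
            expect[idx] = k + 1
        np.testing.assert_array_equal(strat.data["stratum"].to_numpy(), expect)

    def test_null_score_reproduces_raw_exposure_quantiles(self, rng):
        exposure = rng.normal(size=2000)
        score = rng.normal(size=2000)
        # orthogonalise so the fitted score effect is exactly zero
        import statsmodels.api as sm
        score = sm.OLS(score, sm.add_constant(exposure)).fit().resid
        df = pd.DataFrame({"score": score, "exposure": exposure,
                           "outcome": rng.integers(0, 2, 2000)})
        strat = iv_free_strata(df, 4)
        raw_q = pd.qcut(df["exposure"], 4, labels=False) + 1
        assert (strat.data["stratum"] == raw_q).all()

    def test_too_many_strata_errors(self, linear_cohort):
        with pytest.raises(NonlinearMRError, match="smaller than 50"):
            iv_free_strata(linear_cohort.head(1000), 50)


class TestLACE:
    def test_constant_causal_effect_recovered_per_stratum(self, linear_cohort):
        strat = iv_free_strata(linear_cohort, 10)
        laces = lace_per_stratum(strat)
        for e in laces:
            assert e.usable
            assert abs(e.lace - 0.25) < 3.5 * e.se

    def test_null_score_outcome_relation_centres_on_zero(self, rng):
        n = 20_000
        df = pd.DataFrame({"score": rng.normal(size=n)})
        df["exposure"] = 0.5 * df["score"] + rng.normal(size=n)
        df["outcome"] = rng.integers(0, 2, n)     # independent of everything
        laces = lace_per_stratum(iv_free_strata(df, 5))
        z = [e.lace / e.se for e in laces]
        assert np.all(np.abs(z) < 4)

    def test_shared_denominator_construction(self, linear_cohort):
        """The denominator is the full-sample score-exposure slope, so the
        LACE ratio of any two strata equals the ratio of their logistic
        numerators."""
        laces = lace_per_stratum(iv_free_strata(linear_cohort, 5))
        ratio_lace = laces[0].lace / laces[1].lace
        ratio_se = laces[0].se / laces[1].se
        # se = se_num / |bx| with the same bx, so lace and se scale together
        assert laces[0].lace / laces[0].se == pytest.approx(
            ratio_lace / ratio_se * laces[1].lace / laces[1].se)

    def test_stratum_without_cases_flagged_unusable(self, rng):
        n = 6000
        df = pd.DataFrame({"score": rng.normal(size=n)})
        df["exposure"] = 0.5 * df["score"] + rng.normal(size=n)
        # cases only in the top exposure tertile
        df["outcome"] = (df["exposure"] > np.quantile(df["exposure"], 0.9)).astype(int)
        laces = lace_per_stratum(iv_free_strata(df, 3))
        assert any(not e.usable for e in laces)


class TestPiecewise:
    def test_constant_lace_gives_straight_line(self):
        mid = np.arange(5, dtype=float) + 0.5
        curve = piecewise_fit(make_laces(mid, np.full(5, 0.2), np.full(5, 0.01)))
        slopes = np.diff(curve.y_knots) / np.diff(curve.x_knots)
        np.testing.assert_allclose(slopes, 0.2)

    def test_cumulative_sum_oracle(self, rng):
        mid = np.arange(10, dtype=float) + 0.5
        lace = rng.normal(0.1, 0.3, 10)
        laces = make_laces(mid, lace, np.full(10, 0.05))
        curve = piecewise_fit(laces)
        # independent oracle: cumulative slope * width from the reference
        widths = np.array([e.exposure_high - e.exposure_low for e in laces])
        widths[0] = laces[0].exposure_high - curve.reference
        np.testing.assert_allclose(curve.y_knots[1:], np.cumsum(lace * widths))

    def test_reference_is_first_stratum_midpoint(self):
        mid = np.arange(3, dtype=float)
        curve = piecewise_fit(make_laces(mid, [0.1, 0.2, 0.3], [0.01] * 3))
        assert curve.reference == mid[0]
        assert curve.y_knots[0] == 0.0


class TestFPTest:
    def test_power_grid_of_one_degenerates_to_linear(self):
        mid = np.linspace(22, 35, 10)
        laces = make_laces(mid, np.full(10, 0.2), np.full(10, 0.05))
        fp = fp_fit_and_test(laces, powers_set=(1.0,))
        assert fp.degree == 1 and fp.powers == (1.0,)
        assert fp.p_nonlinearity == 1.0

    def test_null_calibration_small(self, rng):
        mid = np.linspace(22, 35, 10)
        rej = 0
        for i in range(200):
            lace = 0.2 + 0.05 * rng.standard_normal(10)
            rej += fp_fit_and_test(make_laces(mid, lace, np.full(10, 0.05)),
                                   seed=i).p_nonlinearity < 0.05
        assert 0.01 <= rej / 200 <= 0.10

    def test_detects_quadratic_curve_with_nonunit_power(self, rng):
        """A quadratic log-OR curve makes the LACE profile linear in
        exposure; the FP fit should select non-unit powers and reject
        linearity in most replicates."""
        mid = np.linspace(22, 35, 10)
        rej, nonunit = 0, 0
        for i in range(100):
            lace = 0.015 * (mid - 28.5) + 0.05 * rng.standard_normal(10)
            fp = fp_fit_and_test(make_laces(mid, lace, np.full(10, 0.05)), seed=i)
            rej += fp.p_nonlinearity < 0.05
            nonunit += fp.powers != (1.0,)
        assert rej / 100 > 0.8
        assert nonunit / 100 > 0.8


class TestHeterogeneity:
    def test_two_strata_q_equals_het_between(self):
        mid = np.array([1.0, 2.0, 3.0])
        lace = np.array([0.1, 0.4, 0.4])
        se = np.array([0.05, 0.08, 0.08])
        res = iv_heterogeneity_tests(make_laces(mid, lace, se))
        # pairwise check via the Q decomposition at 2 strata
        res2 = iv_heterogeneity_tests(make_laces(mid, lace, se))
        assert res["q_df"] == 2
        z, p = het_between(lace[0], se[0], lace[1], se[1])
        # Q on two strata alone equals z^2
        w = 1 / se[:2] ** 2
        pooled = np.sum(w * lace[:2]) / w.sum()
        q2 = float(np.sum(w * (lace[:2] - pooled) ** 2))
        assert q2 == pytest.approx(z**2)

    def test_homogeneous_q_uniform(self, rng):
        from scipy import stats
        mid = np.linspace(20, 35, 8)
        ps = []
        for i in range(300):
            lace = 0.2 + 0.04 * rng.standard_normal(8)
            ps.append(iv_heterogeneity_tests(
                make_laces(mid, lace, np.full(8, 0.04)))["q_pvalue"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_increasing_lace_detected_by_trend(self, rng):
        mid = np.linspace(20, 35, 8)
        hits = 0
        for i in range(50):
            lace = 0.01 * mid + 0.02 * rng.standard_normal(8)
            hits += iv_heterogeneity_tests(
                make_laces(mid, lace, np.full(8, 0.02)))["trend_pvalue"] < 0.05
        assert hits / 50 > 0.9


class TestCollapsesToFullSample:
    def test_weighted_mean_of_lace_matches_full_sample_ratio(self, linear_cohort):
        """With a homogeneous effect, precision-weighted LACE equals the
        one-sample ratio estimate computed on everyone."""
        import statsmodels.api as sm
        laces = lace_per_stratum(iv_free_strata(linear_cohort, 10))
        w = np.array([1 / e.se**2 for e in laces])
        theta = np.array([e.lace for e in laces])
        pooled = np.sum(w * theta) / w.sum()
        pooled_se = 1 / np.sqrt(w.sum())
        df = linear_cohort
        by = sm.GLM(df["outcome"], sm.add_constant(df["score"]),
                    family=sm.families.Binomial()).fit().params.iloc[1]
        bx = sm.OLS(df["exposure"], sm.add_constant(df["score"])).fit().params.iloc[1]
        assert pooled == pytest.approx(by / bx, abs=4 * pooled_se)


class TestColliderBias:
    def test_iv_free_strata_avoid_collider_bias_of_raw_strata(self, rng):
        """Stratifying on the raw exposure conditions on a collider between
        the score and the confounder, biasing stratum estimates; IV-free
        stratification does not.  Paired simulation with a shared confounder
        and a null causal effect."""
        n = 40_000
        u = rng.normal(size=n)                       # confounder
        score = rng.normal(size=n)
        exposure = 0.5 * score + 0.7 * u + 0.5 * rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-2.0 + 1.0 * u)))      # outcome from confounder only
        outcome = (rng.random(n) < p).astype(int)
        df = pd.DataFrame({"score": score, "exposure": exposure,
                           "outcome": outcome})

        ivfree = lace_per_stratum(iv_free_strata(df, 5))
        raw = df.copy()
        raw_strata = pd.qcut(raw["exposure"], 5, labels=False) + 1
        bias_raw, z_raw = [], []
        import statsmodels.api as sm
        bx = sm.OLS(df["exposure"], sm.add_constant(df["score"])).fit().params.iloc[1]
        for k in range(1, 6):
            sub = raw[raw_strata == k]
            fit = sm.GLM(sub["outcome"], sm.add_constant(sub["score"]),
                         family=sm.families.Binomial()).fit()
            bias_raw.append(fit.params.iloc[1] / bx)
            z_raw.append(fit.params.iloc[1] / fit.bse.iloc[1])
        z_ivfree = [e.lace / e.se for e in ivfree if e.usable]
        # raw stratification shows clear spurious signal; IV-free does not
        assert np.max(np.abs(z_raw)) > 4
        assert np.max(np.abs(z_ivfree)) < 4


class TestModelWrapper:
    def test_end_to_end_linear_cohort(self, linear_cohort):
        res = NonlinearMR(linear_cohort).fit(q_piecewise=10, q_fp=20)
        assert res.fp_model.p_nonlinearity > 0.01
        assert len(res.laces_piecewise) == 10
        curve = res.piecewise_curve
        assert curve.y_knots.size == curve.x_knots.size
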