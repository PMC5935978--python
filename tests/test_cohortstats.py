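"""Cohort statistics: t tests, chi-square, Fisher, Spearman, logistic, DeLong."""

import math

import numpy as np
import pandas as pd
import pytest

from nodulequant import (
    CohortConfig,
    ContingencyTable,
    GroupSummary,
    analyze_cohort,
    cohort_to_frame,
    delong_auc,
    delong_compare,
    fisher_exact,
    logistic_fit,
    pearson_chi2,
    pooled_t,
    roc_curve,
    simulate_cohort,
    spearman_rho,
    welch_t,
)
from nodulequant.cohortstats import SeparationError


class TestPooledT:
    def test_pggo_enhancement_strata(self):
        res = pooled_t(
            GroupSummary(33, -533.36, 103.79), GroupSummary(25, -579.80, 92.92)
        )
        assert res.t == pytest.approx(-1.764, abs=5e-4)
        assert res.df == 56

    def test_sn_enhancement_strata(self):
        res = pooled_t(
            GroupSummary(55, -95.67, 94.30), GroupSummary(103, -108.82, 92.51)
        )
        assert res.t == pytest.approx(-0.845, abs=5e-4)

    def test_identical_summaries_t_zero(self):
        s = GroupSummary(20, 1.5, 0.4)
        assert pooled_t(s, s).t == 0.0


class TestWelchT:
    def test_sc_proportion_group_contrast(self):
        res = welch_t(GroupSummary(283, 56.0, 30.0), GroupSummary(92, 14.0, 21.0))
        assert abs(res.t) == pytest.approx(14.87, rel=0.005)
        # consistent with the published value computed on unrounded data
        assert abs(res.t) == pytest.approx(14.822, rel=0.005)

    def test_equal_means_t_zero(self):
        assert welch_t(GroupSummary(10, 5.0, 1.0), GroupSummary(20, 5.0, 3.0)).t == 0.0

    def test_satterthwaite_df_limit(self):
        res = welch_t(GroupSummary(10, 0.0, 0.0), GroupSummary(50, 5.0, 10.0))
        assert res.df == pytest.approx(49, abs=1e-9)

    def test_closed_form_oracle(self):
        a, b = GroupSummary(12, 3.0, 1.5), GroupSummary(18, 4.2, 2.5)
        se = math.sqrt(a.sd**2 / a.n + b.sd**2 / b.n)
        assert welch_t(a, b).t == pytest.approx((b.mean - a.mean) / se)


class TestPearsonChi2:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([[36, 40], [143, 42], [104, 10]], 48.04),
            ([[33, 1], [250, 91]], 9.415),
            ([[172, 77], [89, 12], [22, 3]], 16.346),
            ([[50, 14], [233, 78]], 0.295),
        ],
    )
    def test_published_contingency_tables(self, counts, expected):
        res = pearson_chi2(ContingencyTable(np.array(counts)))
        assert res.chi2 == pytest.approx(expected, abs=5e-3)

    def test_identical_row_proportions_zero(self):
        res = pearson_chi2(ContingencyTable(np.array([[10, 5], [20, 10]])))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_formula_oracle(self):
        counts = np.array([[7, 3], [2, 8]])
        n = counts.sum()
        expected = np.outer(counts.sum(1), counts.sum(0)) / n
        oracle = ((counts - expected) ** 2 / expected).sum()
        assert pearson_chi2(ContingencyTable(counts)).chi2 == pytest.approx(oracle)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2(ContingencyTable(np.array([[0, 0], [5, 5]])))


class TestFisherExact:
    def test_enumeration_value(self):
        p = fisher_exact(ContingencyTable(np.array([[1, 9], [11, 3]])))
        assert p == pytest.approx(0.00276, abs=5e-5)

    def test_hypergeometric_enumeration_oracle(self):
        from scipy.stats import hypergeom

        counts = np.array([[3, 7], [9, 2]])
        r1, r2 = counts.sum(1)
        c1 = counts[:, 0].sum()
        n = counts.sum()
        p_obs = hypergeom.pmf(counts[0, 0], n, r1, c1)
        total = sum(
            hypergeom.pmf(a, n, r1, c1)
            for a in range(max(0, c1 - r2), min(r1, c1) + 1)
            if hypergeom.pmf(a, n, r1, c1) <= p_obs * (1 + 1e-9)
        )
        assert fisher_exact(ContingencyTable(counts)) == pytest.approx(total)

    def test_null_table_p_one(self):
        assert fisher_exact(ContingencyTable(np.array([[5, 5], [5, 5]]))) == 1.0

    def test_transposition_invariance(self):
        t = np.array([[2, 10], [7, 4]])
        assert fisher_exact(ContingencyTable(t)) == pytest.approx(
            fisher_exact(ContingencyTable(t.T))
        )

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(ContingencyTable(np.array([[1.5, 2.0], [3.0, 4.0]])))


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x**3)[0] == pytest.approx(1.0)
        assert spearman_rho(x, -x)[0] == pytest.approx(-1.0)

    def test_midrank_oracle_with_ties(self):
        from scipy.stats import rankdata

        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 5.0])
        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y)[0] == pytest.approx(oracle)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho(np.ones(5), np.arange(5.0))


class TestLogisticFit:
    def test_binary_predictor_or_equals_cross_product(self):
        # necrosis yes/no by invasive/non-invasive: OR = (33*91)/(250*1)
        x = np.repeat([1, 1, 0, 0], [33, 1, 250, 91])
        y = np.repeat([1, 0, 1, 0], [33, 1, 250, 91])
        fit = logistic_fit(pd.DataFrame({"necrosis": x}), y)
        assert fit.odds_ratio("necrosis") == pytest.approx(12.012, abs=1e-3)

    def test_null_model_or_near_one(self, rng):
        x = rng.normal(size=2000)
        y = rng.integers(0, 2, size=2000)
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.table.loc["const", "coef"] == pytest.approx(0.0, abs=0.1)
        assert fit.odds_ratio("x") == pytest.approx(1.0, abs=0.15)

    def test_tiny_dataset_matches_grid_search_mle(self):
        """Coefficients agree with a brute-force likelihood maximizer."""
        x = np.array([-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0])
        y = np.array([0, 0, 1, 0, 1, 0, 1, 1])
        fit = logistic_fit(pd.DataFrame({"x": x}), y)

        def nll(b0, b1):
            eta = b0 + b1 * x
            return -(y * eta - np.log1p(np.exp(eta))).sum()

        b0s = np.linspace(-3, 3, 301)
        b1s = np.linspace(-1, 4, 301)
        grid = np.array([[nll(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(grid.argmin(), grid.shape)
        # refine around the grid optimum
        from scipy.optimize import minimize

        res = minimize(lambda b: nll(*b), x0=[b0s[i], b1s[j]])
        assert fit.table.loc["const", "coef"] == pytest.approx(res.x[0], abs=1e-3)
        assert fit.table.loc["x", "coef"] == pytest.approx(res.x[1], abs=1e-3)

    def test_separation_flagged(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(SeparationError):
            logistic_fit(pd.DataFrame({"x": x}), y)

    def test_collinear_design_named(self, rng):
        x = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        with pytest.raises(ValueError, match="dup"):
            logistic_fit(pd.DataFrame({"x": x, "dup": 2 * x}), y)

    def test_ci_brackets_or(self, rng):
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-x))).astype(int)
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        row = fit.table.loc["x"]
        assert row["ci_low"] < row["odds_ratio"] < row["ci_high"]
        assert row["odds_ratio"] == pytest.approx(np.exp(row["coef"]))


class TestDeLong:
    def test_identical_predictors_z_zero(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        pred = rng.normal(size=40)
        res = delong_compare(pred, pred, labels)
        assert res.z == 0.0 and res.p == 1.0

    def test_swap_flips_sign(self, rng):
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        p1 = rng.normal(size=60) + labels
        p2 = rng.normal(size=60)
        a = delong_compare(p1, p2, labels)
        b = delong_compare(p2, p1, labels)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_auc_matches_roc_module(self, rng):
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        pred = np.round(rng.normal(size=80), 1)  # ties
        auc, _ = delong_auc(pred, labels)
        assert auc == pytest.approx(roc_curve(pred, labels).auc)

    def test_variance_matches_double_loop_oracle(self, rng):
        labels = np.array([1] * 5 + [0] * 7)
        pred = np.round(rng.normal(size=12), 1)
        auc, var = delong_auc(pred, labels)
        pos, neg = pred[labels == 1], pred[labels == 0]
        v10 = np.array(
            [np.mean([(p > n) + 0.5 * (p == n) for n in neg]) for p in pos]
        )
        v01 = np.array(
            [np.mean([(p > n) + 0.5 * (p == n) for p in pos]) for n in neg]
        )
        oracle = np.var(v10, ddof=1) / 5 + np.var(v01, ddof=1) / 7
        assert var == pytest.approx(oracle)
        assert auc == pytest.approx(v10.mean())


@pytest.fixture(scope="module")
def report():
    df = cohort_to_frame(simulate_cohort(CohortConfig(seed=8)))
    return analyze_cohort(df)


class TestAnalyzeCohort:
    def test_report_sections_present(self, report):
        assert {"size_cm", "ggoc_pct", "sc_pct", "suv_max"} <= set(
            report.univariate_continuous
        )
        assert {"location", "contour", "necrosis", "vacuole_cyst"} <= set(
            report.univariate_categorical
        )
        assert report.logistic is not None
        assert {"sc", "size", "combined"} == set(report.aucs)
        assert report.sc_cutoff is not None

    def test_effect_directions_match_biology(self, report):
        """Invasive tumors are larger, more solid, less ground-glass."""
        assert report.univariate_continuous["size_cm"]["t"] < 0  # non-inv minus inv
        assert report.univariate_continuous["sc_pct"]["t"] < 0
        assert report.univariate_continuous["ggoc_pct"]["t"] > 0
        assert report.spearman["sc_pct"][0] < -0.4
        assert report.spearman["ggoc_pct"][0] > 0.3

    def test_combined_model_dominates_components_in_sample(self, report):
        assert report.aucs["combined"] >= max(report.aucs["sc"], report.aucs["size"]) - 1e-9

    def test_null_cohort_type_I_error_calibrated(self):
        """With identical group distributions ~5% of univariate t tests reject."""
        from nodulequant.phantom import COHORT_MARGIN_DEFAULTS

        base = COHORT_MARGIN_DEFAULTS["invasive"]
        rejections = 0
        trials = 0
        for seed in range(60):
            groups = {
                "invasive": {**base, "n": 60},
                "non-invasive": {**base, "n": 60},
            }
            df = cohort_to_frame(simulate_cohort(CohortConfig(groups=groups, seed=seed)))
            df.loc[df["group"] == "non-invasive", "invasive"] = 0
            rep = analyze_cohort(df)
            for var in ("size_cm", "ggoc_pct", "sc_pct"):
                trials += 1
                rejections += rep.univariate_continuous[var]["p"] < 0.05
        rate = rejections / trials
        assert 0.0 <= rate < 0.12  # binomial noise around the nominal 5%

    def test_suv_in_multivariable_rejected(self):
        df = cohort_to_frame(simulate_cohort(CohortConfig(seed=8)))
        with pytest.raises(ValueError, match="SUV"):
            analyze_cohort(df, multivariable=("size_cm", "suv_max"))
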