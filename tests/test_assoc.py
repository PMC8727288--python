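"""Logistic/multinomial models, c-statistic, rank tests, 2x2 machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cllprs.assoc import (c_statistic, continuous_association, exposure_screen,
                          fit_logistic, fit_multinomial, heterogeneity_test,
                          kruskal_wallis, odds_ratio_wald, per_snp_association,
                          quintile_association, two_by_two)
from cllprs.errors import InputError
from conftest import matrix_from


def make_twobytwo_data(a, b, c, d):
    """Outcome/exposure vectors realizing a 2x2 table:
    a = exposed cases, b = exposed controls, c/d unexposed."""
    y = np.r_[np.ones(a + c), np.zeros(b + d)]
    x = np.r_[np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)]
    return y, x


class TestFitLogistic:
    def test_single_binary_predictor_matches_cross_product(self):
        """The printed Q1-vs-Q3 cell counts give a closed-form crude OR of
        (50*553)/(103*597); the IRLS slope and its Woolf SE must match to
        1e-8."""
        y, x = make_twobytwo_data(50, 597, 103, 553)
        fit = fit_logistic(y, np.column_stack([np.ones_like(y), x]),
                           ["intercept", "x"])
        assert fit.converged
        expected = math.log((50 * 553) / (103 * 597))
        assert fit.coef("x") == pytest.approx(expected, abs=1e-8)
        woolf_se = math.sqrt(1 / 50 + 1 / 597 + 1 / 103 + 1 / 553)
        assert fit.se("x") == pytest.approx(woolf_se, abs=1e-8)

    def test_matches_statsmodels_on_mixed_design(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        n = 1500
        X = np.column_stack([np.ones(n), rng.normal(size=n),
                             rng.integers(0, 2, n), rng.normal(60, 10, n)])
        eta = -0.5 + 0.8 * X[:, 1] - 0.4 * X[:, 2] + 0.02 * X[:, 3]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(ours.beta, ref.params, atol=1e-6)
        assert np.allclose(np.sqrt(np.diag(ours.cov)), ref.bse, atol=1e-6)

    def test_degenerate_outcome_flagged(self):
        y = np.zeros(50)
        X = np.column_stack([np.ones(50), np.arange(50.0)])
        fit = fit_logistic(y, X)
        assert fit.separated and not fit.converged

    def test_complete_separation_flagged(self):
        x = np.r_[np.zeros(30), np.ones(30)]
        y = x.copy()
        fit = fit_logistic(y, np.column_stack([np.ones(60), x]))
        assert fit.separated

    def test_wald_null_calibration(self):
        """Under the null the Wald z for a random predictor exceeds 1.96
        about 5% of the time."""
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 400
        for _ in range(reps):
            n = 250
            x = rng.normal(size=n)
            y = rng.integers(0, 2, n).astype(float)
            fit = fit_logistic(y, np.column_stack([np.ones(n), x]))
            z = fit.coef("x1") / fit.se("x1")
            rejections += abs(z) > 1.959964
        assert 0.02 <= rejections / reps <= 0.09


class TestOddsRatioWald:
    def test_zero_coefficient(self):
        y, x = make_twobytwo_data(40, 40, 40, 40)
        fit = fit_logistic(y, np.column_stack([np.ones_like(y), x]),
                           ["intercept", "x"])
        orr, lo, hi, p = odds_ratio_wald(fit, "x")
        assert orr == pytest.approx(1.0, abs=1e-8)
        assert lo < 1.0 < hi
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_per_decade_rescaling(self):
        """A per-year log-OR of 0.0605 reports as e^0.605 ~ 1.83 per decade."""
        from cllprs.assoc import ModelFit
        fit = ModelFit(["age"], np.array([0.0605]), np.array([[1e-6]]),
                       0.0, 1, True, 100)
        orr, lo, hi, _ = odds_ratio_wald(fit, "age", scale=10)
        assert orr == pytest.approx(math.exp(0.605), rel=1e-12)
        assert lo < orr < hi


class TestCStatistic:
    def test_perfect_separation(self):
        auc, lo, hi = c_statistic(np.array([0.9, 0.8, 0.1, 0.2]),
                                  np.array([1, 1, 0, 0]))
        assert auc == 1.0 and hi == 1.0

    def test_null_predictions(self):
        rng = np.random.default_rng(4)
        pred = rng.random(5000)
        y = rng.integers(0, 2, 5000)
        auc, _, _ = c_statistic(pred, y)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_equals_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        pred = np.round(rng.random(400), 2)  # heavy ties
        y = rng.integers(0, 2, 400)
        auc, _, _ = c_statistic(pred, y)
        cases = pred[y == 1]
        controls = pred[y == 0]
        wins = sum((cases[:, None] > controls).sum()
                   for cases, controls in [(cases, controls)])
        ties = (cases[:, None] == controls).sum()
        oracle = (wins + 0.5 * ties) / (len(cases) * len(controls))
        assert auc == pytest.approx(oracle, abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(InputError):
            c_statistic(np.array([0.2, 0.4]), np.array([1, 1]))


class TestKruskalWallis:
    def test_identical_groups(self):
        g = [np.array([1.0, 1, 1]), np.array([1.0, 1])]
        assert kruskal_wallis(g) == (0.0, 1.0)

    def test_textbook_value(self):
        h, p = kruskal_wallis([np.array([1.0, 2, 3]), np.array([4.0, 5, 6]),
                               np.array([7.0, 8, 9])])
        assert h == pytest.approx(7.2, abs=1e-9)

    def test_two_groups_match_ranksum_approximation(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 35)
        _, p_kw = kruskal_wallis([a, b])
        p_rs = stats.ranksums(a, b).pvalue
        assert p_kw == pytest.approx(p_rs, abs=2e-3)


class TestTwoByTwo:
    def test_printed_counts_crude_or(self):
        res = two_by_two(50, 597, 103, 553)
        assert res.odds_ratio == pytest.approx(0.4497, abs=5e-4)
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_symmetric_table(self):
        assert two_by_two(10, 10, 10, 10).odds_ratio == pytest.approx(1.0)

    def test_zero_cell_needs_haldane(self):
        plain = two_by_two(0, 10, 5, 10)
        assert plain.odds_ratio is None
        assert 0 <= plain.fisher_p <= 1
        corrected = two_by_two(0, 10, 5, 10, haldane=True)
        assert corrected.odds_ratio == pytest.approx(
            (0.5 * 10.5) / (10.5 * 5.5))


class TestMultinomial:
    @staticmethod
    def _simulate_three_way(n, slopes, rng):
        prs = rng.normal(7.5, 1.0, n)
        age = rng.normal(64, 10, n)
        male = rng.integers(0, 2, n).astype(float)
        etas = [(-1.6) + s * (prs - 7.5) + 0.02 * (age - 64) + 0.3 * male
                for s in slopes]
        expetas = np.exp(np.column_stack(etas))
        denom = 1 + expetas.sum(axis=1)
        probs = np.column_stack([np.ones(n), expetas]) / denom[:, None]
        u = rng.random(n)
        codes = (u[:, None] >= probs.cumsum(axis=1)).sum(axis=1)
        return codes, prs, age, male

    def test_one_case_category_equals_binary_logistic(self):
        rng = np.random.default_rng(7)
        codes, prs, age, male = self._simulate_three_way(2000, [0.5], rng)
        X = np.column_stack([np.ones(2000), prs, age, male])
        multi = fit_multinomial(codes, X, ["case"])
        binary = fit_logistic((codes == 1).astype(float), X)
        assert np.allclose(multi.B[0], binary.beta, atol=1e-6)
        assert multi.log_likelihood == pytest.approx(binary.log_likelihood,
                                                     abs=1e-6)

    def test_matches_statsmodels_mnlogit(self):
        smd = pytest.importorskip("statsmodels.discrete.discrete_model")
        rng = np.random.default_rng(8)
        codes, prs, age, male = self._simulate_three_way(
            3000, [0.4, 0.8], rng)
        X = np.column_stack([np.ones(3000), prs, age, male])
        ours = fit_multinomial(codes, X, ["a", "b"])
        ref = smd.MNLogit(codes, X).fit(disp=0, maxiter=200)
        assert np.allclose(ours.B.T, ref.params, atol=1e-4)

    def test_single_category_lrt_is_zero(self):
        rng = np.random.default_rng(9)
        codes, prs, age, male = self._simulate_three_way(1500, [0.6], rng)
        cats = np.where(codes == 0, "control", "CLL")
        het = heterogeneity_test(cats, prs, age, male)
        assert het.lrt_statistic == pytest.approx(0.0, abs=1e-6)
        assert het.df == 0

    def test_graded_slopes_detected_and_ordered(self):
        """Printed per-unit effects 1.75 / 2.14 / 2.53 at 2000 per group
        produce ordered fitted slopes and a decisive heterogeneity p."""
        rng = np.random.default_rng(10)
        slopes = [math.log(1.75), math.log(2.14), math.log(2.53)]
        codes, prs, age, male = self._simulate_three_way(16000, slopes, rng)
        cats = np.array(["control", "LC_MBL", "HC_MBL", "CLL"])[codes]
        het = heterogeneity_test(cats, prs, age, male,
                                 case_order=["LC_MBL", "HC_MBL", "CLL"])
        fitted = het.slopes.set_index("category")["slope"]
        assert fitted["LC_MBL"] < fitted["CLL"]
        for cat, true in zip(("LC_MBL", "HC_MBL", "CLL"), slopes):
            assert fitted[cat] == pytest.approx(true, abs=0.12)
        assert het.df == 2
        assert het.p_het < 0.05

    def test_null_heterogeneity_calibration(self):
        """Equal true slopes: the slope-equality LRT rejects ~5% of the
        time at alpha 0.05."""
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 200
        for _ in range(reps):
            codes, prs, age, male = self._simulate_three_way(
                600, [0.5, 0.5], rng)
            cats = np.array(["control", "A", "B"])[codes]
            het = heterogeneity_test(cats, prs, age, male,
                                     case_order=["A", "B"])
            rejections += het.p_het < 0.05
        assert 0.02 <= rejections / reps <= 0.10


class TestQuintileAssociation:
    def test_reference_row_and_counts(self):
        rng = np.random.default_rng(13)
        n = 2000
        cats = rng.choice(["Q1", "Q2", "Q3", "Q4", "Q5"], n)
        y = rng.integers(0, 2, n).astype(float)
        out = quintile_association(cats, y, rng.normal(60, 10, n),
                                   rng.integers(0, 2, n).astype(float))
        ref = out.set_index("row").loc["Q3"]
        assert ref["odds_ratio"] == 1.0 and ref["note"] == "reference"
        assert out["n_cases"].sum() == int(y.sum())
        # null data: all CIs cover 1
        others = out.set_index("row").drop("Q3")
        assert ((others["ci_low"] < 1) & (others["ci_high"] > 1)).all()

    def test_constant_outcome_non_estimable(self):
        cats = np.array(["Q1", "Q2", "Q3", "Q4", "Q5"] * 20)
        y = np.zeros(100)
        out = quintile_association(cats, y, np.full(100, 60.0),
                                   np.zeros(100))
        assert (out.loc[out["row"] != "Q3", "note"] == "non_estimable").all()


class TestPerSNP:
    def test_effect_recovery_and_maf_precision(self):
        """Same per-allele OR at MAF 0.3 vs 0.05: the rare variant's SE is
        larger (the MAF-driven power attenuation)."""
        rng = np.random.default_rng(14)
        n = 5000
        g_common = rng.binomial(2, 0.3, n).astype(float)
        g_rare = rng.binomial(2, 0.05, n).astype(float)
        beta = math.log(1.4)
        eta = -1.0 + beta * g_common + beta * g_rare
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        mat = matrix_from(np.column_stack([g_common, g_rare]))
        out = per_snp_association(mat, y, rng.normal(60, 10, n),
                                  rng.integers(0, 2, n).astype(float))
        assert out.loc[0, "ci_low"] < 1.4 < out.loc[0, "ci_high"]
        width0 = math.log(out.loc[0, "ci_high"]) - math.log(out.loc[0, "ci_low"])
        width1 = math.log(out.loc[1, "ci_high"]) - math.log(out.loc[1, "ci_low"])
        assert width1 > width0

    def test_monomorphic_row_flagged(self):
        n = 200
        mat = matrix_from(np.column_stack([np.zeros(n), np.ones(n)]))
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        out = per_snp_association(mat, y, np.full(n, 60.0), np.zeros(n))
        assert (out["note"] == "monomorphic").all()


class TestExposureScreen:
    def _base(self, n, rng):
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "age": rng.normal(64, 10, n),
            "sex": np.where(rng.integers(0, 2, n) == 1, "M", "F"),
        })

    def test_exposure_identical_to_outcome_separates(self):
        rng = np.random.default_rng(15)
        df = self._base(200, rng)
        df["phenotype"] = np.where(np.arange(200) < 80, "MBL", "control")
        df["expo"] = (df["phenotype"] == "MBL").astype(float)
        out = exposure_screen(df, ["expo"], "MBL")
        assert out.loc[0, "note"] == "separated"

    def test_age_confounded_exposure_adjusts_away(self):
        """An exposure driven by age alone shows a small crude p but an
        adjusted CI covering 1 -- the prior-cancer pattern."""
        rng = np.random.default_rng(16)
        n = 2877
        df = self._base(n, rng)
        age = df["age"].to_numpy()
        p_case = 1 / (1 + np.exp(-(-2.3 + 0.08 * (age - 64))))
        df["phenotype"] = np.where(rng.random(n) < p_case, "MBL", "control")
        df["expo"] = (rng.random(n)
                      < 1 / (1 + np.exp(-(-0.8 + 0.1 * (age - 64))))
                      ).astype(float)
        out = exposure_screen(df, ["expo"], "MBL")
        assert out.loc[0, "crude_p"] < 0.01
        assert out.loc[0, "adj_ci_low"] < 1.0 < out.loc[0, "adj_ci_high"]

    def test_single_level_exposure_skipped(self):
        rng = np.random.default_rng(17)
        df = self._base(100, rng)
        df["phenotype"] = np.where(np.arange(100) < 40, "MBL", "control")
        df["expo"] = 1.0
        out = exposure_screen(df, ["expo"], "MBL")
        assert out.loc[0, "note"] == "single_level"

    def test_per_exposure_complete_case_denominators(self):
        rng = np.random.default_rng(18)
        df = self._base(100, rng)
        df["phenotype"] = np.where(np.arange(100) < 40, "MBL", "control")
        df["expo"] = rng.integers(0, 2, 100).astype(float)
        df.loc[:9, "expo"] = np.nan
        out = exposure_screen(df, ["expo"], "MBL")
        assert out.loc[0, "n_cases"] + out.loc[0, "n_controls"] == 90
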