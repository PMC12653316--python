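"""Statistical layer against textbook-formula oracles and simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sct

from qeegratio import (
    AnalysisConfig,
    SimulationConfig,
    analyze_cohort,
    bonferroni,
    dichotomize,
    fit_linear_model,
    pearson,
    shapiro_wilk,
    simulate_ratio_records,
    stratified_models,
    two_sample_t,
)
from qeegratio.stats import education_stratum
from qeegratio.synthetic import null_slopes


# ---------------------------------------------------------------------------
# Textbook oracles

def ols_oracle(y, X):
    """Normal equations with classical covariance."""
    X = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * sct.t.sf(np.abs(t), df)
    return beta, se, p


def t_oracle(a, b):
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) \
        / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sct.t.sf(abs(t), na + nb - 2)
    d = (np.mean(a) - np.mean(b)) / np.sqrt(sp2)
    return t, p, d


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    r = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
    n = len(x)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    return r, 2 * sct.t.sf(abs(t), n - 2)


# ---------------------------------------------------------------------------

class TestDichotomize:
    def test_boundary_is_high(self):
        assert dichotomize(0.78) == "high"

    def test_below_is_low_and_above_is_high(self):
        assert dichotomize(0.50) == "low"
        assert dichotomize(1.20) == "high"

    def test_non_positive_oab_is_an_error(self):
        with pytest.raises(ValueError):
            dichotomize(0.0)


class TestShapiroWilk:
    def test_null_rejection_rate_is_nominal(self):
        rng = np.random.default_rng(0)
        rejected = sum(
            shapiro_wilk(rng.standard_normal(5000))[1] < 0.05
            for _ in range(200))
        lo, hi = sct.binom.ppf([0.005, 0.995], 200, 0.05)
        assert lo <= rejected <= hi

    def test_lognormal_sample_is_detected(self):
        rng = np.random.default_rng(1)
        hits = sum(
            shapiro_wilk(np.exp(rng.standard_normal(200)))[1] < 0.05
            for _ in range(20))
        assert hits >= 19    # power > 0.99 at n = 200

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk(np.full(10, 3.3))


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p, d = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0) and d == 0.0

    def test_hand_computed_example(self):
        t, p, d = two_sample_t([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        assert d == pytest.approx(-2.0)
        assert t == pytest.approx(-2.449, abs=1e-3)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(size=rng.integers(5, 30))
            b = rng.normal(loc=0.3, size=rng.integers(5, 30))
            t, p, d = two_sample_t(a, b)
            to, po, do = t_oracle(a, b)
            assert t == pytest.approx(to, abs=1e-10)
            assert p == pytest.approx(po, abs=1e-10)
            assert d == pytest.approx(do, abs=1e-10)

    def test_tiny_groups_are_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])


class TestPearson:
    def test_perfect_linear_relationships(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = 0.4 * x + rng.normal(size=50)
        r, p = pearson(x, y)
        ro, po = pearson_oracle(x, y)
        assert r == pytest.approx(ro, abs=1e-12)
        assert p == pytest.approx(po, abs=1e-12)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            pearson(np.ones(10), np.arange(10.0))


class TestLinearModel:
    def test_noiseless_slope_recovery(self):
        oab = np.linspace(0.2, 2.5, 30)
        res = fit_linear_model(3.0 - 0.06 * oab, oab)
        assert res.beta == pytest.approx(-0.06, abs=1e-10)
        assert res.model == "unadjusted"

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = 50
            oab = rng.uniform(0.2, 2.5, n)
            cov = pd.DataFrame(rng.normal(size=(n, 3)),
                               columns=["age", "education_years", "kmmse"])
            y = 0.5 - 0.1 * oab + cov.to_numpy() @ [0.2, -0.1, 0.05] \
                + rng.normal(scale=0.3, size=n)
            res = fit_linear_model(y, oab, cov)
            beta, se, p = ols_oracle(y, np.column_stack([oab, cov]))
            assert res.beta == pytest.approx(beta[1], abs=1e-8)
            assert res.se == pytest.approx(se[1], abs=1e-8)
            assert res.p_value == pytest.approx(p[1], abs=1e-8)
            assert res.n_used == n

    def test_standardized_coefficient_scaling(self):
        rng = np.random.default_rng(5)
        oab = rng.uniform(0.2, 2.5, 60)
        y = 1.0 - 0.2 * oab + rng.normal(scale=0.2, size=60)
        res = fit_linear_model(y, oab)
        expected = res.beta * np.std(oab, ddof=1) / np.std(y, ddof=1)
        assert res.beta_standardized == pytest.approx(expected, abs=1e-12)

    def test_complete_case_dropping_is_reported(self):
        oab = np.linspace(0.2, 2.5, 20)
        y = 1.0 - 0.1 * oab
        rng = np.random.default_rng(7)
        cov = pd.DataFrame({"age": np.r_[np.nan, rng.uniform(60, 85, 19)]})
        res = fit_linear_model(y, oab, cov)
        assert res.n_used == 19

    def test_collinear_design_names_the_columns(self):
        oab = np.linspace(0.2, 2.5, 20)
        cov = pd.DataFrame({"age": np.ones(20) * 2.0})  # constant duplicates
        with pytest.raises(ValueError, match="age"):
            fit_linear_model(np.random.default_rng(6).normal(size=20), oab, cov)

    def test_estimator_is_consistent_as_n_grows(self):
        # Bias of the recovered slope shrinks towards 0 with sample size.
        slope = -0.06
        biases = []
        for n in (100, 400, 1600):
            rng = np.random.default_rng(100 + n)
            betas = []
            for _ in range(40):
                oab = np.exp(rng.normal(np.log(0.78), 0.55, n))
                y = 0.6 + slope * oab + rng.normal(scale=0.33, size=n)
                betas.append(fit_linear_model(y, oab).beta)
            biases.append(abs(np.mean(betas) - slope))
            se_mean = np.std(betas, ddof=1) / np.sqrt(len(betas))
            assert biases[-1] < 3 * se_mean + 1e-3
        assert biases[-1] < 0.01

    def test_independent_covariate_leaves_the_slope_expectation(self):
        rng = np.random.default_rng(9)
        diffs = []
        for _ in range(100):
            n = 150
            oab = np.exp(rng.normal(np.log(0.78), 0.55, n))
            cov = pd.DataFrame({"age": rng.normal(75, 8, n)})
            y = 0.6 - 0.06 * oab + rng.normal(scale=0.33, size=n)
            diffs.append(fit_linear_model(y, oab, cov).beta
                         - fit_linear_model(y, oab).beta)
        assert abs(np.mean(diffs)) < 0.005


class TestStratification:
    def test_stratum_assignment(self):
        assert education_stratum(4) == "<=6"
        assert education_stratum(9) == "7-12"
        assert education_stratum(15) == ">12"
        assert education_stratum(6) == "<=6"
        assert education_stratum(12) == "7-12"

    def test_empty_strata_are_flagged_not_omitted(self):
        rng = np.random.default_rng(10)
        n = 30
        edu = np.full(n, 9.0)          # everyone in the middle stratum
        cov = pd.DataFrame({"age": rng.normal(75, 8, n),
                            "kmmse": rng.normal(23, 5, n)})
        y = rng.normal(size=n)
        oab = rng.uniform(0.2, 2.5, n)
        out = stratified_models(y, oab, edu, cov, AnalysisConfig())
        assert [r.stratum for r in out] == ["<=6", "7-12", ">12"]
        assert out[0].empty and out[2].empty
        assert not out[1].empty

    def test_slope_planted_in_one_stratum_is_recovered_there(self):
        rng = np.random.default_rng(11)
        n = 240
        edu = rng.choice([4.0, 9.0, 15.0], n)
        oab = np.exp(rng.normal(np.log(0.78), 0.55, n))
        cov = pd.DataFrame({"age": rng.normal(75, 8, n),
                            "kmmse": rng.normal(23, 5, n)})
        slope = np.where(edu <= 6, -0.2, 0.0)
        y = 0.6 + slope * oab + rng.normal(scale=0.2, size=n)
        out = stratified_models(y, oab, edu, cov, AnalysisConfig())
        low = next(r for r in out if r.stratum == "<=6")
        assert abs(low.beta - (-0.2)) < 2 * low.se
        for r in out:
            if r.stratum != "<=6":
                assert abs(r.beta) < 3 * r.se


class TestBonferroni:
    def test_simple_scaling_and_capping(self):
        assert bonferroni([0.01], 5)[0] == pytest.approx(0.05)
        assert bonferroni([0.5], 3)[0] == 1.0

    def test_elementwise_against_direct_multiplication(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=10)
        np.testing.assert_allclose(bonferroni(p, 10),
                                   np.minimum(1.0, p * 10), atol=1e-15)

    def test_validation(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 5)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_adjusted_values_stay_probabilities(self, ps):
        adj = bonferroni(ps, 20)
        assert np.all((adj >= 0) & (adj <= 1))
        assert np.all(adj >= np.asarray(ps) - 1e-12)


@pytest.fixture(scope="module")
def cohort():
    cfg = SimulationConfig(n_subjects=80, seed=21,
                           planted_slopes=null_slopes())
    return simulate_ratio_records(cfg)


class TestCohortTables:

    def test_all_tables_have_the_expected_shape(self, cohort):
        meta, ratios = cohort
        tables = analyze_cohort(ratios, meta)
        # 2 indices x 5 lobes x (EO, EC, pooled)
        assert tables["group_comparison"].shape[0] == 30
        assert tables["correlations"].shape[0] == 20
        assert tables["regressions"].shape[0] == 40
        assert tables["stratified"].shape[0] == 60
        assert tables["normality"].shape[0] == 20
        assert {"beta", "se", "p_value", "p_bonferroni",
                "beta_standardized"} <= set(tables["regressions"].columns)

    def test_log_ratios_pass_normality_by_construction(self, cohort):
        meta, ratios = cohort
        tables = analyze_cohort(ratios, meta)
        # Gaussian planted noise: most cells should not reject normality.
        assert (tables["normality"]["p_value"] > 0.05).mean() > 0.8

    def test_bonferroni_never_decreases_p(self, cohort):
        meta, ratios = cohort
        reg = analyze_cohort(ratios, meta)["regressions"]
        assert (reg["p_bonferroni"] >= reg["p_value"] - 1e-12).all()
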