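"""Screening stage: variance filter, per-gene logistic fits, selection rule,
covariate associations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from platesig import (
    LogisticGeneScreen,
    VarianceFilter,
    covariate_association,
    fit_gene_logistic,
    screen_all,
    select_by_pvalue,
    variance_filter,
)
from platesig.logistic import fit_logistic

from oracles import (
    brute_force_spearman,
    brute_force_top_variance,
    grid_search_logistic_slope,
)


class TestVarianceFilter:
    def test_dominant_variance_gene_is_the_sole_survivor(self):
        rng = np.random.default_rng(0)
        data = {f"g{i}": rng.normal(0, 1.0, 12) for i in range(10)}
        data["g7"] = rng.normal(0, np.sqrt(5.0), 12) * 10  # variance far above 1
        matrix = pd.DataFrame(data)
        out = variance_filter(matrix, 0.1)
        assert list(out.columns) == ["g7"]

    def test_matches_brute_force_ranking_oracle(self):
        rng = np.random.default_rng(42)
        matrix = pd.DataFrame(
            rng.normal(0, rng.uniform(0.5, 3.0, 50), size=(20, 50)),
            columns=[f"g{i:02d}" for i in range(50)],
        )
        out = variance_filter(matrix, 0.3)
        assert set(out.columns) == brute_force_top_variance(matrix, 15)

    def test_fraction_one_is_identity_on_the_gene_set(self, tiny_matrix):
        out = variance_filter(tiny_matrix, 1.0)
        assert list(out.columns) == list(tiny_matrix.columns)
        assert out.equals(tiny_matrix)

    def test_idempotence(self, tiny_matrix):
        once = variance_filter(tiny_matrix, 0.5)
        assert variance_filter(once, 1.0).equals(once)

    def test_ties_break_lexicographically(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        matrix = pd.DataFrame({"gB": base, "gA": base, "gC": base * 2})
        out = variance_filter(matrix, 2 / 3)
        assert set(out.columns) == {"gC", "gA"}

    def test_zero_genes_is_an_error(self, tiny_matrix):
        with pytest.raises(ValueError, match="0 genes"):
            variance_filter(tiny_matrix, 0.01)

    def test_sample_order_preserved(self, tiny_matrix):
        out = variance_filter(tiny_matrix, 0.5)
        assert list(out.index) == list(tiny_matrix.index)


class TestFitGeneLogistic:
    def test_symmetric_configuration_forces_the_null(self):
        # identical expression multisets in both groups: the likelihood is
        # invariant under label swap, so its unique maximum has slope 0
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0] * 2)
        y = np.array([1] * 6 + [0] * 6)
        r = fit_gene_logistic(x, y)
        assert r.beta == pytest.approx(0.0, abs=1e-8)
        assert r.or_ == pytest.approx(1.0, abs=1e-8)

    def test_matches_grid_search_oracle_on_toy_data(self):
        rng = np.random.default_rng(7)
        for _ in range(8):
            n = int(rng.integers(12, 30))
            y = np.array([0, 1] * (n // 2))
            x = rng.normal(0.7 * y, 1.0)
            if x[y == 1].min() >= x[y == 0].max():
                continue
            r = fit_gene_logistic(x, y, compute_ci=False)
            assert r.beta == pytest.approx(grid_search_logistic_slope(x, y), abs=1e-6)

    def test_matches_statsmodels_on_nonseparated_data(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(21)
        y = np.array([0, 1] * 10)
        x = rng.normal(0.5 * y, 1.0)
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        r = fit_gene_logistic(x, y)
        assert r.beta == pytest.approx(fit.params[1], abs=1e-6)
        assert r.se == pytest.approx(fit.bse[1], rel=1e-4)
        assert r.p == pytest.approx(fit.pvalues[1], rel=1e-4)

    def test_complete_separation_is_flagged_not_raised(self):
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        r = fit_gene_logistic(x, y)
        assert r.separation_flag
        assert abs(r.beta) > 10
        assert np.isfinite(r.beta)
        assert np.isinf(r.ci_high) or np.isinf(r.ci_low)

    def test_profile_ci_inverts_the_likelihood_ratio_test(self):
        # at each CI bound the profile log-likelihood drops by chi2(1)/2
        from scipy.stats import chi2

        from oracles import profile_over_intercept

        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 8)
        x = rng.normal(0.8 * y, 1.0)
        r = fit_gene_logistic(x, y)
        llmax = profile_over_intercept(r.beta, x, y)
        for bound in (np.log(r.ci_low), np.log(r.ci_high)):
            drop = 2 * (llmax - profile_over_intercept(bound, x, y))
            assert drop == pytest.approx(chi2.ppf(0.95, 1), abs=1e-4)

    def test_profile_ci_brackets_the_estimate(self):
        rng = np.random.default_rng(5)
        y = np.array([0, 1] * 10)
        x = rng.normal(0.6 * y, 1.2)
        r = fit_gene_logistic(x, y)
        assert r.ci_low <= r.or_ <= r.ci_high

    def test_single_class_and_constant_x_are_distinct_errors(self):
        with pytest.raises(ValueError, match="single class"):
            fit_gene_logistic(np.arange(6.0), np.ones(6))
        with pytest.raises(ValueError, match="constant expression"):
            fit_gene_logistic(np.ones(6), np.array([0, 1, 0, 1, 0, 1]))

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_gene_logistic(np.array([1.0, 2.0]), np.array([0, 1]))


class TestScreenAll:
    def test_selection_rule_is_strict_threshold(self):
        p = pd.Series(
            {"FKBP5": 0.0026, "S100P": 0.0082, "SAMSN1": 0.0075,
             "S100A12": 0.0017, "CLEC4E": 0.0079, "other": 0.01},
        )
        assert select_by_pvalue(p, 0.01) == [
            "S100A12", "FKBP5", "SAMSN1", "CLEC4E", "S100P"
        ]
        assert select_by_pvalue(p, 0.0017) == []  # strict: equality excluded

    def test_results_sorted_by_p_and_consistent(self, small_cohort):
        matrix, design = small_cohort
        results, selected = screen_all(matrix, design, compute_ci=False)
        assert results["p"].is_monotonic_increasing
        assert set(selected) <= set(results["gene_id"])
        assert ((results["p"] >= 0) & (results["p"] <= 1)).all()
        np.testing.assert_allclose(results["or"], np.exp(results["beta"]))

    def test_spiked_genes_rank_first(self, small_cohort):
        matrix, design = small_cohort
        results, selected = screen_all(matrix, design, compute_ci=False)
        assert {"g0003", "g0047"} <= set(results.head(5)["gene_id"])
        assert {"g0003", "g0047"} <= set(selected)

    def test_or_ci_consistency_on_converged_genes(self, small_cohort):
        matrix, design = small_cohort
        results, _ = screen_all(matrix.iloc[:, :12], design)
        ok = results["converged"] & ~results["separation_flag"]
        sub = results[ok]
        assert (sub["ci_low"] <= sub["or"]).all()
        assert (sub["or"] <= sub["ci_high"]).all()

    def test_label_permutation_equivariance(self, small_cohort):
        matrix, design = small_cohort
        perm = np.random.default_rng(1).permutation(matrix.shape[0])
        r1, s1 = screen_all(matrix, design, compute_ci=False)
        r2, s2 = screen_all(matrix.iloc[perm], design, compute_ci=False)
        pd.testing.assert_frame_equal(r1, r2)
        assert s1 == s2

    def test_alpha_select_zero_warns_and_selects_nothing(self, tiny_matrix, tiny_design):
        with pytest.warns(UserWarning, match="no gene passed"):
            _, selected = screen_all(
                tiny_matrix, tiny_design, alpha_select=0.0, compute_ci=False
            )
        assert selected == []

    def test_per_gene_failures_are_recorded_not_fatal(self, tiny_design):
        matrix = pd.DataFrame(
            {"good": np.arange(6.0), "flat": np.ones(6)},
            index=tiny_design.sample_ids,
        )
        screen = LogisticGeneScreen(compute_ci=False)
        with pytest.warns(UserWarning):
            screen.fit(matrix, tiny_design.y(matrix.index))
        assert "flat" in screen.errors_
        assert list(screen.results_["gene_id"]) == ["good"]

    def test_alpha_ordering_enforced(self, tiny_matrix, tiny_design):
        with pytest.raises(ValueError, match="alpha_select"):
            screen_all(tiny_matrix, tiny_design, alpha_report=0.01, alpha_select=0.05)


class TestCovariateAssociation:
    def test_monotone_transform_gives_rho_one(self):
        expr = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        r = covariate_association(expr, np.exp(expr))
        assert r.rho == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(11)
        expr = rng.normal(size=10)
        cov = np.round(rng.normal(size=10), 1)  # ties likely
        r = covariate_association(expr, cov)
        assert r.rho == pytest.approx(brute_force_spearman(expr, cov), abs=1e-12)

    def test_null_pvalues_are_roughly_uniform(self):
        rng = np.random.default_rng(13)
        ps = [
            covariate_association(rng.normal(size=15), rng.normal(size=15)).p
            for _ in range(400)
        ]
        assert 0.25 < np.mean(ps) < 0.75
        assert np.mean(np.array(ps) < 0.05) < 0.12

    def test_constant_covariate_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            covariate_association(np.arange(5.0), np.ones(5))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 1.0))
def test_filter_selects_floor_fraction_of_genes(seed, fraction):
    rng = np.random.default_rng(seed)
    matrix = pd.DataFrame(
        rng.normal(size=(6, 17)), columns=[f"g{i:02d}" for i in range(17)]
    )
    k = int(np.floor(fraction * 17))
    if k == 0:
        with pytest.raises(ValueError):
            variance_filter(matrix, fraction)
    else:
        assert variance_filter(matrix, fraction).shape == (6, k)
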