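"""Interaction models, simple slopes, FDR, mediation, sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcsleep import (
    CohortSpec,
    bh_fdr,
    fit_interaction_model,
    generate_cohort,
    mediation_analysis,
    pearson_correlation,
    run_primary_models,
    sensitivity_min_effect,
    simple_slopes,
)
from lcsleep.stats import power_one_predictor


def _near_noiseless_cohort(**kw):
    spec = CohortSpec(noise_sd=1e-9, mediator_noise_sd=1e-9, **kw)
    df, truth = generate_cohort(spec, seed=1)
    return df, truth


class TestInteractionModel:
    def test_noiseless_recovery_of_planted_coefficients(self):
        df, _ = _near_noiseless_cohort(slope_young=0.4, slope_old=1.2)
        res = fit_interaction_model(
            df, "psqi", "lc_activity", "age_group", covariates=("sex", "bmi")
        )
        assert res.params["lc_activity"] == pytest.approx(1.2, abs=1e-6)  # ref = old
        assert res.params["interaction"] == pytest.approx(0.4 - 1.2, abs=1e-6)
        assert res.params["bmi"] == pytest.approx(0.1, abs=1e-6)

    def test_parameter_recovery_simulation(self):
        """Mean interaction estimate within 3 MC-SE of the planted 0.8 gap."""
        estimates = []
        for seed in range(200):
            df, _ = generate_cohort(
                CohortSpec(n_young=250, n_old=250, slope_young=0.0, slope_old=0.8),
                seed=seed,
            )
            res = fit_interaction_model(
                df, "psqi", "lc_activity", "age_group", covariates=("sex", "bmi")
            )
            # interaction coefficient = slope(young) - slope(old); its
            # magnitude is the planted group gap
            estimates.append(abs(res.params["interaction"]))
        estimates = np.asarray(estimates)
        mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - 0.8) < 3 * mc_se

    def test_duplicated_covariate_raises_collinearity_error(self):
        df, _ = generate_cohort(CohortSpec(), seed=0)
        df["bmi_copy"] = df["bmi"]
        with pytest.raises(ValueError, match="collinear.*bmi"):
            fit_interaction_model(
                df, "psqi", "lc_activity", "age_group", covariates=("bmi", "bmi_copy")
            )

    def test_non_binary_moderator_errors(self):
        df, _ = generate_cohort(CohortSpec(), seed=0)
        df.loc[df.index[:5], "age_group"] = "middle"
        with pytest.raises(ValueError, match="binary"):
            fit_interaction_model(df, "psqi", "lc_activity", "age_group")

    def test_affine_covariate_rescaling_leaves_p_values_unchanged(self):
        df, _ = generate_cohort(CohortSpec(slope_old=0.6), seed=4)
        res1 = fit_interaction_model(
            df, "psqi", "lc_activity", "age_group", covariates=("sex", "bmi")
        )
        df2 = df.copy()
        df2["bmi"] = 10.0 * df2["bmi"] + 3.0
        res2 = fit_interaction_model(
            df2, "psqi", "lc_activity", "age_group", covariates=("sex", "bmi")
        )
        for term in ("predictor", "moderator", "interaction"):
            assert res1.term_tests[term].p == pytest.approx(
                res2.term_tests[term].p, abs=1e-8
            )

    def test_gamma_family_requires_positive_outcome(self):
        df, _ = generate_cohort(CohortSpec(), seed=0)
        df["psqi"] = df["psqi"] - df["psqi"].max() - 1.0
        with pytest.raises(ValueError, match="positive"):
            fit_interaction_model(df, "psqi", "lc_activity", "age_group", family="gamma")

    def test_partial_r2_formula(self):
        df, _ = generate_cohort(CohortSpec(slope_old=1.0), seed=3)
        res = fit_interaction_model(df, "psqi", "lc_activity", "age_group")
        t = res.term_tests["interaction"]
        assert t.partial_r2 == pytest.approx(t.f * t.df1 / (t.f * t.df1 + t.df2))
        assert 0.0 <= t.partial_r2 <= 1.0


class TestSimpleSlopes:
    def test_zero_interaction_gives_equal_slopes(self):
        # exactly linear data with a common slope in both groups
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        group = np.repeat(["young", "old"], 30)
        df = pd.DataFrame({
            "lc_activity": x,
            "age_group": group,
            "psqi": 2.0 + 0.5 * x + 0.7 * (group == "old"),
        })
        res = fit_interaction_model(df, "psqi", "lc_activity", "age_group")
        s_young, _, _ = simple_slopes(res, "young")
        s_old, _, _ = simple_slopes(res, "old")
        assert s_young == pytest.approx(s_old, abs=1e-10)
        assert s_young == pytest.approx(0.5, abs=1e-10)

    def test_reference_level_swap_invariance(self):
        df, _ = generate_cohort(CohortSpec(slope_old=0.9), seed=6)
        res = fit_interaction_model(df, "psqi", "lc_activity", "age_group")
        # relabel so the other level sorts first, flipping the reference
        df2 = df.copy()
        df2["age_group"] = df2["age_group"].map({"old": "z_old", "young": "a_young"})
        res2 = fit_interaction_model(df2, "psqi", "lc_activity", "age_group")
        for g, g2 in (("young", "a_young"), ("old", "z_old")):
            s1, t1, p1 = simple_slopes(res, g)
            s2, t2, p2 = simple_slopes(res2, g2)
            assert s1 == pytest.approx(s2, abs=1e-8)
            assert p1 == pytest.approx(p2, abs=1e-8)

    def test_unknown_group_errors(self):
        df, _ = generate_cohort(CohortSpec(), seed=0)
        res = fit_interaction_model(df, "psqi", "lc_activity", "age_group")
        with pytest.raises(ValueError, match="unknown group"):
            simple_slopes(res, "middle")

    def test_planted_slope_coverage_over_seeds(self):
        """Old-group slope estimate lands in [0.4, 0.6] for >=95% of seeds."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            df, _ = generate_cohort(
                CohortSpec(n_young=500, n_old=500, slope_young=0.0, slope_old=0.5),
                seed=seed,
            )
            res = fit_interaction_model(
                df, "psqi", "lc_activity", "age_group", covariates=("sex", "bmi")
            )
            slope, _, _ = simple_slopes(res, "old")
            hits += 0.4 <= slope <= 0.6
        assert hits / n_seeds >= 0.95


def _brute_force_bh(p, q):
    """Literal step-up rule: largest k with p(k) <= k q / m, reject smallest k."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    kmax = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= rank * q / m:
            kmax = rank
    rejected = [False] * m
    for i in order[:kmax]:
        rejected[i] = True
    crit = p[order[kmax - 1]] if kmax else 0.0
    return rejected, crit


class TestBhFdr:
    def test_textbook_example(self):
        p = [0.005, 0.01, 0.03, 0.2, 0.5, 0.9]
        rejected, crit, adjusted = bh_fdr(p, q=0.05)
        assert rejected.tolist() == [True, True, False, False, False, False]
        assert crit == 0.01
        assert np.all(np.diff(adjusted[np.argsort(p)]) >= -1e-12)

    def test_all_ones_rejects_nothing(self):
        rejected, crit, _ = bh_fdr([1.0, 1.0, 1.0], q=0.05)
        assert not rejected.any() and crit == 0.0

    def test_single_p_reduces_to_alpha_test(self):
        rejected, crit, adjusted = bh_fdr([0.04], q=0.05)
        assert rejected.tolist() == [True] and crit == 0.04
        assert adjusted[0] == pytest.approx(0.04)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            bh_fdr([], q=0.05)

    def test_brute_force_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = rng.integers(1, 13)
            p = rng.random(m).round(4).tolist()
            q = float(rng.choice([0.01, 0.05, 0.1, 0.2]))
            rej, crit, _ = bh_fdr(p, q=q)
            bf_rej, bf_crit = _brute_force_bh(p, q)
            assert rej.tolist() == bf_rej
            assert crit == pytest.approx(bf_crit)

    def test_adjusted_p_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.random(rng.integers(2, 12))
            rej, _, adjusted = bh_fdr(p.tolist(), q=0.05)
            sm_rej, sm_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(adjusted, sm_adj, atol=1e-12)
            assert rej.tolist() == sm_rej.tolist()


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_correlation([1.0, 2.0], [3.0, 4.0])

    def test_bivariate_normal_simulation(self):
        rho = -0.5
        rs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cov = [[1.0, rho], [rho, 1.0]]
            xy = rng.multivariate_normal([0, 0], cov, size=10_000)
            rs.append(pearson_correlation(xy[:, 0], xy[:, 1])[0])
        assert abs(np.mean(rs) - rho) < 0.02


class TestMediation:
    def test_null_indirect_path(self):
        """a = 0 and no interaction: PIE% ~ 0 inside its bootstrap CI."""
        df, _ = generate_cohort(
            CohortSpec(a=0.0, b=0.6, c_prime=0.8, gamma=0.0, n_young=500, n_old=500),
            seed=2,
        )
        res = mediation_analysis(
            df, "psqi", "lc_activity", "rem_theta_energy",
            covariates=("age_group", "sex", "bmi"),
            n_boot=400, seed=0, transform="sqrt",
        )
        lo, hi = res.pie_percent_ci
        assert lo <= 0.0 <= hi or abs(res.pie_percent) < 5.0

    def test_full_mediation_decomposition(self):
        """c' = 0, gamma = 0: PIE% in [90, 110] and CDE% in [-10, 10]."""
        df, _ = generate_cohort(
            CohortSpec(a=0.8, b=0.8, c_prime=0.0, gamma=0.0, n_young=1000, n_old=1000),
            seed=3,
        )
        res = mediation_analysis(
            df, "psqi", "lc_activity", "rem_theta_energy",
            covariates=("age_group", "sex", "bmi"),
            n_boot=300, seed=1, transform="sqrt",
        )
        assert 90.0 <= res.pie_percent <= 110.0
        assert -10.0 <= res.cde_percent <= 10.0
        assert not res.unstable

    def test_product_of_coefficients_oracle_without_interaction(self):
        """PIE equals a_hat * b_hat from separately fitted working models."""
        df, _ = generate_cohort(
            CohortSpec(a=0.5, b=0.7, c_prime=0.3), seed=4
        )
        m = np.sqrt(df["rem_theta_energy"].to_numpy())
        x = df["lc_activity"].to_numpy()
        y = df["psqi"].to_numpy()
        ones = np.ones_like(x)
        a_hat = np.linalg.lstsq(np.column_stack([ones, x]), m, rcond=None)[0][1]
        b_hat = np.linalg.lstsq(np.column_stack([ones, x, m]), y, rcond=None)[0][2]
        res = mediation_analysis(
            df, "psqi", "lc_activity", "rem_theta_energy",
            n_boot=200, seed=0, transform="sqrt", interaction=False,
        )
        assert res.pie == pytest.approx(a_hat * b_hat, abs=1e-6)

    def test_degenerate_mediator_errors(self):
        df, _ = generate_cohort(CohortSpec(), seed=0)
        df["rem_theta_energy"] = 4.0
        with pytest.raises(ValueError, match="degenerate mediator"):
            mediation_analysis(df, "psqi", "lc_activity", "rem_theta_energy", n_boot=200)

    def test_unstable_total_effect_is_flagged(self):
        # no planted effects and a large cohort: total effect ~ 0
        df, _ = generate_cohort(CohortSpec(n_young=500, n_old=500), seed=5)
        res = mediation_analysis(
            df, "psqi", "lc_activity", "rem_theta_energy",
            n_boot=300, seed=2, transform="sqrt",
        )
        assert res.unstable

    def test_n_boot_floor(self):
        df, _ = generate_cohort(CohortSpec(), seed=0)
        with pytest.raises(ValueError, match="at least 200"):
            mediation_analysis(df, "psqi", "lc_activity", "rem_theta_energy", n_boot=50)


class TestSensitivity:
    def test_study_design_minimum_detectable_effect(self):
        res = sensitivity_min_effect(n=52, alpha=0.05, power=0.8, sides=1, n_covariates=4)
        assert round(res.min_detectable_r, 2) == 0.33
        assert round(res.min_detectable_r2, 2) == 0.11

    def test_power_equals_alpha_limit(self):
        res = sensitivity_min_effect(n=52, alpha=0.05, power=0.05, sides=1, n_covariates=4)
        assert res.min_detectable_r == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_df_errors(self):
        with pytest.raises(ValueError, match="df"):
            sensitivity_min_effect(n=5, n_covariates=4)

    @pytest.mark.parametrize("n,sides,ncov", [(52, 1, 4), (52, 2, 3), (30, 2, 2), (100, 1, 4)])
    def test_inverse_of_power_function(self, n, sides, ncov):
        res = sensitivity_min_effect(n=n, alpha=0.05, power=0.8, sides=sides, n_covariates=ncov)
        achieved = power_one_predictor(res.min_detectable_r, n, 0.05, sides, ncov)
        assert achieved == pytest.approx(0.8, abs=1e-6)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.3, 0.95), st.integers(20, 200))
    def test_min_r_monotone_in_power(self, power, n):
        lo = sensitivity_min_effect(n=n, power=power * 0.9).min_detectable_r
        hi = sensitivity_min_effect(n=n, power=power).min_detectable_r
        assert hi >= lo - 1e-12


class TestPrimaryModels:
    def test_report_always_contains_six_models(self):
        df, _ = generate_cohort(CohortSpec(), seed=0)
        report = run_primary_models(df)
        assert len(report["models"]) == 6
        assert set(report["fdr"]["outcomes"]) == set(report["models"])

    def test_missing_outcome_column_is_named(self):
        df, _ = generate_cohort(CohortSpec(), seed=0)
        with pytest.raises(KeyError, match="swe"):
            run_primary_models(df.drop(columns=["swe"]))

    def test_energy_models_include_tst_covariate(self):
        df, _ = generate_cohort(CohortSpec(), seed=0)
        report = run_primary_models(df)
        assert "tst" in report["models"]["swe"]["coefficients"]
        assert "tst" not in report["models"]["psqi"]["coefficients"]

    def test_planted_effects_detected_on_psqi_and_theta(self):
        """Interaction planted on PSQI and REM theta flagged pre-FDR in >=80% of seeds."""
        n_seeds = 120
        psqi_hits = theta_hits = 0
        null_flags = 0
        for seed in range(n_seeds):
            df, _ = generate_cohort(
                # group slope gap 1.04 ~ interaction f^2 = 0.25 at these group sizes
                CohortSpec(slope_young=0.0, slope_old=1.04),
                seed=seed,
            )
            report = run_primary_models(df)
            fdr = report["fdr"]["outcomes"]
            psqi_hits += fdr["psqi"]["p"] < 0.05
            theta_hits += fdr["rem_theta_energy"]["p"] < 0.05
            null_flags += sum(
                fdr[o]["p"] < 0.05 for o in ("sol", "sleep_efficiency", "rem_percentage", "swe")
            )
        assert psqi_hits / n_seeds >= 0.8
        assert theta_hits / n_seeds >= 0.8
        # the four null outcomes stay near the nominal false-positive rate
        rate = null_flags / (4 * n_seeds)
        assert rate < 0.12
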