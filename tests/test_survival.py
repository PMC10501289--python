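import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbpscore import (
    SimulationConfig,
    concordance_index,
    cox_fit,
    generate_cohort,
    km_fit,
    km_optimal_split_report,
    max_selected_cutoff,
    timedep_cindex,
)
from gbpscore.survival import logrank_zstat

from oracles import allpairs_cindex, hand_logrank_chi2, newton_raphson_cox


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        fit = km_fit([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        tab = fit.tables["all"].set_index("time")
        assert tab.loc[2.0, "survival"] == pytest.approx(0.5)
        assert tab.loc[4.0, "survival"] == pytest.approx(0.0)
        assert (np.diff(tab["survival"]) <= 1e-12).all()
        assert (np.diff(tab["at_risk"]) <= 0).all()

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            km_fit([1.0, 2.0, 3.0], [0, 0, 0])

    def test_six_subject_logrank_matches_hand_table(self):
        """Two groups (1,2,3 vs 2,4,5, all events): chi-square equals the
        observed-vs-expected hand computation to 1e-10."""
        times = np.array([1.0, 2.0, 3.0, 2.0, 4.0, 5.0])
        events = np.ones(6, dtype=int)
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        fit = km_fit(times, events, groups)
        expected = hand_logrank_chi2(times, events, groups)
        assert fit.logrank_statistic == pytest.approx(expected, abs=1e-10)
        assert fit.degrees_of_freedom == 1

    def test_logrank_invariant_to_time_rescaling(self, small_cohort):
        _, _, clin, _, truth = small_cohort
        groups = np.where(truth.latent > 0, "hi", "lo")
        a = km_fit(clin["os_time"], clin["os_event"], groups).logrank_statistic
        b = km_fit(clin["os_time"] * 365.25, clin["os_event"], groups).logrank_statistic
        assert a == pytest.approx(b, rel=1e-12)

    def test_zstat_squared_equals_chi2(self, small_cohort):
        _, _, clin, _, truth = small_cohort
        mask = truth.latent > 0
        z = logrank_zstat(clin["os_time"].to_numpy(), clin["os_event"].to_numpy(), mask)
        chi2 = km_fit(clin["os_time"], clin["os_event"], np.where(mask, "a", "b")).logrank_statistic
        assert z**2 == pytest.approx(chi2, rel=1e-9)


class TestMaxSelectedCutoff:
    def test_min_prop_half_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="min_prop"):
            max_selected_cutoff(rng.standard_normal(50), rng.exponential(1, 50), np.ones(50, int), min_prop=0.5)

    def test_cutoff_is_a_candidate_respecting_min_prop(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal(200)
        times = rng.exponential(1, 200)
        res = max_selected_cutoff(scores, times, np.ones(200, int), min_prop=0.1)
        assert res.cutoff in res.candidates
        frac_high = (scores > res.cutoff).mean()
        assert 0.1 <= frac_high <= 0.9
        assert res.selection_corrected is False

    def test_step_hazard_recovered(self):
        cfg = SimulationConfig(n_samples=400, hazard_coef_latent=-1.2, hazard_step_at=0.0, seed=4)
        _, clin, _, truth = generate_cohort(cfg)
        res = max_selected_cutoff(truth.latent, clin["os_time"].to_numpy(), clin["os_event"].to_numpy())
        band = np.quantile(truth.latent, [0.3, 0.7])
        assert band[0] <= res.cutoff <= band[1]

    def test_null_scores_show_selection_inflation(self):
        """Naive p at the selected cutoff rejects far above the nominal 5%
        under the null — the documented reason for the uncorrected-p flag."""
        rejections = 0
        n_rep = 60
        rng = np.random.default_rng(7)
        for _ in range(n_rep):
            n = 80
            times = rng.exponential(1, n)
            scores = rng.standard_normal(n)
            res = max_selected_cutoff(scores, times, np.ones(n, int))
            rejections += res.p_naive < 0.05
        assert rejections / n_rep > 0.15


class TestCox:
    def test_null_covariate_beta_small(self):
        rng = np.random.default_rng(5)
        n = 500
        times = rng.exponential(1, n)
        events = (rng.random(n) < 0.7).astype(int)
        x = rng.standard_normal(n)
        fit = cox_fit(times, events, pd.DataFrame({"x": x}))
        assert abs(fit.summary.loc["x", "coef"]) <= 0.2

    def test_recovery_matches_independent_newton_raphson(self, small_cohort):
        _, _, clin, _, truth = small_cohort
        fit = cox_fit(clin["os_time"], clin["os_event"], pd.DataFrame({"latent": truth.latent}))
        oracle = newton_raphson_cox(clin["os_time"], clin["os_event"], truth.latent)
        assert fit.summary.loc["latent", "coef"] == pytest.approx(oracle, abs=1e-6)
        assert fit.summary.loc["latent", "ci_low"] <= fit.summary.loc["latent", "ci_high"]
        assert fit.summary.loc["latent", "hr"] > 0

    def test_duplication_near_invariance_and_exact_breslow_invariance(self):
        rng = np.random.default_rng(6)
        n = 80
        x = rng.standard_normal(n)
        times = rng.exponential(1, n) / np.exp(0.5 * x)
        events = np.ones(n, int)
        single = cox_fit(times, events, pd.DataFrame({"x": x})).summary.loc["x", "coef"]
        doubled = cox_fit(
            np.concatenate([times, times]), np.concatenate([events, events]),
            pd.DataFrame({"x": np.concatenate([x, x])}),
        ).summary.loc["x", "coef"]
        # Efron tie handling: near-invariant under duplication
        assert doubled == pytest.approx(single, rel=0.02)
        # the Breslow partial likelihood is exactly invariant
        b1 = newton_raphson_cox(times, events, x)
        b2 = newton_raphson_cox(np.concatenate([times, times]), np.concatenate([events, events]), np.concatenate([x, x]))
        assert b2 == pytest.approx(b1, abs=1e-8)

    def test_affine_covariate_rescaling_scales_beta(self):
        rng = np.random.default_rng(8)
        n = 200
        x = rng.standard_normal(n)
        times = rng.exponential(1, n) / np.exp(0.4 * x)
        events = np.ones(n, int)
        b = cox_fit(times, events, pd.DataFrame({"x": x})).summary.loc["x", "coef"]
        b_scaled = cox_fit(times, events, pd.DataFrame({"x": 10 * x + 3})).summary.loc["x", "coef"]
        assert b_scaled == pytest.approx(b / 10, rel=1e-5)

    def test_missing_covariates_dropped_complete_case(self):
        rng = np.random.default_rng(9)
        n = 100
        x = rng.standard_normal(n)
        x[:10] = np.nan
        fit = cox_fit(rng.exponential(1, n), np.ones(n, int), pd.DataFrame({"x": x}))
        assert fit.n_used == 90 and fit.n_dropped == 10

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], pd.DataFrame({"x": [2.0, 2.0, 2.0, 2.0]}))


class TestConcordance:
    def test_perfect_anti_ordering_gives_one(self):
        c, _ = concordance_index([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], [4.0, 3.0, 2.0, 1.0])
        assert c == 1.0

    def test_worked_four_subject_case_matches_all_pairs(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        risks = [4.0, 3.0, 1.0, 2.0]
        c, n_pairs = concordance_index(times, events, risks)
        oracle_c, oracle_pairs = allpairs_cindex(times, events, risks)
        assert c == pytest.approx(5 / 6) == pytest.approx(oracle_c)
        assert n_pairs == 6 == oracle_pairs

    def test_random_risk_near_half(self):
        rng = np.random.default_rng(10)
        n = 1000
        c, _ = concordance_index(rng.exponential(1, n), np.ones(n, int), rng.standard_normal(n))
        assert c == pytest.approx(0.5, abs=0.03)

    def test_censored_data_matches_all_pairs(self):
        rng = np.random.default_rng(11)
        n = 60
        times = rng.exponential(1, n)
        events = (rng.random(n) < 0.6).astype(int)
        risk = rng.standard_normal(n)
        c, n_pairs = concordance_index(times, events, risk)
        oc, op = allpairs_cindex(times, events, risk)
        assert c == pytest.approx(oc, abs=1e-12) and n_pairs == op

    @given(st.integers(0, 1000))
    @settings(max_examples=20, derandomize=True)
    def test_risk_negation_flips_c(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        times = rng.exponential(1, n)
        risk = rng.standard_normal(n)  # continuous → no risk ties
        c_pos, _ = concordance_index(times, np.ones(n, int), risk)
        c_neg, _ = concordance_index(times, np.ones(n, int), -risk)
        assert c_pos == pytest.approx(1.0 - c_neg, abs=1e-12)


class TestTimeDependentCindex:
    def test_full_follow_up_equals_harrell_without_censoring(self):
        rng = np.random.default_rng(12)
        n = 100
        times = rng.exponential(1, n)
        risk = rng.standard_normal(n)
        curve = timedep_cindex(times, np.ones(n, int), risk, [times.max()])
        c, n_pairs = concordance_index(times, np.ones(n, int), risk)
        assert curve["cindex"].iloc[0] == pytest.approx(c, abs=1e-12)
        assert curve["n_pairs"].iloc[0] == n_pairs

    def test_perfect_risk_ordering_gives_one_everywhere(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        curve = timedep_cindex(times, np.ones(5, int), -times, [2.0, 3.5, 5.0])
        assert (curve["cindex"] == 1.0).all()

    def test_matches_brute_force_on_censored_cohort(self, small_cohort):
        _, _, clin, _, truth = small_cohort
        times = clin["os_time"].to_numpy()
        events = clin["os_event"].to_numpy()
        risk = -truth.latent
        eval_times = np.quantile(times[events == 1], [0.25, 0.5, 0.75])
        curve = timedep_cindex(times, events, risk, eval_times)
        for t, c in zip(curve["time"], curve["cindex"]):
            num, pairs = 0.0, 0
            for i in range(len(times)):
                if events[i] != 1 or times[i] > t:
                    continue
                for j in range(len(times)):
                    if times[i] < times[j]:
                        pairs += 1
                        num += 1.0 if risk[i] > risk[j] else (0.5 if risk[i] == risk[j] else 0.0)
            assert c == pytest.approx(num / pairs, abs=0.02)

    def test_eval_time_before_first_event_rejected(self):
        with pytest.raises(ValueError, match="first event"):
            timedep_cindex([2.0, 3.0, 4.0], [1, 1, 1], [1.0, 2.0, 3.0], [1.0])


class TestPerGeneSplitReport:
    def test_protective_gene_reports_hr_below_one(self, small_cohort):
        _, expr, clin, _, _ = small_cohort
        report = km_optimal_split_report(expr, ["GBP1"], clin["os_time"], clin["os_event"])
        assert report.loc["GBP1", "hr_high_vs_low"] < 1
        assert report.loc["GBP1", "direction"] == "protective"

    def test_null_gene_post_selection_ci_coverage_degraded(self):
        """A survival-independent gene split at its optimal cutoff: the
        post-split HR's 95% CI covers 1 far below the nominal 95% — the
        documented anti-conservativeness of maximal selection (naive
        rejection near 40% under the null with inner-80% candidates)."""
        covered = 0
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = 150
            times = rng.exponential(10, n)
            events = (rng.random(n) < 0.7).astype(int)
            gene = rng.standard_normal(n)
            cut = max_selected_cutoff(gene, times, events)
            high = (gene > cut.cutoff).astype(float)
            fit = cox_fit(times, events, pd.DataFrame({"high": high}))
            row = fit.summary.loc["high"]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert 40 <= covered <= 80

    def test_constant_gene_propagates_cutoff_error(self, small_cohort):
        _, expr, clin, _, _ = small_cohort
        expr = expr.copy()
        expr.loc["FLAT"] = 1.0
        with pytest.raises(ValueError):
            km_optimal_split_report(expr, ["FLAT"], clin["os_time"], clin["os_event"])
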