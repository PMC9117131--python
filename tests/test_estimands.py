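"""Effect measures, analysis sets, categorical tests and design calculations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.stats import chi2_contingency

from pregquit.estimands import (AnalysisSet, TwoByTwoTable, bhapkar_test,
                                build_table, cluster_variance_rr,
                                contamination_example, odds_ratio,
                                odds_ratio_from_table, pearson_chi2,
                                relative_risk, sample_size)
from pregquit.outcomes import classify_cohort
from pregquit.simulate import generate_worked_example_cohort

tables = st.tuples(st.integers(1, 50), st.integers(0, 200),
                   st.integers(1, 50), st.integers(0, 200)).map(
    lambda t: TwoByTwoTable(t[0], t[0] + t[1], t[2], t[2] + t[3]))


class TestRelativeRisk:
    def test_equal_proportions_give_unit_rr(self):
        for k, n in ((3, 10), (25, 569), (1, 2)):
            assert relative_risk(TwoByTwoTable(k, n, k, n)).point == pytest.approx(1.0)

    def test_zero_events_not_calculable(self):
        est = relative_risk(TwoByTwoTable(2, 546, 0, 549))
        assert est.not_calculable

    @settings(max_examples=100, deadline=None)
    @given(tables)
    def test_swapping_arms_inverts_the_estimate(self, t):
        est = relative_risk(t)
        inv = relative_risk(TwoByTwoTable(t.events_arm2, t.total_arm2,
                                          t.events_arm1, t.total_arm1))
        assert inv.point == pytest.approx(1.0 / est.point)
        assert inv.ci_low == pytest.approx(1.0 / est.ci_high)
        assert inv.ci_high == pytest.approx(1.0 / est.ci_low)
        assert inv.p_two_sided == pytest.approx(est.p_two_sided)


class TestOddsRatio:
    def test_identity_at_equal_proportions(self):
        assert odds_ratio(0.5, 0.5) == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None)
    @given(tables)
    def test_proportion_based_or_matches_cross_multiplication(self, t):
        a, n1, b, n2 = t.counts
        if a == n1 or b == n2:
            return
        direct = (a * (n2 - b)) / (b * (n1 - a))
        assert odds_ratio(b / n2, a / n1) == pytest.approx(direct)
        assert odds_ratio_from_table(t) == pytest.approx(direct)


class TestPearsonChi2:
    def test_identical_proportions_give_zero(self):
        stat, df, p = pearson_chi2(TwoByTwoTable(10, 100, 10, 100))
        assert stat == pytest.approx(0.0)
        assert df == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            pearson_chi2(TwoByTwoTable(0, 100, 0, 100))

    @settings(max_examples=100, deadline=None)
    @given(tables)
    def test_matches_scipy_without_correction_and_transposes(self, t):
        a, n1, b, n2 = t.counts
        obs = np.array([[a, n1 - a], [b, n2 - b]])
        if (obs.sum(0) == 0).any() or (obs.sum(1) == 0).any():
            return
        stat, df, p = pearson_chi2(t)
        ref = chi2_contingency(obs, correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        # transposition invariance: arms vs outcome axes interchangeable
        stat_t = chi2_contingency(obs.T, correction=False).statistic
        assert stat == pytest.approx(stat_t)
        # equals z^2 of the pooled two-proportion test
        pp = (a + b) / (n1 + n2)
        z = (a / n1 - b / n2) / math.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
        assert stat == pytest.approx(z * z)


class TestBhapkar:
    def test_symmetric_table_has_zero_statistic(self):
        M = np.array([[5, 3, 2], [3, 7, 1], [2, 1, 9]])
        stat, df, p = bhapkar_test(M)
        assert stat == pytest.approx(0.0)
        assert df == 2 and p == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        M = np.array([[10.0, 7.0], [3.0, 15.0]])
        n = M.sum()
        p12, p21 = M[0, 1] / n, M[1, 0] / n
        expected = n * (p12 - p21) ** 2 / (p12 + p21 - (p12 - p21) ** 2)
        assert bhapkar_test(M)[0] == pytest.approx(expected)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            bhapkar_test(np.ones((2, 3)))

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(1, 40), min_size=9, max_size=9))
    def test_matches_explicit_multinomial_quadratic_form(self, cells):
        """Independent oracle: build the covariance of the marginal-difference
        vector from the full multinomial covariance of the vectorized table."""
        M = np.array(cells, dtype=float).reshape(3, 3)
        n = M.sum()
        k = 3
        p = (M / n).ravel()
        A = np.zeros((k - 1, k * k))
        for i in range(k - 1):
            for r in range(k):
                for c in range(k):
                    A[i, r * k + c] = (r == i) - (c == i)
        d = A @ p
        S = A @ ((np.diag(p) - np.outer(p, p)) / n) @ A.T
        expected = float(d @ np.linalg.solve(S, d)) if not np.allclose(d, 0) else 0.0
        assert bhapkar_test(M)[0] == pytest.approx(expected, rel=1e-9)


class TestSampleSize:
    def test_power_monotonicity(self):
        ns = [sample_size(0.08, 0.14, 0.05, pw).n_per_arm
              for pw in (0.5, 0.7, 0.8, 0.9, 0.95)]
        assert ns == sorted(ns)

    def test_equal_proportions_rejected(self):
        with pytest.raises(ValueError, match="no detectable difference"):
            sample_size(0.1, 0.1)

    def test_formula_n_achieves_nominal_power_by_simulation(self):
        """The pooled-variance formula n reaches the nominal rejection rate in
        a direct simulation of the pooled two-proportion z-test (it may be
        mildly conservative, never anti-conservative)."""
        dc = sample_size(0.10, 0.30, 0.05, 0.80)
        rng = np.random.default_rng(42)
        reps, n = 40000, dc.n_per_arm
        x1 = rng.binomial(n, 0.10, reps)
        x2 = rng.binomial(n, 0.30, reps)
        pp = (x1 + x2) / (2 * n)
        se = np.sqrt(2 * pp * (1 - pp) / n)
        z = np.abs(x2 / n - x1 / n) / np.where(se > 0, se, np.inf)
        power = float((z > stats.norm.ppf(0.975)).mean())
        assert 0.80 <= power <= 0.85


@pytest.fixture(scope="module")
def worked_calls():
    cohort = generate_worked_example_cohort(100, 0.10, 0.20, 1.0, 0.5)
    return classify_cohort(cohort)


class TestAnalysisSets:

    def test_itt_keeps_everyone(self, worked_calls):
        t = build_table(worked_calls, "self_prolonged_eop", AnalysisSet.ITT)
        assert t.counts == (28, 100, 24, 100)

    def test_abstinent_switcher_exclusion_shrinks_both_margins(self, worked_calls):
        t = build_table(worked_calls, "self_prolonged_eop",
                        AnalysisSet.EXCLUDE_ABSTINENT_SWITCHERS)
        assert t.counts == (10, 82, 20, 96)

    def test_reclassification_keeps_denominators(self, worked_calls):
        t = build_table(worked_calls, "self_prolonged_eop",
                        AnalysisSet.RECLASSIFY_SWITCHERS)
        assert t.counts == (10, 100, 20, 100)

    def test_no_switchers_makes_all_sets_identical(self):
        calls = classify_cohort(
            generate_worked_example_cohort(100, 0.10, 0.20, 0.0, 0.0))
        counts = {s: build_table(calls, "self_prolonged_eop", s).counts
                  for s in AnalysisSet}
        assert len(set(counts.values())) == 1

    def test_per_protocol_drops_non_starters_and_never_contacted(self, trial_calls):
        t_itt = build_table(trial_calls, "validated_prolonged_eop", AnalysisSet.ITT)
        t_pp = build_table(trial_calls, "validated_prolonged_eop",
                           AnalysisSet.PER_PROTOCOL)
        expected = int(trial_calls["in_per_protocol"].sum())
        assert t_pp.total_arm1 + t_pp.total_arm2 == expected
        assert t_pp.total_arm1 < t_itt.total_arm1

    def test_exclusion_never_changes_numerator_without_abstinent_switchers(
            self, trial_calls):
        t_full = build_table(trial_calls, "self_pp_4wk",
                             AnalysisSet.EXCLUDE_ABSTINENT_SWITCHERS)
        # the numerator only drops by the arm's own abstinent switchers
        switch_events = trial_calls[
            (trial_calls["arm"] == "ECIG") & trial_calls["abstinent_switcher"]
            & trial_calls["self_pp_4wk"]]
        t_itt = build_table(trial_calls, "self_pp_4wk", AnalysisSet.ITT)
        assert t_full.events_arm1 == t_itt.events_arm1 - len(switch_events)


class TestContaminationExample:
    def test_reproduces_the_published_arithmetic(self):
        rates = contamination_example(100, 0.10, 0.20, 1.0, 0.5)
        assert rates["itt"]["A"] == pytest.approx(28.0)
        assert rates["itt"]["B"] == pytest.approx(24.0)
        assert rates["exclude_all_switchers"]["A"] == pytest.approx(100.0)
        assert round(rates["exclude_all_switchers"]["B"]) == 33
        assert round(rates["exclude_abstinent_switchers"]["A"]) == 12
        assert round(rates["exclude_abstinent_switchers"]["B"]) == 21

    def test_no_contamination_returns_true_rates_everywhere(self):
        rates = contamination_example(100, 0.10, 0.20, 0.0, 0.0)
        for estimand in ("itt", "exclude_all_switchers",
                         "exclude_abstinent_switchers"):
            assert rates[estimand]["A"] == pytest.approx(10.0)
            assert rates[estimand]["B"] == pytest.approx(20.0)

    def test_abstinent_only_exclusion_is_least_biased_on_a_random_grid(self):
        """The trial's methodological claim: excluding only abstinent
        switchers lands closer to the true rates (max absolute deviation over
        both arms) than either ITT-with-crossover or all-switcher exclusion."""
        rng = np.random.default_rng(7)
        for _ in range(300):
            pA, pB = rng.uniform(0.02, 0.6, 2)
            fA, fB = rng.uniform(0.05, 1.0, 2)
            rates = contamination_example(1, pA, pB, fA, fB,
                                          integer_bookkeeping=False)
            def dev(estimand):
                return max(abs(rates[estimand]["A"] - 100 * pA),
                           abs(rates[estimand]["B"] - 100 * pB))
            d_abst = dev("exclude_abstinent_switchers")
            assert d_abst <= dev("itt") + 1e-9
            assert d_abst <= dev("exclude_all_switchers") + 1e-9


class TestClusterVarianceRR:
    def test_singleton_clusters_recover_the_wald_interval(self):
        rng = np.random.default_rng(1)
        n = 2000
        arms = np.array(["ECIG"] * n + ["NRT"] * n)
        events = np.concatenate([rng.random(n) < 0.15,
                                 rng.random(n) < 0.10]).astype(int)
        est = cluster_variance_rr(events, arms, np.arange(2 * n),
                                  n_boot=2000, seed=5)
        t = TwoByTwoTable(int(events[:n].sum()), n, int(events[n:].sum()), n)
        wald = relative_risk(t)
        assert est.point == pytest.approx(wald.point)
        hw_boot = math.log(est.ci_high / est.ci_low) / 2
        hw_wald = math.log(wald.ci_high / wald.ci_low) / 2
        assert abs(hw_boot - hw_wald) / hw_wald < 0.02

    def test_duplicating_observations_within_clusters_keeps_the_point(self):
        rng = np.random.default_rng(2)
        n = 500
        arms = np.array(["ECIG"] * n + ["NRT"] * n)
        events = np.concatenate([rng.random(n) < 0.2,
                                 rng.random(n) < 0.3]).astype(int)
        ids = np.arange(2 * n)
        single = cluster_variance_rr(events, arms, ids, n_boot=200, seed=3)
        doubled = cluster_variance_rr(np.repeat(events, 2), np.repeat(arms, 2),
                                      np.repeat(ids, 2), n_boot=200, seed=3)
        assert doubled.point == pytest.approx(single.point)

    def test_coverage_on_correlated_twin_cohorts(self):
        """Percentile bootstrap covers the true RR 92-98% of the time over
        500 synthetic twin cohorts with within-pair correlation."""
        def twin_events(rng, n_pairs, p, rho):
            shared = rng.random(n_pairs) < p
            use_shared = rng.random((n_pairs, 2)) < rho
            indiv = rng.random((n_pairs, 2)) < p
            return np.where(use_shared, shared[:, None], indiv).astype(int)

        p1, p2, cover = 0.3, 0.2, 0
        for i in range(500):
            rng = np.random.default_rng(100 + i)
            e1 = twin_events(rng, 150, p1, 0.5)
            e2 = twin_events(rng, 150, p2, 0.5)
            events = np.concatenate([e1.ravel(), e2.ravel()])
            arms = np.array(["ECIG"] * 300 + ["NRT"] * 300)
            ids = np.concatenate([np.repeat(np.arange(150), 2),
                                  np.repeat(np.arange(150, 300), 2)])
            est = cluster_variance_rr(events, arms, ids, n_boot=500, seed=i)
            cover += est.ci_low <= p1 / p2 <= est.ci_high
        assert 0.92 <= cover / 500 <= 0.98
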