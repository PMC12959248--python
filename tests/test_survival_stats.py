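import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from melmorph import survival as sv
from melmorph.errors import FitError

from _oracles import (auc_mannwhitney, concordance_bruteforce,
                      cox_score_statistic, km_by_hand, logrank_two_group)


class TestLogTransform:
    def test_exact_values(self):
        np.testing.assert_allclose(
            sv.log_transform([1.0, np.e, np.e**2]), [0, 1, 2], atol=1e-12)

    def test_zero_rejected_with_case_ids(self):
        with pytest.raises(FitError, match="bad_case"):
            sv.log_transform([1.0, 0.0], case_ids=["ok", "bad_case"])

    def test_lognormal_sample_symmetrized(self, rng):
        x = rng.lognormal(0.5, 1.0, size=20000)
        assert sps.skew(x) > 1.0
        assert abs(sps.skew(sv.log_transform(x))) < 0.05


class TestQuartileGroups:
    def test_eight_distinct_values_split_evenly(self):
        g = sv.quartile_groups(np.arange(1.0, 9.0))
        assert [list(g).count(f"Q{i}") for i in (1, 2, 3, 4)] == [2, 2, 2, 2]

    def test_group_sizes_within_one_for_distinct_values(self, rng):
        g = sv.quartile_groups(rng.normal(size=10))
        counts = [list(g).count(f"Q{i}") for i in (1, 2, 3, 4)]
        assert max(counts) - min(counts) <= 1

    def test_boundary_ties_take_lower_group(self):
        v = np.array([1, 1, 1, 2, 2, 2, 3, 3])
        g = sv.quartile_groups(v)
        # every value equal to the 25% quantile goes to Q1
        q1 = np.quantile(v, 0.25)
        assert all(lab == "Q1" for val, lab in zip(v, g) if val <= q1)

    def test_identical_values_rejected(self):
        with pytest.raises(FitError, match="quartile"):
            sv.quartile_groups(np.ones(8))


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        c = sv.km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(
            [c.survival_at(1), c.survival_at(2), c.survival_at(3)],
            [2 / 3, 1 / 3, 0], atol=1e-12)

    def test_all_censored_stays_at_one(self):
        c = sv.km_estimate([1, 2, 3], [0, 0, 0])
        assert c.survival_at(3) == 1.0

    def test_mixed_hand_example(self):
        # events at 1, 3; censored at 2, 4, 5
        c = sv.km_estimate([1, 2, 3, 4, 5], [1, 0, 1, 0, 0])
        assert c.survival_at(1) == pytest.approx(4 / 5)
        assert c.survival_at(3) == pytest.approx(8 / 15)

    def test_matches_hand_product_limit_on_random_data(self, rng):
        t = rng.exponential(1, 40).round(2)
        e = (rng.random(40) < 0.6).astype(int)
        ot, os_ = km_by_hand(t, e)
        c = sv.km_estimate(t, e)
        for u, s in zip(ot, os_):
            assert c.survival_at(u) == pytest.approx(s, abs=1e-12)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(1, 50)
        c = sv.km_estimate(t, np.ones(50, int))
        for u in rng.choice(t, 10):
            assert c.survival_at(u) == pytest.approx((t > u).mean(), abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(FitError):
            sv.km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0] * 2
        g = ["a"] * 5 + ["b"] * 5
        chi2, df, p = sv.logrank_test(t, e, g)
        assert chi2 == pytest.approx(0, abs=1e-9)
        assert p == pytest.approx(1, abs=1e-9)

    def test_four_groups_have_three_df(self, rng):
        t = rng.exponential(1, 40)
        e = np.ones(40, int)
        g = np.repeat(list("abcd"), 10)
        _, df, _ = sv.logrank_test(t, e, g)
        assert df == 3

    def test_single_group_rejected(self):
        with pytest.raises(FitError):
            sv.logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_matches_hand_two_group_statistic(self, rng):
        t = rng.exponential(1, 30)
        e = (rng.random(30) < 0.7).astype(int)
        g = (rng.random(30) < 0.5).astype(int)
        chi2, _, _ = sv.logrank_test(t, e, g)
        assert chi2 == pytest.approx(logrank_two_group(t, e, g), rel=1e-9)


class TestHarrellsC:
    def test_perfect_ordering(self):
        assert sv.harrells_c([4, 3, 2, 1], [1, 2, 3, 4], [1, 1, 1, 1]) == 1.0

    def test_random_scores_near_half(self, rng):
        n = 800
        c = sv.harrells_c(rng.normal(size=n), rng.exponential(1, n),
                          np.ones(n, int))
        assert c == pytest.approx(0.5, abs=0.05)

    def test_censored_toy_set_equals_enumeration(self):
        r = [2.0, 1.0, 3.0, 1.5]
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 0]
        assert sv.harrells_c(r, t, e) == concordance_bruteforce(r, t, e)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 31))
            r = rng.choice([0.1, 0.5, 0.9, 1.3], size=n)  # induces score ties
            t = rng.integers(1, 10, size=n).astype(float)  # induces time ties
            e = (rng.random(n) < 0.7).astype(int)
            if not ((e == 1) & (t < t.max())).any():
                continue
            assert sv.harrells_c(r, t, e) == pytest.approx(
                concordance_bruteforce(r, t, e), abs=1e-12)

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(FitError):
            sv.harrells_c([1, 2], [5, 5], [1, 1])


class TestCoxLogrankIdentity:
    def test_score_test_equals_logrank_statistic(self, rng):
        """Classical identity: Cox score test at beta=0 for one binary
        covariate with no tied event times equals the 2-group log-rank."""
        n = 60
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / np.exp(0.5 * x))  # continuous: no ties
        e = (rng.random(n) < 0.8).astype(int)
        score = cox_score_statistic(t, e, x)
        chi2, _, _ = sv.logrank_test(t, e, x)
        assert chi2 == pytest.approx(score, abs=1e-6)


def _sim_cohort(rng, n, beta=0.0):
    x = rng.lognormal(0.5, 0.6, n)
    eta = beta * (np.log(x) - 0.5)
    t = rng.exponential(1 / np.exp(eta))
    c = rng.exponential(2.0, n)
    return pd.DataFrame({
        "case_id": [str(i) for i in range(n)],
        "dbt": x,
        "age": rng.normal(60, 10, n),
        "sex": rng.choice(["male", "female"], n),
        "site": rng.choice(["central", "peripheral"], n),
        "time_os": np.minimum(t, c),
        "event_os": (t <= c).astype(int),
        "time_mss": np.minimum(t, c),
        "event_mss": (t <= c).astype(int),
    })


class TestFitCox:
    def test_null_covariate_hazard_ratio_near_one(self, rng):
        cover = sum(
            1 for s in range(20)
            if (lambda r: r.ci_low <= 1.0 <= r.ci_high)(
                sv.fit_cox(_sim_cohort(np.random.default_rng(s), 400), "dbt",
                           adjusted=False, compute_c=False)))
        assert cover >= 17

    def test_true_hazard_ratio_inside_wald_ci_most_seeds(self):
        beta = np.log(2.0)
        cover = 0
        for s in range(12):
            df = _sim_cohort(np.random.default_rng(100 + s), 2000, beta=beta)
            r = sv.fit_cox(df, "dbt", adjusted=False, compute_c=False)
            cover += r.ci_low <= 2.0 <= r.ci_high
        assert cover >= 10

    def test_missing_covariates_dropped_and_counted(self, rng):
        df = _sim_cohort(rng, 200, beta=0.5)
        df.loc[:4, "site"] = np.nan
        r = sv.fit_cox(df, "dbt", adjusted=True)
        assert r.n_dropped == 5
        assert r.n == 195

    def test_nonpositive_parameter_rejected(self, rng):
        df = _sim_cohort(rng, 50)
        df.loc[3, "dbt"] = 0.0
        with pytest.raises(FitError):
            sv.fit_cox(df, "dbt", adjusted=False)


class TestBootstrapCox:
    def test_same_seed_identical_ci(self, rng):
        df = _sim_cohort(rng, 120, beta=0.5)
        ci1 = sv.bootstrap_cox(df, "dbt", B=25, seed=42)
        ci2 = sv.bootstrap_cox(df, "dbt", B=25, seed=42)
        assert ci1 == ci2

    def test_single_replicate_degenerate_ci(self, rng):
        df = _sim_cohort(rng, 120, beta=0.5)
        lo, hi = sv.bootstrap_cox(df, "dbt", B=1, seed=7)
        assert lo == pytest.approx(hi)

    def test_seed_required(self, rng):
        with pytest.raises(FitError):
            sv.bootstrap_cox(_sim_cohort(rng, 50), "dbt", B=2)

    def test_percentile_ci_coverage_at_reduced_scale(self):
        """Nested Monte-Carlo: the percentile CI covers the generating
        hazard ratio in most outer replicates (reduced scale)."""
        hr_true = np.exp(0.6)
        cover = 0
        outer = 30
        for s in range(outer):
            df = _sim_cohort(np.random.default_rng(500 + s), 120, beta=0.6)
            lo, hi = sv.bootstrap_cox(df, "dbt", adjusted=False, B=120,
                                      seed=1000 + s)
            cover += lo <= hr_true <= hi
        assert cover >= 24  # ~95% nominal, binomial slack at 30 replicates


class TestSchoenfeld:
    def test_output_has_per_covariate_and_global_pvalues(self, rng):
        df = _sim_cohort(rng, 300, beta=0.4)
        r = sv.fit_cox(df, "dbt", adjusted=True)
        out = sv.schoenfeld_ph_check(r)
        assert set(out["p"]) == {"log_dbt", "age", "sex_male", "site_central",
                                 "global"}

    def test_null_pvalues_not_concentrated_low(self):
        ps = []
        for s in range(15):
            df = _sim_cohort(np.random.default_rng(200 + s), 250, beta=0.4)
            r = sv.fit_cox(df, "dbt", adjusted=False)
            ps.append(sv.schoenfeld_ph_check(r)["p"]["log_dbt"])
        assert np.mean(np.array(ps) < 0.05) <= 0.2
        assert np.mean(ps) > 0.25

    def test_reversing_effect_detected(self):
        detected = 0
        for s in range(5):
            rng = np.random.default_rng(300 + s)
            n = 400
            x = rng.integers(0, 2, n).astype(float)
            # effect +1.5 before t0, -1.5 after: a strong PH violation
            t0 = 0.5
            u = rng.exponential(1, n)
            h1, h2 = np.exp(1.5 * x), np.exp(-1.5 * x)
            t = np.where(u < h1 * t0, u / h1, t0 + (u - h1 * t0) / h2)
            df = pd.DataFrame({
                "dbt": np.exp(x), "time_os": t, "event_os": np.ones(n, int),
                "time_mss": t, "event_mss": np.ones(n, int),
            })
            r = sv.fit_cox(df, "dbt", adjusted=False)
            p = sv.schoenfeld_ph_check(r)["p"]["global"]
            detected += p < 0.01
        assert detected >= 4


class TestLogisticRoc:
    def _cohort(self, scores, cases):
        n = len(scores)
        return pd.DataFrame({
            "dbt": np.asarray(scores, float),
            "time_mss": np.where(cases, 2.0, 6.0),
            "event_mss": np.asarray(cases, int),
        })

    def test_auc_trapezoid_equals_mannwhitney(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 51))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = rng.choice([0.1, 0.3, 0.5, 0.9], n)
            assert sv.roc_auc(y, s) == pytest.approx(auc_mannwhitney(y, s),
                                                     abs=1e-12)

    def test_four_point_hand_example(self):
        # controls 0.1, 0.4; cases 0.35, 0.8 -> 3 of 4 pairs concordant
        y = [0, 0, 1, 1]
        s = [0.1, 0.4, 0.35, 0.8]
        assert sv.roc_auc(y, s) == pytest.approx(auc_mannwhitney(y, s))
        assert sv.roc_auc(y, s) == pytest.approx(0.75)

    def test_constant_predictor_gives_chance_auc(self, rng):
        n = 60
        cases = rng.random(n) < 0.4
        df = self._cohort(np.ones(n), cases)
        r = sv.logistic_5yr(df, ("dbt",), log_morph=False)
        assert r.auc == 0.5

    def test_separating_predictor_rejected(self, rng):
        n = 40
        cases = np.r_[np.ones(15, bool), np.zeros(25, bool)]
        scores = np.r_[np.linspace(2, 3, 15), np.linspace(0.1, 1, 25)]
        with pytest.raises(FitError, match="separation"):
            sv.logistic_5yr(self._cohort(scores, cases), ("dbt",))

    def test_censored_before_horizon_excluded(self, rng):
        n = 200
        df = pd.DataFrame({
            "dbt": rng.lognormal(0.5, 0.5, n),
            "time_mss": rng.uniform(0, 10, n),
            "event_mss": (rng.random(n) < 0.4).astype(int),
        })
        r = sv.logistic_5yr(df, ("dbt",))
        early_censor = ((df.event_mss == 0) & (df.time_mss < 5)).sum()
        assert r.n_excluded == early_censor
        assert r.n_used == n - early_censor

    def test_too_few_events_rejected(self, rng):
        df = self._cohort(rng.normal(2, 0.1, 30), np.r_[np.ones(5, bool),
                                                        np.zeros(25, bool)])
        with pytest.raises(FitError, match="events"):
            sv.logistic_5yr(df, ("dbt",))


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert sv.spearman(x, x**3) == pytest.approx(1.0)
        assert sv.spearman(x, -x) == pytest.approx(-1.0)

    def test_tied_rank_toy_set_matches_hand_midranks(self):
        x = [1.0, 2.0, 2.0, 3.0]       # mid-ranks 1, 2.5, 2.5, 4
        y = [10.0, 20.0, 30.0, 30.0]   # mid-ranks 1, 2, 3.5, 3.5
        rx = np.array([1, 2.5, 2.5, 4.0])
        ry = np.array([1, 2.0, 3.5, 3.5])
        hand = np.corrcoef(rx, ry)[0, 1]
        assert sv.spearman(x, y) == pytest.approx(hand, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(FitError):
            sv.spearman([1, 1, 1], [1, 2, 3])


class TestWilcoxon:
    def test_identical_distributions_pvalue_near_one(self):
        v = np.r_[np.arange(20.0), np.arange(20.0)]
        g = np.r_[np.zeros(20), np.ones(20)]
        _, p = sv.wilcoxon_subgroup(v, g)
        assert p > 0.9

    def test_exact_small_sample_no_overlap(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        g = ["a", "a", "a", "b", "b", "b"]
        _, p = sv.wilcoxon_subgroup(v, g)
        assert p == pytest.approx(0.1, abs=1e-12)  # 2 / C(6,3)

    def test_large_shift_strongly_significant(self):
        hits = 0
        for s in range(3):
            rng = np.random.default_rng(s)
            v = np.r_[rng.normal(0, 1, 60), rng.normal(2.0, 1, 60)]
            g = np.r_[np.zeros(60), np.ones(60)]
            _, p = sv.wilcoxon_subgroup(v, g)
            hits += p < 0.001
        assert hits == 3

    def test_empty_group_rejected(self):
        with pytest.raises(FitError):
            sv.wilcoxon_subgroup([1.0, 2.0], ["a", "a"])
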