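import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from bimeta.dataio import ClinicalTable
from bimeta.errors import NotEstimableError, RankDeficiencyError
from bimeta.survival import (
    SurvivalEffect,
    cox_fit,
    km_estimate,
    logrank_test,
    meta_random_effects,
    run_survival_screen,
)


def make_clinical(time, event, **covs):
    idx = pd.Index([f"s{i}" for i in range(len(time))], name="sample_id")
    return ClinicalTable("c", pd.DataFrame({"time": time, "event": event, **covs},
                                           index=idx))


def efron_loglik_scalar(beta, time, event, x):
    """Reference Efron partial log-likelihood for one covariate (brute force)."""
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        risk = time >= t
        tied = (time == t) & (event == 1)
        d = tied.sum()
        s_r = np.exp(beta * x[risk]).sum()
        s_d = np.exp(beta * x[tied]).sum()
        ll += beta * x[tied].sum()
        for l in range(d):
            ll -= np.log(s_r - (l / d) * s_d)
    return ll


class TestCox:
    def test_matches_grid_search_on_toy(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        clin = make_clinical(time, event)
        eff = cox_fit(clin, {"x": x})[0]
        grid = np.arange(-4.0, 4.0, 5e-4)
        lls = [efron_loglik_scalar(b, time, event, x) for b in grid]
        assert eff.log_hr == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)

    def test_agrees_with_lifelines_with_ties(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(3)
        n = 120
        x = rng.binomial(1, 0.4, n).astype(float)
        t = np.ceil(rng.exponential(1 / (0.2 * np.exp(0.6 * x))))
        c = rng.exponential(8, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        eff = cox_fit(make_clinical(time, event), {"x": x})[0]
        cph = CoxPHFitter().fit(
            pd.DataFrame({"time": time, "event": event, "x": x}), "time", "event")
        assert eff.log_hr == pytest.approx(cph.summary.loc["x", "coef"], abs=1e-3)
        assert eff.se == pytest.approx(cph.summary.loc["x", "se(coef)"], abs=1e-3)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(8)
        n = 80
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1 / (0.2 * np.exp(0.5 * x)))
        clin = make_clinical(t, np.ones(n, dtype=int))
        a = cox_fit(clin, {"x": x})[0]
        b = cox_fit(clin, {"x": 1.0 - x})[0]
        assert a.log_hr == pytest.approx(-b.log_hr, abs=1e-6)
        assert a.se == pytest.approx(b.se, abs=1e-8)

    def test_null_coverage(self):
        """Binary predictor independent of survival: 95% CI covers 0 ~nominally."""
        rng = np.random.default_rng(15)
        n = 60
        covered = 0
        reps = 200
        for _ in range(reps):
            x = rng.binomial(1, 0.5, n).astype(float)
            t = rng.exponential(5.0, n)
            c = np.minimum(10.0, rng.exponential(12.0, n))
            clin = make_clinical(np.minimum(t, c), (t <= c).astype(int))
            eff = cox_fit(clin, {"x": x})[0]
            lo, hi = eff.ci()
            covered += lo <= 0.0 <= hi
        assert covered / reps >= 0.90

    def test_duplicated_predictor_is_rank_deficient(self):
        x = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        clin = make_clinical(np.arange(1.0, 7.0), np.ones(6, dtype=int))
        with pytest.raises(RankDeficiencyError):
            cox_fit(clin, {"a": x, "b": x})

    def test_too_few_events(self):
        clin = make_clinical([1.0, 2.0, 3.0], [0, 0, 1])
        with pytest.raises(NotEstimableError):
            cox_fit(clin, {"x": np.array([0.0, 1.0, 0.0])})

    def test_separation_flagged_not_raised(self):
        # all events in one group, none in the other -> monotone likelihood
        x = np.array([1.0] * 10 + [0.0] * 10)
        time = np.concatenate([np.linspace(1, 2, 10), np.linspace(5, 6, 10)])
        event = np.array([1] * 10 + [0] * 10)
        eff = cox_fit(make_clinical(time, event), {"x": x})[0]
        assert not eff.converged
        assert np.isinf(eff.log_hr)

    def test_multivariate_terms(self):
        rng = np.random.default_rng(44)
        n = 150
        x = rng.binomial(1, 0.4, n).astype(float)
        age = rng.normal(65, 8, n)
        t = rng.exponential(1 / (0.05 * np.exp(0.7 * x + 0.02 * (age - 65))))
        c = np.minimum(15.0, rng.exponential(20.0, n))
        clin = make_clinical(np.minimum(t, c), (t <= c).astype(int))
        effs = cox_fit(clin, pd.DataFrame({"x": x, "age": age},
                                          index=clin.data.index))
        assert [e.mode for e in effs] == ["x", "age"]
        assert effs[0].log_hr > 0


class TestLogrank:
    def test_identical_groups_give_null(self):
        time = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        event = np.array([1, 1, 1, 1, 0, 0])
        groups = np.array([0, 1, 0, 1, 0, 1])
        stat, p = logrank_test(time, event, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_tables(self):
        # groups A: (1,death),(3,death),(5,censor); B: (2,death),(4,death),(6,death)
        time = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        event = np.array([1, 1, 0, 1, 1, 1])
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        # hand computation of observed-minus-expected for group A:
        o_minus_e = 0.0
        var = 0.0
        for t in [1.0, 2.0, 3.0, 4.0, 6.0]:
            at_risk = time >= t
            n_tot = at_risk.sum()
            n_a = (at_risk & (groups == "A")).sum()
            d = ((time == t) & (event == 1)).sum()
            d_a = ((time == t) & (event == 1) & (groups == "A")).sum()
            o_minus_e += d_a - d * n_a / n_tot
            if n_tot > 1:
                var += d * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d) / (n_tot - 1)
        expected_stat = o_minus_e ** 2 / var
        stat, _ = logrank_test(time, event, groups)
        assert stat == pytest.approx(expected_stat, rel=1e-10)

    def test_symmetric_under_label_swap(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        groups = np.array([0, 1, 1, 0, 1, 0])
        s1, p1 = logrank_test(time, event, groups)
        s2, p2 = logrank_test(time, event, 1 - groups)
        assert s1 == pytest.approx(s2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])


class TestKM:
    def test_all_censored_is_flat_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.at(0.0) == 1.0
        assert km.at(5.0) == 1.0

    def test_three_events_closed_form(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert km.at(1.0) == pytest.approx(2 / 3)
        assert km.at(2.0) == pytest.approx(1 / 3)
        assert km.at(3.0) == pytest.approx(0.0)

    def test_negative_times_rejected(self):
        from bimeta.errors import DomainError
        with pytest.raises(DomainError):
            km_estimate([-1.0, 2.0], [1, 1])

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(3, 200)
        e = rng.binomial(1, 0.7, 200)
        km = km_estimate(t, e)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km.survival[0] <= 1.0


class TestMeta:
    def test_single_study_identity(self):
        eff = SurvivalEffect("c1", "g", "binary", log_hr=0.4, se=0.1, p=0.01,
                             n=50, n_events=30)
        res = meta_random_effects([eff])
        assert res.pooled_log_hr == pytest.approx(0.4)
        assert res.pooled_se == pytest.approx(0.1)
        assert res.tau2 == 0.0
        assert res.k == 1

    def test_homogeneous_effects_collapse(self):
        res = meta_random_effects(([0.3, 0.3, 0.3], [0.1, 0.2, 0.4]))
        assert res.tau2 == 0.0
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.pooled_log_hr == pytest.approx(0.3)

    def test_equal_ses_give_arithmetic_mean(self):
        theta = [0.2, 0.35, 0.26]  # close effects so Q <= k-1
        res = meta_random_effects((theta, [0.3, 0.3, 0.3]))
        assert res.tau2 == 0.0
        assert res.pooled_log_hr == pytest.approx(np.mean(theta))

    def test_three_study_formula_transcription(self):
        theta = np.array([0.2, 0.5, 0.9])
        se = np.array([0.1, 0.2, 0.3])
        # independent transcription of the DerSimonian-Laird formulas
        w = 1 / se ** 2
        theta_fe = (w * theta).sum() / w.sum()
        Q = (w * (theta - theta_fe) ** 2).sum()
        tau2 = max(0.0, (Q - 2) / (w.sum() - (w ** 2).sum() / w.sum()))
        w_star = 1 / (se ** 2 + tau2)
        pooled = (w_star * theta).sum() / w_star.sum()
        pooled_se = w_star.sum() ** -0.5
        res = meta_random_effects((theta, se))
        assert res.pooled_log_hr == pytest.approx(pooled, abs=1e-10)
        assert res.pooled_se == pytest.approx(pooled_se, abs=1e-10)
        assert res.tau2 == pytest.approx(tau2, abs=1e-10)
        assert res.Q == pytest.approx(Q, abs=1e-10)

    def test_agrees_with_statsmodels_dl(self):
        theta = np.array([0.1, 0.6, 0.4, -0.2, 0.9])
        se = np.array([0.15, 0.25, 0.2, 0.3, 0.4])
        res = meta_random_effects((theta, se))
        sm_res = combine_effects(theta, se ** 2, method_re="dl")
        assert res.tau2 == pytest.approx(sm_res.tau2, rel=1e-8)
        frame = sm_res.summary_frame()
        assert res.pooled_log_hr == pytest.approx(
            frame.loc["random effect", "eff"], rel=1e-8)

    def test_heterogeneity_zero_when_q_small(self):
        res = meta_random_effects(([0.1, 0.12], [0.3, 0.3]))
        assert res.tau2 == 0.0
        assert res.I2 == 0.0

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            meta_random_effects(([], []))
        from bimeta.errors import BimetaError
        with pytest.raises(BimetaError):
            meta_random_effects(([np.inf], [1.0]))


class TestScreen:
    def test_small_cohorts_excluded(self, small_study):
        inputs = small_study.survival_inputs()
        # shrink the first cohort below the gate
        ds0, clin0 = inputs[0]
        keep = clin0.data.index[:9]
        from bimeta.dataio import ClinicalTable, ExpressionDataset
        small_clin = ClinicalTable(clin0.cohort_id, clin0.data.loc[keep])
        trimmed = [(ds0, small_clin)] + inputs[1:]
        screen = run_survival_screen(trimmed, ["KYNU"], min_n=10)
        res = screen.results["KYNU"]
        assert res.meta_binary.k == len(inputs) - 1
        assert any("excluded (n=9" in line for line in screen.exclusions)

    def test_absent_gene_reported_not_screened(self, small_study):
        screen = run_survival_screen(small_study.survival_inputs(), ["NOSUCH"])
        assert screen.not_screened == ["NOSUCH"]

    def test_dual_modes_detect_positive_effect(self, small_study):
        screen = run_survival_screen(small_study.survival_inputs(), ["KYNU"])
        res = screen.results["KYNU"]
        assert res.meta_binary.pooled_log_hr > 0
        assert res.meta_continuous.pooled_log_hr > 0
        assert res.meta_binary.pooled_p < 0.05
        frame = screen.to_frame()
        assert {"binary_hr", "continuous_hr"} <= set(frame.columns)
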