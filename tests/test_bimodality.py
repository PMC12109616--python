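import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from bimeta.bimodality import (
    MixtureFit,
    _em_core_numpy,
    _em_rows_jit,
    bimodal_index,
    dichotomize_cluster,
    dichotomize_median,
    dichotomize_quantile,
    fit_gmm2,
    screen_bimodal_genes,
    screen_bimodal_study,
    zscore_standardize,
)
from bimeta.errors import DegenerateFitError, DegenerateInputError


def make_fit(mu_low, mu_high, sigma, pi_high) -> MixtureFit:
    return MixtureFit(mu_low=mu_low, mu_high=mu_high, sigma=sigma,
                      pi_high=pi_high, loglik=0.0, n_iter=1, converged=True, n=100)


class TestFitGmm2:
    def test_parameter_recovery(self, bimodal_sample):
        fit = fit_gmm2(bimodal_sample)
        assert fit.converged
        assert abs(fit.mu_low - 0.0) < 0.2
        assert abs(fit.mu_high - 3.0) < 0.2
        assert abs(fit.sigma - 1.0) < 0.15
        assert abs(fit.pi_high - 0.3) < 0.06

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateInputError):
            fit_gmm2(np.zeros(50))

    def test_short_input_raises(self):
        with pytest.raises(DegenerateInputError):
            fit_gmm2(np.arange(5.0))

    def test_unimodal_data_has_small_bimodal_index(self):
        # the equal-variance mixture MLE splits even a pure Gaussian into two
        # close components (delta ~1.27, BI ~0.64; cross-checked against
        # mclust model "E"), far below a genuinely bimodal gene's BI
        rng = np.random.default_rng(6)
        fit = fit_gmm2(rng.normal(0.0, 1.0, 2000))
        assert fit.delta < 1.6
        assert fit.bimodal_index < 0.9

    def test_loglik_nondecreasing_over_iterations(self, bimodal_sample):
        lls = [fit_gmm2(bimodal_sample, tol=0.0, max_iter=k, n_starts=1).loglik
               for k in range(1, 25)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_mirror_symmetry(self, bimodal_sample):
        fit = fit_gmm2(bimodal_sample)
        mirrored = fit_gmm2(-bimodal_sample)
        assert mirrored.mu_low == pytest.approx(-fit.mu_high, abs=1e-6)
        assert mirrored.mu_high == pytest.approx(-fit.mu_low, abs=1e-6)
        assert mirrored.pi_high == pytest.approx(1.0 - fit.pi_high, abs=1e-6)
        assert mirrored.bimodal_index == pytest.approx(fit.bimodal_index, abs=1e-6)

    def test_jit_kernel_matches_numpy_path(self):
        if _em_rows_jit is None:
            pytest.skip("numba unavailable")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 60))
        gamma = np.clip(
            (X > np.quantile(X, 0.5, axis=1, keepdims=True)).astype(float),
            0.01, 0.99)
        floors = np.full(20, 1e-8)
        a = _em_core_numpy(X.copy(), gamma.copy(), floors, 1e-8, 300)
        b = _em_rows_jit(X.copy(), gamma.copy(), floors, 1e-8, 300)
        for ai, bi in zip(a[:5], b[:5]):
            np.testing.assert_allclose(np.asarray(ai), np.asarray(bi),
                                       rtol=0, atol=1e-10)


class TestBimodalIndex:
    @pytest.mark.parametrize("delta, pi, expected", [
        (2.0, 0.5, 1.0),
        (3.0, 0.5, 1.5),
    ])
    def test_closed_form(self, delta, pi, expected):
        fit = make_fit(0.0, delta, 1.0, pi)
        assert bimodal_index(fit) == pytest.approx(expected, abs=1e-15)

    def test_vanishes_as_minor_component_disappears(self):
        bis = [bimodal_index(make_fit(0.0, 2.0, 1.0, pi))
               for pi in (0.3, 0.1, 0.01, 0.001)]
        assert all(b > a for a, b in zip(bis[1:], bis[:-1]))
        assert bis[-1] < 0.1


class TestDichotomizeCluster:
    def test_balanced_cutoff_is_midpoint(self):
        fit = make_fit(0.0, 4.0, 1.0, 0.5)
        assert fit.cutoff == pytest.approx(2.0)

    def test_cutoff_equals_posterior_half_crossing(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            mu1 = rng.normal(0, 2)
            mu2 = mu1 + rng.uniform(0.5, 5)
            sigma = rng.uniform(0.3, 2.0)
            pi = rng.uniform(0.05, 0.95)
            fit = make_fit(mu1, mu2, sigma, pi)
            root = brentq(lambda x: fit.posterior_high(x) - 0.5,
                          mu1 - 10 * sigma, mu2 + 10 * sigma, xtol=1e-12)
            assert fit.cutoff == pytest.approx(root, abs=1e-8)

    def test_map_labels_equal_threshold_rule(self, bimodal_sample):
        fit = fit_gmm2(bimodal_sample)
        labels = dichotomize_cluster(bimodal_sample, fit)
        posterior = fit.posterior_high(bimodal_sample)
        np.testing.assert_array_equal(labels.labels == "high", posterior > 0.5)

    def test_component_mean_is_labeled_high(self):
        fit = make_fit(0.0, 3.0, 1.0, 0.3)
        labels = dichotomize_cluster(np.array([fit.mu_high]), fit)
        assert labels.labels[0] == "high"

    def test_degenerate_fit_rejected(self):
        fit = MixtureFit(mu_low=1.0, mu_high=1.0, sigma=1.0, pi_high=0.5,
                         loglik=0.0, n_iter=1, converged=True, n=10)
        with pytest.raises(DegenerateFitError):
            dichotomize_cluster(np.array([1.0, 2.0]), fit)


class TestDichotomizeMedian:
    def test_basic_split(self):
        labels = dichotomize_median([1.0, 2.0, 3.0, 4.0])
        assert list(labels.labels) == ["low", "low", "high", "high"]
        assert labels.cutoff_low == 2.5

    def test_ties_at_median_go_low(self):
        labels = dichotomize_median([5.0, 5.0, 5.0])
        assert set(labels.labels) == {"low"}

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_group_imbalance_bounded_by_median_ties(self, values):
        x = np.asarray(values)
        labels = dichotomize_median(x)
        n_high = int((labels.labels == "high").sum())
        n_low = int((labels.labels == "low").sum())
        n_tied = int((x == np.median(x)).sum())
        # n_high = #{x >= med} - ties >= ceil(n/2) - ties, so the imbalance
        # n - 2*n_high is at most 2*ties; tie-free input splits exactly evenly
        assert abs(n_high - n_low) <= 2 * n_tied


class TestDichotomizeQuantile:
    def test_hundred_distinct_values(self):
        labels = dichotomize_quantile(np.arange(1.0, 101.0))
        assert int((labels.labels == "high").sum()) == 20
        assert int((labels.labels == "low").sum()) == 70
        assert int((labels.labels == "excluded").sum()) == 10

    def test_collapsed_band_is_strict_median_split(self):
        x = np.arange(1.0, 10.0)
        labels = dichotomize_quantile(x, hi_q=0.5, lo_q=0.5)
        med = np.median(x)
        np.testing.assert_array_equal(labels.labels == "high", x > med)
        np.testing.assert_array_equal(labels.labels == "low", x < med)

    def test_top_quantile_one_leaves_no_high(self):
        labels = dichotomize_quantile(np.arange(10.0), hi_q=1.0, lo_q=0.5)
        assert not (labels.labels == "high").any()

    def test_reversed_quantiles_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_quantile(np.arange(10.0), hi_q=0.3, lo_q=0.7)


class TestZscore:
    def test_unit_example(self):
        np.testing.assert_allclose(zscore_standardize([1.0, 2.0, 3.0]),
                                   [-1.0, 0.0, 1.0])

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=30)
        np.testing.assert_allclose(zscore_standardize(2.5 + 3.0 * v),
                                   zscore_standardize(v), atol=1e-12)

    def test_moments(self):
        rng = np.random.default_rng(5)
        out = zscore_standardize(rng.normal(5, 3, 100))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            zscore_standardize(np.full(10, 2.0))


class TestScreen:
    def test_target_ranks_first_in_cohort(self, small_study):
        screen = screen_bimodal_genes(small_study.cohorts[0].expression)
        assert screen.iloc[0]["gene"] == "KYNU"
        bis = screen["BI"].dropna().to_numpy()
        assert (np.diff(bis) <= 1e-12).all()

    def test_constant_gene_flagged_not_ranked(self, toy_expression):
        import copy
        ds = copy.deepcopy(toy_expression)
        ds.values[1, :] = 7.0
        ds.values[0, :] = [1.0, 2.0, 30.0]
        # need >= 10 samples for a fit: tile columns
        from bimeta.dataio import ExpressionDataset
        wide = ExpressionDataset(
            "c", ds.gene_ids, [f"s{i}" for i in range(12)],
            np.hstack([ds.values] * 4))
        screen = screen_bimodal_genes(wide)
        row = screen[screen["gene"] == "g2"].iloc[0]
        assert bool(row["degenerate"])
        assert np.isnan(row["BI"])

    def test_study_screen_aggregates_median(self, small_study):
        agg = screen_bimodal_study([c.expression for c in small_study.cohorts])
        assert agg.iloc[0]["gene"] == "KYNU"
        assert (agg["n_cohorts"] == len(small_study.cohorts)).all()
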