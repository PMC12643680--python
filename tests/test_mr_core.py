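"""The six MR estimators: closed forms, oracles, and equivariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrmediate.summary_io import harmonized_from_arrays
from mrmediate.mr_core import (InsufficientInstrumentsError, MRSettings, ivw,
                               mode_estimator, mr_egger, run_all_methods,
                               wald_ratio, weighted_median,
                               _weighted_median_value)
from mrmediate.synthetic import SimConfig, simulate_summary_direct
from mrmediate.experiments import planted_harmonized


def _h(bx, by, sy, sx=None):
    sx = sx if sx is not None else [0.05] * len(bx)
    return harmonized_from_arrays(bx, sx, by, sy)


class TestWaldRatio:
    @pytest.mark.parametrize("bx,by,sy,beta,se", [
        (0.5, 0.5, 0.05, 1.0, 0.1),
        (1.0, 0.0, 0.1, 0.0, 0.1),
        (-0.5, 0.25, 0.05, -0.5, 0.1),
    ])
    def test_ratio_and_first_order_se(self, bx, by, sy, beta, se):
        est = wald_ratio(_h([bx], [by], [sy]))
        assert est.beta == pytest.approx(beta)
        assert est.se == pytest.approx(se)
        assert est.or_ == pytest.approx(np.exp(est.beta), rel=1e-15)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(_h([0.0], [0.1], [0.1]))


class TestIVW:
    def test_two_instrument_closed_form(self, two_instrument_set):
        est = ivw(two_instrument_set, "fixed")
        assert est.beta == pytest.approx(0.6, rel=1e-12)
        assert est.se == pytest.approx(0.070711, abs=1e-6)

    def test_multiplicative_random_inflates_by_q(self, two_instrument_set):
        est = ivw(two_instrument_set, "multiplicative_random")
        # Q = 2.0 with J-1 = 1: SE = fixed * sqrt(2) = 0.1
        assert est.se == pytest.approx(0.1, rel=1e-10)

    def test_perfect_proportionality_equalises_models(self):
        h = _h([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.1, 0.1, 0.1])
        fe, mre = ivw(h, "fixed"), ivw(h, "multiplicative_random")
        assert fe.beta == pytest.approx(0.5, rel=1e-12)
        assert mre.se == pytest.approx(fe.se, rel=1e-12)  # floor at fixed SE

    def test_equal_weights_equal_unweighted_origin_regression(self, rng):
        bx = rng.normal(0.2, 0.05, 8)
        by = rng.normal(0.04, 0.02, 8)
        est = ivw(_h(bx, by, [0.1] * 8), "fixed")
        assert est.beta == pytest.approx(
            float(np.sum(bx * by) / np.sum(bx**2)), rel=1e-12)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(_h([1.0], [0.5], [0.1]))


class TestEgger:
    def test_collinear_fixture_exact(self, collinear_egger_set):
        est = mr_egger(collinear_egger_set)
        assert est.beta == pytest.approx(1.0, abs=1e-10)
        assert est.intercept == pytest.approx(0.1, abs=1e-10)

    def test_proportional_pairs_zero_intercept(self):
        est = mr_egger(_h([0.1, 0.2, 0.3], [0.2, 0.4, 0.6], [0.1, 0.1, 0.1]))
        assert est.beta == pytest.approx(2.0, abs=1e-10)
        assert est.intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        bx = np.abs(rng.normal(0.3, 0.1, 12))
        by = rng.normal(0.1, 0.1, 12)
        sy = rng.uniform(0.05, 0.2, 12)
        est = mr_egger(_h(bx, by, sy))
        W = np.diag(1 / sy**2)
        X = np.column_stack([np.ones(12), bx])
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ by)
        assert est.intercept == pytest.approx(coef[0], rel=1e-9)
        assert est.beta == pytest.approx(coef[1], rel=1e-9)

    def test_requires_three_instruments(self, two_instrument_set):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(two_instrument_set)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            mr_egger(_h([0.2, 0.2, 0.2], [0.1, 0.2, 0.3], [0.1, 0.1, 0.1]))


class TestWeightedMedian:
    def test_percentile_rule_three_equal_weights(self):
        # cumulative percentiles (1/6, 1/2, 5/6): 0.5 lands on the middle ratio
        assert _weighted_median_value(np.array([0.4, 0.6, 10.0]),
                                      np.ones(3)) == pytest.approx(0.6)

    def test_identical_ratios_ignore_weights(self, rng):
        w = rng.uniform(0.1, 5.0, 6)
        assert _weighted_median_value(np.full(6, 0.3), w) == pytest.approx(0.3)

    def test_concentrated_weight_limit(self):
        r = np.array([0.1, 0.9, 2.0])
        w = np.array([1e6, 1.0, 1.0])
        assert _weighted_median_value(r, w) == pytest.approx(0.1, abs=1e-4)

    def test_estimator_on_harmonized_set(self):
        h = _h([1.0, 1.0, 1.0], [0.4, 0.6, 10.0], [0.1, 0.1, 0.1])
        est = weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.6)
        assert est.se > 0

    def test_odd_equal_weights_reduce_to_sample_median(self, rng):
        r = np.sort(rng.normal(0.5, 0.2, 5))
        assert _weighted_median_value(r, np.ones(5)) == pytest.approx(
            float(np.median(r)))


def _grid_mode_oracle(ratios, weights, bandwidth):
    """Independent brute-force density scan (plain loops, fine grid)."""
    grid = np.linspace(min(ratios) - 3 * bandwidth,
                       max(ratios) + 3 * bandwidth, 4001)
    best, best_d = grid[0], -1.0
    wsum = sum(weights)
    for g in grid:
        d = sum(w * np.exp(-0.5 * ((g - r) / bandwidth) ** 2)
                for r, w in zip(ratios, weights)) / wsum
        if d > best_d:
            best, best_d = g, d
    return best


class TestModeEstimator:
    def test_identical_ratios_return_that_value(self):
        h = _h([1.0, 1.0, 1.0], [0.3, 0.3, 0.3], [0.1, 0.1, 0.1])
        est = mode_estimator(h, n_boot=20, seed=1)
        assert est.beta == pytest.approx(0.3)

    def test_majority_cluster_wins(self):
        h = _h([1.0] * 4, [0.5, 0.5, 0.5, 5.0], [0.1] * 4)
        est = mode_estimator(h, bandwidth_factor=0.5, n_boot=20, seed=1)
        assert est.beta == pytest.approx(0.5, abs=0.1)

    def test_matches_grid_search_oracle(self, rng):
        ratios = np.concatenate([rng.normal(0.5, 0.05, 8),
                                 rng.normal(2.0, 0.05, 3)])
        h = _h(np.ones(11), ratios, np.full(11, 0.1))
        est = mode_estimator(h, n_boot=20, seed=1)
        from scipy.stats import median_abs_deviation
        bw = 0.9 * min(np.std(ratios, ddof=1),
                       median_abs_deviation(ratios, scale="normal")) \
            * len(ratios) ** -0.2
        oracle = _grid_mode_oracle(ratios, np.ones(11), bw)
        assert est.beta == pytest.approx(oracle, abs=0.02)

    def test_weighted_variant_downweights_outlier(self):
        # outlier ratio carries near-zero weight -> mode stays in the cluster
        bx = np.array([1.0, 1.0, 1.0, 1.0])
        by = np.array([0.5, 0.52, 0.48, 5.0])
        sy = np.array([0.05, 0.05, 0.05, 5.0])  # huge SE -> tiny weight
        est = mode_estimator(_h(bx, by, sy), weighted=True,
                             bandwidth_factor=0.5, n_boot=20, seed=1)
        assert 0.4 < est.beta < 0.6


class TestRunAllMethods:
    def test_single_pair_gives_wald_only(self):
        out = run_all_methods(_h([0.5], [0.25], [0.05]))
        assert [e.method for e in out] == ["wald_ratio"]
        assert not out[0].is_primary

    def test_two_pairs_exclude_egger(self, two_instrument_set):
        methods = {e.method for e in run_all_methods(
            two_instrument_set, MRSettings(n_boot=20))}
        assert methods == {"ivw_fe", "ivw_mre", "weighted_median",
                           "simple_mode", "weighted_mode"}

    def test_six_methods_and_primary_flag(self, default_sim):
        exp, _, out, _, _ = default_sim
        h = planted_harmonized(exp, out)
        ests = run_all_methods(h, MRSettings(n_boot=20))
        assert {e.method for e in ests} == {"ivw_fe", "ivw_mre", "egger",
                                            "weighted_median", "simple_mode",
                                            "weighted_mode"}
        primary = [e for e in ests if e.is_primary]
        assert len(primary) == 1
        assert primary[0].method in ("ivw_fe", "ivw_mre")

    def test_all_methods_converge_with_strong_data(self):
        cfg = SimConfig(n_snp=50, n_exp=1_000_000, n_out=2_000_000,
                        prevalence=None, seed=4)
        exp, _, out, _, truth = simulate_summary_direct(cfg)
        h = planted_harmonized(exp, out)
        for est in run_all_methods(h, MRSettings(n_boot=20)):
            assert est.beta == pytest.approx(truth.beta0_true, abs=0.02), \
                est.method


class TestEquivariances:
    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_sign_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        J = 6
        bx = rng.normal(0.3, 0.1, J)
        by = rng.normal(0.06, 0.05, J)
        sy = rng.uniform(0.05, 0.2, J)
        h_pos, h_neg = _h(bx, by, sy), _h(bx, -by, sy)
        for f in (lambda h: ivw(h, "fixed"),
                  lambda h: ivw(h, "multiplicative_random"), mr_egger):
            a, b = f(h_pos), f(h_neg)
            assert a.beta == pytest.approx(-b.beta, rel=1e-9, abs=1e-12)
            assert a.se == pytest.approx(b.se, rel=1e-9)
        # bootstrap SEs of median/mode are sign-symmetric only in
        # distribution; the point estimates negate exactly
        for f in (lambda h: weighted_median(h, n_boot=5, seed=9),
                  lambda h: mode_estimator(h, n_boot=5, seed=9)):
            a, b = f(h_pos), f(h_neg)
            assert a.beta == pytest.approx(-b.beta, rel=1e-9, abs=1e-12)

    def test_scale_equivariance(self, rng):
        J, c = 6, 2.5
        bx = rng.normal(0.3, 0.1, J)
        by = rng.normal(0.06, 0.05, J)
        sy = rng.uniform(0.05, 0.2, J)
        sx = np.full(J, 0.01)
        for f in (lambda h: ivw(h, "fixed"), mr_egger,
                  lambda h: weighted_median(h, n_boot=30, seed=9)):
            a = f(harmonized_from_arrays(bx, sx, by, sy))
            b = f(harmonized_from_arrays(c * bx, c * sx, by, sy))
            assert b.beta == pytest.approx(a.beta / c, rel=1e-6)
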