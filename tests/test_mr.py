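"""MR estimators, Steiger directionality, sensitivity gating, and BH-FDR."""

import numpy as np
import pytest
import statsmodels.api as sm

from cismr.mr import (
    bh_adjust, egger, ivw, penalized_weighted_median, run_mr, sensitivity_gate,
    steiger, wald_ratio, weighted_median, weighted_mode,
)
from cismr.instruments import InstrumentSet
from cismr.sumstats import StudyMeta

from helpers import bh_oracle, make_pair, make_pairs

QUANT = StudyMeta(trait_id="expr", trait_type="quantitative")
CC = StudyMeta(trait_id="disease", trait_type="case_control", case_fraction=0.5)
N_BOOT = 200  # bootstrap replicates for SE smoke checks


class TestWaldRatio:
    def test_ratio_arithmetic(self):
        res = wald_ratio(make_pair(0.5, 0.25, se_exp=0.1, se_out=0.05))
        assert res.estimate == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)

    def test_null_outcome(self):
        res = wald_ratio(make_pair(1.0, 0.0, se_out=0.1))
        assert res.estimate == 0.0
        assert res.pvalue == 1.0

    def test_negative_exposure_sign(self):
        res = wald_ratio(make_pair(-0.5, 0.25, se_out=0.05))
        assert res.estimate == pytest.approx(-0.5)
        assert res.se == pytest.approx(0.1)

    def test_zero_exposure_error(self):
        with pytest.raises(ValueError, match="undefined instrument"):
            wald_ratio(make_pair(0.0, 0.1))

    def test_or_ci_ordering(self):
        res = wald_ratio(make_pair(0.5, -0.12, se_out=0.05))
        assert res.or_low95 <= res.or_point <= res.or_high95


class TestIVW:
    def test_symmetric_mean(self):
        pairs = make_pairs([1.0, 1.0], [0.4, 0.6], se_out=[0.1, 0.1])
        assert ivw(pairs).estimate == pytest.approx(0.5)

    def test_single_pair_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            ivw(make_pairs([1.0], [0.5]))

    def test_matches_weighted_least_squares_oracle(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.1, 0.5, 5)
        by = rng.normal(0.3 * bx, 0.05)
        sy = rng.uniform(0.03, 0.08, 5)
        res = ivw(make_pairs(bx, by, se_out=sy))
        fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        assert res.estimate == pytest.approx(fit.params[0], rel=1e-10)
        # implementation floors the heterogeneity scaling at the fixed-effect SE
        se_fixed = float(np.sum(bx**2 / sy**2) ** -0.5)
        assert res.se == pytest.approx(max(se_fixed, fit.bse[0]), rel=1e-10)


class TestEgger:
    def test_exact_linear_fit(self):
        bx = np.array([0.2, 0.4, 0.6])
        fit = egger(make_pairs(bx, 0.1 + 0.3 * bx))
        assert fit.slope.estimate == pytest.approx(0.3)
        assert fit.intercept == pytest.approx(0.1)

    def test_proportional_through_origin(self):
        bx = np.array([0.2, 0.4, 0.6])
        fit = egger(make_pairs(bx, 0.5 * bx))
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_orientation_sign_invariance(self):
        # jointly negating (beta_exp, beta_out) of any pair leaves the fit unchanged
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.1, 0.6, 5)
        by = rng.normal(0.05 + 0.25 * bx, 0.03)
        sy = rng.uniform(0.03, 0.08, 5)
        flip = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
        a = egger(make_pairs(bx, by, se_out=sy))
        b = egger(make_pairs(bx * flip, by * flip, se_out=sy))
        assert b.slope.estimate == pytest.approx(a.slope.estimate, rel=1e-12)
        assert b.intercept == pytest.approx(a.intercept, rel=1e-12)

    def test_matches_two_parameter_wls_oracle(self):
        rng = np.random.default_rng(10)
        bx = rng.uniform(0.1, 0.6, 6)  # positive: orientation is a no-op
        by = rng.normal(0.05 + 0.25 * bx, 0.04)
        sy = rng.uniform(0.03, 0.08, 6)
        fit = egger(make_pairs(bx, by, se_out=sy))
        X = sm.add_constant(bx)
        ref = sm.WLS(by, X, weights=1.0 / sy**2).fit()
        assert fit.intercept == pytest.approx(ref.params[0], rel=1e-10)
        assert fit.slope.estimate == pytest.approx(ref.params[1], rel=1e-10)
        # implementation floors the heterogeneity scale at 1 (SE never below
        # the unit-scale SE); statsmodels always applies its estimated scale
        floor_ratio = max(1.0, np.sqrt(ref.scale)) / np.sqrt(ref.scale)
        assert fit.intercept_se == pytest.approx(ref.bse[0] * floor_ratio, rel=1e-10)
        if ref.scale >= 1.0:
            assert fit.intercept_p == pytest.approx(ref.pvalues[0], rel=1e-8)

    def test_too_few_instruments(self):
        with pytest.raises(ValueError, match="at least 3"):
            egger(make_pairs([0.2, 0.3], [0.1, 0.2]))


class TestWeightedMedian:
    def test_middle_ratio_equal_weights(self):
        est = weighted_median(make_pairs([1, 1, 1], [0.2, 0.5, 0.9]), n_boot=N_BOOT, seed=0)
        assert est.estimate == pytest.approx(0.5)

    def test_dominant_weight(self):
        # middle instrument carries ~99% of the weight via a tiny outcome SE
        pairs = make_pairs([1, 1, 1], [0.2, 0.7, 0.9], se_out=[0.5, 0.005, 0.5])
        est = weighted_median(pairs, n_boot=N_BOOT, seed=0)
        assert est.estimate == pytest.approx(0.7, abs=0.02)

    def test_matches_interpolation_formula_oracle(self):
        rng = np.random.default_rng(12)
        bx = rng.uniform(0.2, 0.6, 5)
        by = rng.normal(0.3 * bx, 0.05)
        sy = rng.uniform(0.03, 0.08, 5)
        est = weighted_median(make_pairs(bx, by, se_out=sy), n_boot=N_BOOT, seed=0)
        # independent re-implementation of the interpolation rule
        r = by / bx
        w = (bx / sy) ** 2
        order = np.argsort(r)
        r_s, w_s = r[order], w[order]
        s = (np.cumsum(w_s) - w_s / 2) / w_s.sum()
        below = np.max(np.flatnonzero(s < 0.5))
        frac = (0.5 - s[below]) / (s[below + 1] - s[below])
        expected = r_s[below] + frac * (r_s[below + 1] - r_s[below])
        assert est.estimate == pytest.approx(expected, rel=1e-10)


class TestPenalizedWeightedMedian:
    def test_homogeneous_equals_plain_median(self):
        pairs = make_pairs([0.3, 0.4, 0.5], [0.09, 0.12, 0.15])  # all ratios 0.3
        plain = weighted_median(pairs, n_boot=N_BOOT, seed=0)
        pen = penalized_weighted_median(pairs, n_boot=N_BOOT, seed=0)
        assert pen.estimate == pytest.approx(plain.estimate)

    def test_outlier_downweighted(self):
        # heavy-weight outlier ratio at 1.0 drags the plain median to ~0.49;
        # penalization collapses its weight and restores the 0.3 cluster
        bx = np.array([1.0, 1.0, 1.0, 1.0])
        by = np.array([0.28, 0.30, 0.32, 1.0])
        pairs = make_pairs(bx, by, se_out=[0.1, 0.1, 0.1, 0.0577])
        pen = penalized_weighted_median(pairs, n_boot=N_BOOT, seed=0)
        plain = weighted_median(pairs, n_boot=N_BOOT, seed=0)
        assert plain.estimate > 0.4
        assert abs(pen.estimate - 0.30) < abs(plain.estimate - 0.30)
        assert pen.estimate == pytest.approx(0.30, abs=0.03)


class TestWeightedMode:
    def test_cluster_mode(self):
        pairs = make_pairs([1, 1, 1, 1], [0.29, 0.30, 0.31, 0.90])
        est = weighted_mode(pairs, n_boot=N_BOOT, seed=0)
        assert 0.28 <= est.estimate <= 0.32

    def test_degenerate_identical_ratios(self):
        pairs = make_pairs([0.5, 1.0, 2.0], [0.2, 0.4, 0.8])  # all ratios 0.4
        est = weighted_mode(pairs, n_boot=N_BOOT, seed=0)
        assert est.estimate == pytest.approx(0.4)

    def test_weight_dominance(self):
        pairs = make_pairs(
            [1, 1, 1, 1, 1], [0.7, 0.71, 0.69, -0.7, -0.71],
            se_out=[0.01, 0.01, 0.01, 0.5, 0.5],
        )
        est = weighted_mode(pairs, n_boot=N_BOOT, seed=0)
        assert est.estimate > 0.5


class TestSteiger:
    def test_exposure_dominant_direction_true(self):
        # strong exposure association, weak outcome association
        pairs = make_pairs([0.5], [0.01], se_exp=[0.02], se_out=[0.02])
        direction, p = steiger(pairs, QUANT, CC)
        assert direction is True
        assert p < 0.05

    def test_tie_is_false(self):
        # identical z and n on both (quantitative) sides: r2 ties exactly
        pairs = make_pairs([0.3], [0.3], se_exp=[0.05], se_out=[0.05],
                           n_exp=10_000.0, n_out=10_000.0)
        direction, p = steiger(pairs, QUANT, QUANT)
        assert direction is False
        assert p == pytest.approx(1.0)

    def test_missing_n_error(self):
        pair = make_pair(0.5, 0.1)
        pair.n_exp = None
        with pytest.raises(ValueError, match="sample sizes"):
            steiger([pair], QUANT, CC)


class TestRunMR:
    def iset(self, pairs):
        return InstrumentSet(pairs=pairs, gene_id="G1", outcome_id="o")

    def test_single_instrument_wald(self):
        primary, report = run_mr(self.iset(make_pairs([0.5], [0.25])), QUANT, CC,
                                 n_boot=N_BOOT, seed=0)
        assert primary.method == "wald_ratio"
        assert report.egger is None and report.weighted_median is None
        assert report.steiger_direction is not None

    def test_two_instruments_ivw_no_battery(self):
        primary, report = run_mr(self.iset(make_pairs([0.5, 0.4], [0.25, 0.2])),
                                 QUANT, CC, n_boot=N_BOOT, seed=0)
        assert primary.method == "ivw"
        assert report.egger is None
        assert report.overall_pass == report.pass_steiger

    def test_three_instruments_full_battery(self):
        pairs = make_pairs([0.5, 0.4, 0.3], [0.25, 0.2, 0.15])
        primary, report = run_mr(self.iset(pairs), QUANT, CC, n_boot=N_BOOT, seed=0)
        assert primary.method == "ivw"
        assert report.egger is not None
        assert report.weighted_median is not None
        assert report.weighted_mode is not None

    def test_empty_set_error(self):
        with pytest.raises(ValueError, match="empty"):
            run_mr(self.iset([]), QUANT, CC)

    def test_reproducible_given_seed(self):
        pairs = make_pairs([0.5, 0.4, 0.3], [0.25, 0.18, 0.16])
        a = run_mr(self.iset(pairs), QUANT, CC, n_boot=N_BOOT, seed=7)
        b = run_mr(self.iset(pairs), QUANT, CC, n_boot=N_BOOT, seed=7)
        assert a[1].weighted_median.se == b[1].weighted_median.se


class TestSensitivityGate:
    def test_egger_intercept_failure(self):
        pairs = make_pairs([0.5, 0.4, 0.3], [0.25, 0.2, 0.15])
        primary, report = run_mr(InstrumentSet(pairs=pairs), QUANT, CC,
                                 n_boot=N_BOOT, seed=0)
        report.egger.intercept_p = 0.02
        assert sensitivity_gate(report, primary) is False
        assert report.pass_egger_intercept is False

    def test_sign_inconsistency_failure(self):
        pairs = make_pairs([0.5, 0.4, 0.3], [0.25, 0.2, 0.15])
        primary, report = run_mr(InstrumentSet(pairs=pairs), QUANT, CC,
                                 n_boot=N_BOOT, seed=0)
        report.weighted_mode.estimate = -0.5
        assert sensitivity_gate(report, primary) is False
        assert report.pass_sign_consistency is False

    def test_all_consistent_passes(self):
        pairs = make_pairs([0.5, 0.4, 0.3], [0.25, 0.2, 0.15])
        primary, report = run_mr(InstrumentSet(pairs=pairs), QUANT, CC,
                                 n_boot=N_BOOT, seed=0)
        assert report.pass_steiger
        assert sensitivity_gate(report, primary) is True


class TestBHAdjust:
    def test_textbook_monotone_case(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(21)
        p = rng.uniform(1e-6, 1, 20)
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(list(p)), rtol=1e-12)

    def test_permutation_equivariance_and_monotonicity(self):
        rng = np.random.default_rng(22)
        p = rng.uniform(1e-6, 1, 15)
        adj = bh_adjust(p)
        perm = rng.permutation(15)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], rtol=1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
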