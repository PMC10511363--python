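"""Colocalization engine: ABFs, posteriors, prior scan, peak diagnostic."""

import numpy as np
import pytest

from cismr.coloc import (
    ColocStudyInput, coloc_abf, detect_secondary_peaks, estimate_sdY,
    prior_sensitivity, wakefield_labf,
)
from cismr.simulate import SimScenario, simulate_pair

from helpers import coloc_enumeration_oracle, make_stats


def studies_from_labf(labf1, labf2):
    """Inputs whose Wakefield log-ABFs equal the requested values exactly.

    With a fixed prior SD W and SE, labf is monotone in z²; invert for |z|.
    """
    W = 0.2
    se = 0.05
    shrink = W**2 / (se**2 + W**2)
    offset = 0.5 * np.log(se**2 / (se**2 + W**2))

    def betas(labf):
        z2 = 2.0 * (np.asarray(labf, dtype=float) - offset) / shrink
        return np.sqrt(np.maximum(z2, 0.0)) * se

    kw = dict(se=np.full(len(labf1), se), trait_type="quantitative", prior_sd=W)
    return (ColocStudyInput(beta=betas(labf1), **kw),
            ColocStudyInput(beta=betas(labf2), **kw))


class TestEstimateSdY:
    def test_exact_model_consistency(self):
        maf = np.full(10, 0.5)
        n = np.full(10, 1000.0)
        vbeta = 1.0 / (2 * n * maf * (1 - maf))  # sdY = 1 exactly
        assert estimate_sdY(vbeta, maf, n) == pytest.approx(1.0)

    def test_scale_equivariance(self):
        maf = np.full(10, 0.5)
        n = np.full(10, 1000.0)
        vbeta = 4.0 / (2 * n * maf * (1 - maf))
        assert estimate_sdY(vbeta, maf, n) == pytest.approx(2.0)

    def test_noisy_recovery_within_5pct(self):
        rng = np.random.default_rng(3)
        maf = rng.uniform(0.05, 0.5, 500)
        n = np.full(500, 10_000.0)
        vbeta = 1.0 / (2 * n * maf * (1 - maf)) * rng.lognormal(0, 0.05, 500)
        assert estimate_sdY(vbeta, maf, n) == pytest.approx(1.0, rel=0.05)

    def test_missing_inputs_error(self):
        with pytest.raises(ValueError):
            estimate_sdY([0.002, 0.002], [0.5, np.nan], [1000, 1000])


class TestWakefieldLabf:
    def test_null_prior_unit_bf(self):
        assert wakefield_labf(0.3, 0.05, 0.0) == pytest.approx(0.0)

    def test_zero_z_negative_evidence(self):
        labf = wakefield_labf(0.0, 0.05, 0.2)
        assert labf == pytest.approx(0.5 * np.log(0.0025 / 0.0425))
        assert labf < 0

    def test_closed_form_value(self):
        assert wakefield_labf(0.3, 0.05, 0.2) == pytest.approx(15.5246, abs=1e-3)


class TestColocABF:
    def test_flat_bf_reduces_to_priors(self):
        s1, s2 = studies_from_labf([0.0, 0.0], [0.0, 0.0])
        res = coloc_abf(s1, s2)
        prior_mass = np.array([1.0, 2e-4, 2e-4, 2e-8, 2e-5])
        np.testing.assert_allclose(
            [res.pp[h] for h in ("pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4")],
            prior_mass / prior_mass.sum(), rtol=1e-9,
        )
        assert res.pp["pp_h0"] == pytest.approx(0.9996, abs=1e-4)

    def test_shared_peak_h4_dominant(self):
        s1, s2 = studies_from_labf([20.0, 0.0, 0.0], [20.0, 0.0, 0.0])
        res = coloc_abf(s1, s2)
        assert max(res.pp, key=res.pp.get) == "pp_h4"

    def test_distinct_peaks_h3_dominant(self):
        s1, s2 = studies_from_labf([20.0, 0.0, 0.0], [0.0, 20.0, 0.0])
        res = coloc_abf(s1, s2)
        assert max(res.pp, key=res.pp.get) == "pp_h3"

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for trial in range(200):
            m = int(rng.integers(1, 9))
            labf1 = rng.uniform(-5, 25, m)
            labf2 = rng.uniform(-5, 25, m)
            s1, s2 = studies_from_labf(labf1, labf2)
            res = coloc_abf(s1, s2)
            expected = coloc_enumeration_oracle(res._labf1, res._labf2)
            got = np.array([res.pp[h] for h in
                            ("pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4")])
            assert np.max(np.abs(got - expected) / np.maximum(expected, 1e-300)) < 1e-10

    def test_no_overflow_at_extreme_labf(self):
        s1 = ColocStudyInput(beta=np.array([38.0, 0.0]), se=np.array([0.01, 0.01]),
                             trait_type="case_control")  # |z| = 3800, labf ~ 700
        s2 = ColocStudyInput(beta=np.array([38.0, 0.0]), se=np.array([0.01, 0.01]),
                             trait_type="case_control")
        res = coloc_abf(s1, s2)
        pp = np.array(list(res.pp.values()))
        assert np.isfinite(pp).all()
        assert pp.sum() == pytest.approx(1.0, abs=1e-12)
        assert res.per_variant_h4.sum() == pytest.approx(1.0, abs=1e-12)

    def test_variant_permutation_invariance(self):
        rng = np.random.default_rng(19)
        labf1, labf2 = rng.uniform(-2, 15, 6), rng.uniform(-2, 15, 6)
        s1, s2 = studies_from_labf(labf1, labf2)
        res = coloc_abf(s1, s2)
        perm = rng.permutation(6)
        s1p, s2p = studies_from_labf(labf1[perm], labf2[perm])
        resp = coloc_abf(s1p, s2p)
        for h in res.pp:
            assert resp.pp[h] == pytest.approx(res.pp[h], rel=1e-10)
        np.testing.assert_allclose(resp.per_variant_h4, res.per_variant_h4[perm], rtol=1e-10)

    def test_misaligned_inputs_fatal(self):
        s1, _ = studies_from_labf([1.0, 2.0], [1.0, 2.0])
        _, s2 = studies_from_labf([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="same ordered variant list"):
            coloc_abf(s1, s2)


class TestPriorSensitivity:
    def test_pp_h4_nondecreasing_in_p12(self):
        rng = np.random.default_rng(23)
        s1, s2 = studies_from_labf(rng.uniform(-2, 18, 8), rng.uniform(-2, 18, 8))
        curve, _, _ = prior_sensitivity(s1, s2)
        assert np.all(np.diff(curve["pp_h4"]) >= -1e-12)

    def test_h4_instance_robust(self):
        s1, s2 = studies_from_labf([25.0, 0.0, 0.0], [25.0, 0.0, 0.0])
        _, min_pass, robust = prior_sensitivity(s1, s2)
        assert min_pass is not None and min_pass <= 1e-6
        assert robust is True

    def test_null_instance_never_passes(self):
        s1, s2 = studies_from_labf([0.0, 0.0], [0.0, 0.0])
        _, min_pass, robust = prior_sensitivity(s1, s2)
        assert min_pass is None
        assert robust is False


class TestDetectSecondaryPeaks:
    def window(self, scenario, seed):
        _, outcome, ld, _ = simulate_pair(scenario, rng=np.random.default_rng(seed),
                                          apply_stressors=False)
        return outcome, ld

    def test_single_causal_not_flagged(self):
        sc = SimScenario(m=241, rho=0.9, hypothesis="H2", causal_indices=(120,),
                         outcome_effect=0.15, maf_range=(0.2, 0.5))
        outcome, ld = self.window(sc, 1)
        violation, peaks = detect_secondary_peaks(outcome, ld=ld)
        assert violation is False
        assert len(peaks) == 1

    def test_two_distant_causals_flagged(self):
        sc = SimScenario(m=241, rho=0.9, hypothesis="H2", causal_indices=(60, 180),
                         outcome_effect=0.15, maf_range=(0.2, 0.5))
        outcome, ld = self.window(sc, 1)
        violation, peaks = detect_secondary_peaks(outcome, ld=ld)
        assert violation is True
        assert len(peaks) >= 2

    def test_flat_pvalues_no_peaks(self):
        stats = make_stats([{"pos": 1000 * i, "pvalue": 0.5} for i in range(1, 20)])
        violation, peaks = detect_secondary_peaks(stats)
        assert violation is False
        assert peaks == []
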