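import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from causalmr import (
    egger,
    estimate_all,
    ivw,
    wald_ratios,
    weighted_median,
    weighted_mode,
)
from causalmr.estimators import _mode_bandwidth, _mode_point
from causalmr.exceptions import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)

from conftest import make_harmonized


class TestWaldRatios:
    def test_single_ratio(self):
        h = make_harmonized([0.2], [0.1], sey=0.02)
        theta, se = wald_ratios(h)
        assert theta[0] == pytest.approx(0.5)
        assert se[0] == pytest.approx(0.1)

    def test_zero_outcome_effects(self):
        h = make_harmonized([0.1, 0.2], [0.0, 0.0])
        theta, _ = wald_ratios(h)
        np.testing.assert_array_equal(theta, [0.0, 0.0])

    def test_toy_b_ratios(self, toy_b):
        theta, _ = wald_ratios(toy_b)
        np.testing.assert_allclose(theta, [0.5, 0.6, 0.3], rtol=1e-12)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratios(make_harmonized([0.1, 0.0], [0.05, 0.05]))


class TestIVW:
    def test_toy_a_closed_form(self, toy_a):
        est = ivw(toy_a)
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert est.metadata["q"] == pytest.approx(0.0, abs=1e-20)
        assert est.metadata["se_fixed"] == pytest.approx(1 / math.sqrt(350), rel=1e-12)
        # Q = 0 -> floored inflation is exactly 1
        assert est.se == pytest.approx(est.metadata["se_fixed"], rel=1e-12)

    def test_toy_b_hand_value(self, toy_b):
        assert ivw(toy_b).beta == pytest.approx(0.4, abs=1e-12)

    def test_single_snp_reduces_to_wald(self):
        h = make_harmonized([0.2], [0.1], sey=0.02)
        est = ivw(h)
        assert est.method == "wald"
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_fixed_vs_floored_se(self, toy_b):
        fixed = ivw(toy_b, re_model="fixed")
        floored = ivw(toy_b, re_model="multiplicative_floored")
        assert floored.beta == fixed.beta
        q = fixed.metadata["q"]
        assert floored.se == pytest.approx(fixed.se * math.sqrt(q / 2), rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(2, 12), st.integers(0, 10_000))
    def test_equals_inverse_variance_meta_of_ratios(self, k, seed):
        """IVW == fixed-effect meta-analysis of Wald ratios weighted by
        their inverse squared first-order SEs (algebraic identity)."""
        rng = np.random.default_rng(seed)
        h = make_harmonized(rng.uniform(0.05, 0.5, k) * rng.choice([-1, 1], k),
                            rng.normal(0, 0.1, k),
                            sey=rng.uniform(0.01, 0.05, k))
        theta, theta_se = wald_ratios(h)
        w = theta_se ** -2
        meta = float(np.sum(w * theta) / np.sum(w))
        assert ivw(h, re_model="fixed").beta == pytest.approx(meta, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0), st.integers(0, 10_000))
    def test_exposure_rescaling_divides_estimates(self, c, seed):
        rng = np.random.default_rng(seed)
        h = make_harmonized(rng.uniform(0.05, 0.5, 6), rng.normal(0, 0.1, 6))
        hc = replace(h, bx=c * h.bx, sex=c * h.sex)
        assert ivw(hc).beta == pytest.approx(ivw(h).beta / c, rel=1e-9)
        assert egger(hc).beta == pytest.approx(egger(h).beta / c, rel=1e-9)


class TestEgger:
    def test_toy_a_exact_fit(self, toy_a):
        est = egger(toy_a)
        assert est.beta == pytest.approx(0.5, abs=1e-9)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)
        assert est.intercept_pval == pytest.approx(1.0, abs=1e-9)

    def test_toy_b_hand_wls(self, toy_b):
        est = egger(toy_b)
        assert est.beta == pytest.approx(0.2, abs=1e-12)
        assert est.intercept == pytest.approx(0.046667, abs=1e-6)

    def test_orientation_invariance(self, toy_b):
        flipped = replace(toy_b, bx=toy_b.bx * np.array([-1, 1, 1]),
                          by=toy_b.by * np.array([-1, 1, 1]))
        base, alt = egger(toy_b), egger(flipped)
        assert alt.beta == pytest.approx(base.beta, rel=1e-12)
        assert alt.intercept == pytest.approx(base.intercept, rel=1e-12)

    def test_requires_three_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_harmonized([0.1, 0.2], [0.05, 0.1]))


class TestWeightedMedian:
    def test_toy_b_interpolation_oracle(self, toy_b):
        est = weighted_median(toy_b, n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.4, abs=1e-12)

    def test_all_equal_ratios(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.07, 0.14, 0.21], sex=1e-6, sey=1e-6)
        est = weighted_median(h, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.7, abs=1e-9)
        assert est.se < 1e-4  # bootstrap SE shrinks with the noise

    def test_permutation_invariance(self, toy_b):
        perm = [2, 0, 1]
        hp = replace(toy_b, snp_ids=[toy_b.snp_ids[i] for i in perm],
                     bx=toy_b.bx[perm], sex=toy_b.sex[perm],
                     by=toy_b.by[perm], sey=toy_b.sey[perm],
                     eaf_x=toy_b.eaf_x[perm])
        assert weighted_median(hp, 100, 0).beta == pytest.approx(
            weighted_median(toy_b, 100, 0).beta, abs=1e-12)

    def test_bootstrap_seeded_reproducible(self, toy_b):
        a = weighted_median(toy_b, n_boot=150, seed=9)
        b = weighted_median(toy_b, n_boot=150, seed=9)
        assert a.se == b.se


class TestWeightedMode:
    def test_all_equal_ratios_return_common(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], sex=1e-7, sey=1e-7)
        assert weighted_mode(h, n_boot=100, seed=0).beta == pytest.approx(0.5, abs=1e-9)

    def test_majority_cluster_wins(self):
        # ratios 0.5, 0.5, 0.5, 2.0 with equal weights
        bx = np.array([0.1, 0.1, 0.1, 0.1])
        by = np.array([0.05, 0.05, 0.05, 0.2])
        h = make_harmonized(bx, by, sex=0.01, sey=0.01)
        theta = by / bx
        hband = _mode_bandwidth(theta, 1.0)
        est = weighted_mode(h, n_boot=100, seed=0)
        assert abs(est.beta - 0.5) <= hband

    def test_phi_keeps_mode_in_ratio_range(self, toy_b):
        for phi in (0.5, 1.0, 2.0, 4.0):
            est = weighted_mode(toy_b, phi=phi, n_boot=100, seed=0)
            assert 0.3 - 1e-9 <= est.beta <= 0.6 + 1e-9

    def test_grid_argmax_against_bruteforce(self):
        rng = np.random.default_rng(5)
        theta = rng.normal(0.4, 0.2, 9)
        w = rng.uniform(0.5, 2.0, 9)
        w = w / w.sum()
        hband = _mode_bandwidth(theta, 1.0)
        got = _mode_point(theta, w, hband)
        grid = np.linspace(theta.min() - 3 * hband, theta.max() + 3 * hband, 200_001)
        dens = np.array([
            np.sum(w * np.exp(-0.5 * ((g - theta) / hband) ** 2)) for g in grid[::20]
        ])
        brute = grid[::20][np.argmax(dens)]
        assert abs(got - brute) < (grid[1] - grid[0]) * 40


class TestEstimateAll:
    def test_toy_a_all_methods_agree(self, toy_a):
        ests = estimate_all(toy_a, n_boot=100, seed=0)
        assert {e.method for e in ests} == {"ivw", "egger", "wme", "mbe"}
        for e in ests:
            assert e.ok
            assert e.beta == pytest.approx(0.5, abs=1e-6)

    def test_two_snp_gating(self):
        h = make_harmonized([0.1, 0.2], [0.05, 0.1])
        ests = estimate_all(h, n_boot=100, seed=0)
        by_method = {e.method: e for e in ests}
        assert by_method["ivw"].ok
        for m in ("egger", "wme", "mbe"):
            assert not by_method[m].ok
            assert by_method[m].error

    def test_or_scale_for_binary_outcomes(self, toy_a):
        h = replace(toy_a, outcome_type="binary")
        est = ivw(h)
        lo, mid, hi = est.or_scale[1], est.or_scale[0], est.or_scale[2]
        assert mid == pytest.approx(math.exp(est.beta))
        assert lo < mid < hi
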