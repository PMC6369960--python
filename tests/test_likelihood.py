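"""Unit and property tests for the read-count likelihood model.

The independent oracle throughout is the explicit four-configuration
probability sum for a single sampled read,

    P(lyrata read) = k(1-r)(1-E) + (1-k)r(1-E) + krE + (1-k)(1-r)E,

optionally re-weighted by a lyrata sampling odds b, and brute-force
per-read products for chromosome likelihoods.
"""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from sdmap.genmap import MapAnchor, fit_map
from sdmap.likelihood import (
    DistortionModel,
    ancestry_prob,
    estimate_null_ratio,
    loglik_germline,
    optimize_k,
    profile_kmax,
    read_prob,
)

probs = st.floats(0.01, 0.99)
rfracs = st.floats(0.0, 0.5)
errs = st.floats(0.0, 0.4)


def four_term_read_prob(k, r, E):
    return k * (1 - r) * (1 - E) + (1 - k) * r * (1 - E) + k * r * E + (1 - k) * (1 - r) * E


class TestAncestryProb:
    def test_mendelian_symmetry(self):
        for r in (0.0, 0.1, 0.5):
            assert ancestry_prob(0.5, r) == 0.5

    def test_complete_linkage(self):
        assert ancestry_prob(0.64, 0.0) == 0.64

    def test_two_case_enumeration(self):
        # k=0.64, r=0.25: distorted-origin & no swap + other-origin & swap
        assert ancestry_prob(0.64, 0.25) == pytest.approx(0.57, abs=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            ancestry_prob(0.5, 0.6)


class TestReadProb:
    def test_identity_no_error_no_bias(self):
        assert read_prob(0.7) == pytest.approx(0.7)

    def test_error_mixing(self):
        assert read_prob(0.57, error_rate=0.001) == pytest.approx(0.56986, abs=1e-9)

    def test_four_term_equivalence_worked(self):
        k, r, E = 0.64, 0.25, 0.001
        assert read_prob(ancestry_prob(k, r), E) == pytest.approx(
            four_term_read_prob(k, r, E), abs=1e-12
        )

    @given(k=probs, r=rfracs, E=errs)
    @settings(max_examples=100, deadline=None)
    def test_four_term_equivalence_property(self, k, r, E):
        assert read_prob(ancestry_prob(k, r), E, bias=1.0) == pytest.approx(
            four_term_read_prob(k, r, E), abs=1e-12
        )

    def test_bias_calibration_reproduces_somatic_ratio(self):
        for k_s in (0.51, 0.55, 0.62):
            b = DistortionModel.bias_from_null_ratio(k_s)
            assert read_prob(0.5, 0.0, b) == pytest.approx(k_s, abs=1e-12)
            # with error the post-error mix of 0.5 is still 0.5: ratio unchanged
            assert read_prob(0.5, 0.01, b) == pytest.approx(k_s, abs=1e-12)

    @given(q1=probs, q2=probs, E=errs, b=st.floats(0.2, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_q(self, q1, q2, E, b):
        if q1 + 1e-9 < q2:
            assert read_prob(q1, E, b) < read_prob(q2, E, b)

    @given(q=probs, b1=st.floats(0.2, 5.0), b2=st.floats(0.2, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_bias(self, q, b1, b2):
        if b1 < b2:
            assert read_prob(q, 0.0, b1) < read_prob(q, 0.0, b2)

    def test_domain(self):
        with pytest.raises(ValueError):
            read_prob(1.2)
        with pytest.raises(ValueError):
            read_prob(0.5, error_rate=0.5)
        with pytest.raises(ValueError):
            read_prob(0.5, bias=0.0)


class TestEstimateNullRatio:
    def test_pooled_fraction(self):
        assert estimate_null_ratio([550], [450]) == pytest.approx(0.55)

    def test_balanced(self):
        assert estimate_null_ratio([10, 20], [20, 10]) == pytest.approx(0.5)

    def test_error_correction(self):
        # f = 0.55, E = 0.001 -> (0.55 - 0.001)/0.998
        k_s = estimate_null_ratio([550], [450], error_rate=0.001)
        assert k_s == pytest.approx(0.549 / 0.998, rel=1e-12)
        assert k_s == pytest.approx(0.55010, abs=1e-5)

    def test_all_zero_depth_errors(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_null_ratio([0, 0], [0, 0])

    def test_matches_direct_optimization(self, rng):
        lyr = rng.binomial(50, 0.57, size=40)
        hal = 50 - lyr
        k_s = estimate_null_ratio(lyr, hal, error_rate=0.002)
        grid = np.linspace(0.4, 0.7, 20001)
        p = grid * (1 - 0.002) + (1 - grid) * 0.002
        ll = lyr.sum() * np.log(p) + hal.sum() * np.log1p(-p)
        assert k_s == pytest.approx(grid[np.argmax(ll)], abs=2e-4)


@pytest.fixture
def toy_map():
    return fit_map([MapAnchor("c", 1, 0.0), MapAnchor("c", 10_000_000, 10.0)])


def brute_force_loglik(sites, gmap, chromosome, i, k, E, b):
    """Per-read product over an exhaustively enumerated tiny dataset."""
    total = 0.0
    for pos, n_lyr, n_hal in sites:
        r = gmap.recomb_fraction(chromosome, i, pos)
        p = four_term_read_prob(k, r, E)
        p = b * p / (b * p + (1 - p))
        for _ in range(n_lyr):
            total += math.log(p)
        for _ in range(n_hal):
            total += math.log(1 - p)
    return total


class TestLoglikGermline:
    def test_single_site_at_distorter(self, toy_map):
        res = loglik_germline([100], [7], [3], toy_map, "c", 100, 0.7,
                              error_rate=0.0, bias=1.0)
        assert res.loglik == pytest.approx(7 * math.log(0.7) + 3 * math.log(0.3), abs=1e-12)
        assert res.n_sites == 1

    def test_mendelian_position_invariance(self, toy_map):
        sites = ([100, 5000, 2_000_000], [3, 8, 4], [5, 6, 9])
        a = loglik_germline(*sites, toy_map, "c", 100, 0.5, error_rate=0.0)
        b = loglik_germline(*sites, toy_map, "c", 9_000_000, 0.5, error_rate=0.0)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-10)

    def test_empty_counts(self, toy_map):
        res = loglik_germline([100, 200], [0, 0], [0, 0], toy_map, "c", 100, 0.6)
        assert res.loglik == 0.0
        assert res.n_sites == 0

    def test_zero_depth_sites_skipped(self, toy_map):
        full = loglik_germline([100, 900], [7, 0], [3, 0], toy_map, "c", 100, 0.7,
                               error_rate=0.0)
        only = loglik_germline([100], [7], [3], toy_map, "c", 100, 0.7, error_rate=0.0)
        assert full.loglik == pytest.approx(only.loglik)
        assert full.n_sites == 1

    @pytest.mark.parametrize("bias", [1.0, 1.3])
    @pytest.mark.parametrize("error_rate", [0.0, 0.001, 0.01])
    def test_brute_force_oracle(self, toy_map, bias, error_rate):
        # <= 20 reads across 4 sites, enumerated read by read
        sites = [(50, 2, 1), (400_000, 3, 2), (2_500_000, 1, 4), (9_000_000, 4, 3)]
        i, k = 400_000, 0.63
        expected = brute_force_loglik(sites, toy_map, "c", i, k, error_rate, bias)
        res = loglik_germline(
            [s[0] for s in sites], [s[1] for s in sites], [s[2] for s in sites],
            toy_map, "c", i, k, error_rate=error_rate, bias=bias,
        )
        assert res.loglik == pytest.approx(expected, abs=1e-10)


class TestOptimizeK:
    def test_single_site_closed_form(self, toy_map):
        k_hat, _ = optimize_k([100], [70], [30], toy_map, "c", 100,
                              error_rate=0.0, bias=1.0)
        assert k_hat == pytest.approx(0.7, abs=1e-4)

    def test_mendelian_recovery(self, toy_map, rng):
        pos = np.sort(rng.integers(1, 10_000_000, size=300))
        lyr = rng.binomial(60, 0.5, size=300)
        k_hat, _ = optimize_k(pos, lyr, 60 - lyr, toy_map, "c", 5_000_000,
                              error_rate=0.0)
        assert k_hat == pytest.approx(0.5, abs=3 * 0.5 / math.sqrt(300 * 60))

    def test_parameter_recovery_at_truth(self, toy_map, rng):
        i_true, k_true, depth = 4_000_000, 0.64, 200
        pos = np.sort(rng.integers(1, 10_000_000, size=400))
        r = np.asarray(toy_map.recomb_fraction("c", i_true, pos))
        q = k_true * (1 - r) + (1 - k_true) * r
        lyr = rng.binomial(depth, q)
        k_hat, _ = optimize_k(pos, lyr, depth - lyr, toy_map, "c", i_true,
                              error_rate=0.0)
        se = math.sqrt(k_true * (1 - k_true) / (400 * depth))
        assert k_hat == pytest.approx(k_true, abs=4 * se)

    def test_no_data_returns_mendelian(self, toy_map):
        assert optimize_k([100], [0], [0], toy_map, "c", 100) == (0.5, 0.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_optimizer_dominance(self, toy_map, seed):
        r = np.random.default_rng(seed)
        pos = np.sort(r.integers(1, 10_000_000, size=25))
        lyr = r.binomial(20, 0.58, size=25)
        k_hat, best = optimize_k(pos, lyr, 20 - lyr, toy_map, "c", 1_000_000,
                                 error_rate=0.001, bias=1.1)
        for k in np.linspace(0.05, 0.95, 19):
            ll = loglik_germline(pos, lyr, 20 - lyr, toy_map, "c", 1_000_000,
                                 float(k), error_rate=0.001, bias=1.1).loglik
            assert best >= ll - 1e-9


class TestProfileKernel:
    """The vectorised Newton kernel must agree with the scalar Brent route."""

    @pytest.mark.parametrize("bias", [1.0, 0.8, 1.25])
    def test_agreement_with_optimize_k(self, toy_map, bias, rng):
        pos = np.sort(rng.integers(1, 10_000_000, size=60))
        lyr = rng.binomial(35, 0.61, size=60)
        hal = 35 - lyr
        grid = np.array([100, 2_000_000, 5_500_000, 9_999_000])
        site_m = np.asarray(toy_map.genetic_position("c", pos))
        grid_m = np.asarray(toy_map.genetic_position("c", grid))
        d = np.abs(grid_m[:, None] - site_m[None, :])
        rr = 0.5 * (1 - np.exp(-2 * d))
        E = 0.001
        alpha = E + (1 - 2 * E) * rr
        beta = (1 - 2 * E) * (1 - 2 * rr)
        k_vec, ll_vec = profile_kmax(alpha, beta, lyr, hal, bias=bias)
        for j, i_pos in enumerate(grid):
            k_ref, ll_ref = optimize_k(pos, lyr, hal, toy_map, "c", int(i_pos),
                                       error_rate=E, bias=bias, tol=1e-9)
            assert k_vec[j] == pytest.approx(k_ref, abs=1e-5)
            assert ll_vec[j] == pytest.approx(ll_ref, abs=1e-7)

    def test_weights_equal_row_duplication(self, toy_map, rng):
        pos = np.sort(rng.integers(1, 10_000_000, size=30))
        lyr = rng.binomial(25, 0.6, size=30)
        hal = 25 - lyr
        w = rng.multinomial(30, np.full(30, 1 / 30))
        site_m = np.asarray(toy_map.genetic_position("c", pos))
        d = np.abs(0.03 - site_m)[None, :]
        rr = 0.5 * (1 - np.exp(-2 * d))
        alpha, beta = 0.0 + rr, 1 - 2 * rr
        k_w, ll_w = profile_kmax(alpha, beta, lyr, hal, weights=w)
        rep = np.repeat(np.arange(30), w)
        k_d, ll_d = profile_kmax(alpha[:, rep], beta[:, rep], lyr[rep], hal[rep])
        assert k_w[0] == pytest.approx(k_d[0], abs=1e-6)
        assert ll_w[0] == pytest.approx(ll_d[0], abs=1e-6)
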