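"""Growth-rate fits, yield arithmetic and Duncan's multiple range test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from kivdesign import (
    BatchSimParams,
    characterize_culture,
    compute_yields,
    detect_exponential_phase,
    duncan_mrt,
    fit_mu_max,
    linear_calibration,
    od_to_dcw,
    simulate_batch_culture,
)


class TestOdToDcw:
    @pytest.mark.parametrize("od, expected", [(1.0, 0.452), (0.0, 0.0), (2.0, 0.904)])
    def test_linear_conversion(self, od, expected):
        assert od_to_dcw(od) == pytest.approx(expected, abs=1e-12)

    def test_negative_od_rejected(self):
        with pytest.raises(ValueError):
            od_to_dcw(-0.1)


class TestExponentialPhase:
    def test_pure_exponential_selects_full_range(self):
        t = np.arange(0.0, 6.0, 0.5)
        X = 0.1 * np.exp(0.5 * t)
        assert detect_exponential_phase(t, X) == (0, len(t))

    def test_plateau_excluded_and_beats_full_range_fit(self):
        """Exhaustive window enumeration oracle: the detected window must
        achieve the best R^2 among all admissible windows, and beat the
        full-range fit when a plateau is present."""
        t = np.arange(0.0, 15.0, 1.0)
        X = np.minimum(0.1 * np.exp(0.4 * t), 2.0)  # exponential then plateau
        start, stop = detect_exponential_phase(t, X, min_points=4)
        plateau_start = int(np.argmax(X >= 2.0))
        assert stop <= plateau_start + 1

        def window_r2(i, j):
            res = stats.linregress(t[i:j], np.log(X[i:j]))
            return res.rvalue ** 2

        best = max(window_r2(i, j)
                   for i, j in itertools.combinations(range(len(t) + 1), 2)
                   if j - i >= 4 and np.ptp(np.log(X[i:j])) > 0)
        assert window_r2(start, stop) == pytest.approx(best, abs=1e-12)
        assert window_r2(start, stop) > window_r2(0, len(t))

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            detect_exponential_phase([0.0, 1.0], [1.0, 2.0], min_points=4)

    def test_nonpositive_biomass_excluded_from_windows(self):
        t = np.arange(8.0)
        X = np.array([0.0, 0.1, 0.15, 0.22, 0.33, 0.5, 0.74, 1.1])
        start, stop = detect_exponential_phase(t, X)
        assert start >= 1  # the zero reading cannot enter the window


class TestMuMax:
    def test_noiseless_recovery_is_exact(self):
        t = np.linspace(0.0, 5.0, 11)
        fit = fit_mu_max(t, 0.1 * np.exp(0.5 * t))
        assert fit.mu_max == pytest.approx(0.5, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_biomass_gives_zero_rate(self):
        fit = fit_mu_max(np.arange(5.0), np.full(5, 2.0), window=(0, 5))
        assert fit.mu_max == 0.0

    def test_noisy_replicates_recover_mean_rate(self):
        mus = []
        for seed in range(20):
            c = simulate_batch_culture(BatchSimParams(noise_sd=0.02, seed=seed))
            mus.append(fit_mu_max(c.time_h.values, c.dcw_g_l.values).mu_max)
        assert np.mean(mus) == pytest.approx(0.5, rel=0.02)

    def test_zero_time_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_mu_max([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4], window=(0, 4))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           mu=st.floats(min_value=0.05, max_value=1.5))
    def test_invariant_to_biomass_rescaling(self, scale, mu):
        """The slope of a logarithm ignores multiplicative units (OD vs
        gDCW/L vs cells/mL)."""
        t = np.linspace(0.0, 4.0, 9)
        X = 0.08 * np.exp(mu * t)
        a = fit_mu_max(t, X, window=(0, 9)).mu_max
        b = fit_mu_max(t, scale * X, window=(0, 9)).mu_max
        assert a == pytest.approx(b, rel=1e-9)


class TestYields:
    def test_published_endpoint_yields(self):
        # glucose and lactose batches of the producer strain
        assert compute_yields(0.408, 10.2, 2.18)[1] == pytest.approx(0.21, abs=0.005)
        assert compute_yields(0.45, 9.0, 2.41)[1] == pytest.approx(0.27, abs=0.005)

    def test_zero_substrate_rejected(self):
        with pytest.raises(ValueError, match="substrate"):
            compute_yields(1.0, 0.0, 1.0)

    def test_zero_biomass_rejected(self):
        with pytest.raises(ValueError, match="biomass"):
            compute_yields(0.0, 1.0, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_homogeneous_of_degree_zero(self, scale):
        base = compute_yields(0.4, 10.0, 2.0)
        scaled = compute_yields(0.4 * scale, 10.0 * scale, 2.0 * scale)
        assert np.allclose(base, scaled, rtol=1e-9)

    def test_closed_loop_with_simulator(self):
        params = BatchSimParams(mu=0.45, Yxs=0.35, Yps=0.22)
        c = simulate_batch_culture(params)
        est = characterize_culture(c.time_h, c.dcw_g_l, c.substrate_g_l, c.product_g_l)
        assert est.mu_max == pytest.approx(params.mu, rel=1e-9)
        assert est.Yxs == pytest.approx(params.Yxs, rel=1e-9)
        assert est.Yps == pytest.approx(params.Yps, rel=1e-9)


def test_linear_calibration_recovers_line():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    slope, intercept, r2 = linear_calibration(x, 2.5 * x + 0.3)
    assert (slope, intercept) == pytest.approx((2.5, 0.3), rel=1e-9)
    assert r2 == pytest.approx(1.0, abs=1e-12)


class TestDuncan:
    def test_identical_groups_share_one_letter(self):
        groups = [np.array([1.0, 1.1, 0.9])] * 3
        comp = duncan_mrt(groups)
        assert len(set(comp.letters.values())) == 1

    def test_far_apart_groups_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        comp = duncan_mrt([rng.normal(0, 1, 5), rng.normal(100, 1, 5)])
        assert comp.letters["g1"] != comp.letters["g2"]

    def test_two_groups_reduce_to_fisher_lsd(self):
        """With k=2 the protection level collapses to alpha, so the Duncan
        decision must equal the pooled-t LSD closed form, across effect
        sizes straddling the boundary."""
        rng = np.random.default_rng(3)
        for shift in (0.0, 0.5, 1.0, 1.5, 2.0, 3.0):
            g1 = rng.normal(0.0, 1.0, 6)
            g2 = rng.normal(shift, 1.0, 6)
            comp = duncan_mrt([g1, g2], alpha=0.05)
            duncan_sig = comp.letters["g1"] != comp.letters["g2"]

            n1, n2 = len(g1), len(g2)
            df = n1 + n2 - 2
            sp2 = (((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()) / df
            lsd = stats.t.ppf(0.975, df) * np.sqrt(sp2 * (1 / n1 + 1 / n2))
            assert duncan_sig == (abs(g1.mean() - g2.mean()) > lsd)

    def test_letter_display_is_transitively_consistent(self):
        rng = np.random.default_rng(7)
        means = [0.0, 0.3, 0.6, 3.0, 3.2]
        groups = [rng.normal(m, 0.5, 5) for m in means]
        comp = duncan_mrt(groups)
        # sharing a letter is reflexive/symmetric by construction; check
        # that any two groups declared different share no letter and that
        # each group has at least one letter
        for lab in comp.letters:
            assert comp.letters[lab]
        shared = {(a, b): bool(set(comp.letters[a]) & set(comp.letters[b]))
                  for a in comp.letters for b in comp.letters}
        for a in comp.letters:
            assert shared[(a, a)]

    def test_significance_monotone_in_mean_difference(self):
        rng = np.random.default_rng(5)
        noise = [rng.normal(0, 1, 5) for _ in range(2)]
        decisions = []
        for shift in (0.0, 1.0, 2.0, 4.0, 8.0, 16.0):
            comp = duncan_mrt([noise[0], noise[1] + shift])
            decisions.append(comp.letters["g1"] != comp.letters["g2"])
        assert decisions == sorted(decisions)  # once significant, stays so

    def test_zero_variance_unequal_means_all_significant(self):
        comp = duncan_mrt([np.full(3, 1.0), np.full(3, 2.0), np.full(3, 3.0)])
        letters = list(comp.letters.values())
        assert len(set(letters)) == 3

    def test_single_replicate_group_rejected(self):
        with pytest.raises(ValueError):
            duncan_mrt([np.array([1.0]), np.array([1.0, 2.0])])

    def test_null_family_error_matches_protected_level(self):
        """Under equal true means with k=2 groups, the rejection rate
        should match alpha within Monte-Carlo error."""
        rng = np.random.default_rng(11)
        alpha = 0.05
        reps = 1000
        hits = 0
        for _ in range(reps):
            g1 = rng.normal(0, 1, 5)
            g2 = rng.normal(0, 1, 5)
            comp = duncan_mrt([g1, g2], alpha=alpha)
            hits += comp.letters["g1"] != comp.letters["g2"]
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(hits / reps - alpha) < 4 * se
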