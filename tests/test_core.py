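"""Unit and property tests for the continuous and discrete circle models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from socialcircles.core import (
    DegenerateWeightsError,
    NormalizedDistances,
    Regime,
    TieWeights,
    chi_continuous,
    chi_discrete,
    discrete_layer_probs,
    eta_confidence_interval,
    eta_from_mu,
    fit_ego,
    log_derivative_chi,
    log_likelihood,
    mean_distance_curve,
    normalize_distances,
    solve_eta,
)
from socialcircles.synth import sample_tie_distances


def nd_from_t(t_values):
    t = np.asarray(t_values, dtype=float)
    return NormalizedDistances(
        ego_id="t", t_values=tuple(t), t_bar=float(t.mean()),
        s_max=1.0, s_min=0.0, sigma=float(1.0 - t.mean()),
    )


class TestNormalizeDistances:
    def test_hand_computed_example(self):
        nd = normalize_distances(TieWeights("e", [1, 1, 10]))
        assert nd.s_max == 10 and nd.s_min == 1
        assert nd.t_values == (1.0, 1.0, 0.0)
        assert nd.t_bar == pytest.approx(2 / 3)

    def test_sigma_is_mean_weight_and_consistent_with_t_bar(self):
        nd = normalize_distances(TieWeights("e", [2, 4, 6]))
        assert nd.sigma == 4.0
        # t_bar = (s_max - sigma)/(s_max - s_min)
        assert nd.t_bar == pytest.approx((nd.s_max - nd.sigma) / (nd.s_max - nd.s_min))

    def test_degenerate_weights_rejected(self):
        with pytest.raises(DegenerateWeightsError):
            normalize_distances(TieWeights("e", [3, 3, 3]))

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            TieWeights("e", [1.0, 0.0, 2.0])

    @given(
        st.lists(st.floats(0.5, 100.0), min_size=2, max_size=40).filter(
            lambda w: max(w) > min(w)
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_t_values_bounded_with_both_endpoints(self, weights):
        nd = normalize_distances(TieWeights("e", weights))
        t = np.array(nd.t_values)
        assert t.min() == 0.0 and t.max() == 1.0
        assert np.all((t >= 0) & (t <= 1))


class TestMeanDistanceCurve:
    @pytest.mark.parametrize(
        "eta, expected, tol",
        [
            (0.0, 0.5, 0.0),
            (6.0, 0.8358182, 1e-6),
            (-6.0, 0.1641818, 1e-6),
        ],
    )
    def test_reference_values(self, eta, expected, tol):
        assert mean_distance_curve(eta) == pytest.approx(expected, abs=max(tol, 1e-12))

    def test_symmetry_on_grid(self):
        for eta in np.linspace(-40, 40, 201):
            assert mean_distance_curve(-eta) == pytest.approx(
                1 - mean_distance_curve(eta), abs=1e-12
            )

    def test_strictly_increasing(self):
        grid = np.linspace(-50, 50, 501)
        vals = [mean_distance_curve(e) for e in grid]
        assert np.all(np.diff(vals) > 0)

    def test_series_agrees_with_closed_form_at_cutoff(self):
        # series expansion matches the exact expression where it takes over
        eta = 1.2e-4
        closed = 1.0 / (-math.expm1(-eta)) - 1.0 / eta
        series = 0.5 + eta / 12.0 - eta**3 / 720.0
        assert series == pytest.approx(closed, abs=1e-11)


class TestSolveEta:
    @pytest.mark.parametrize(
        "t_bar, expected, tol",
        [
            (0.5, 0.0, 1e-12),
            (0.8358182, 6.0, 1e-4),
            (2 / 3, 2.149, 1e-2),
        ],
    )
    def test_reference_values(self, t_bar, expected, tol):
        assert solve_eta(t_bar) == pytest.approx(expected, abs=tol)

    def test_round_trip_over_grid(self):
        for eta in np.linspace(-30, 30, 121):
            assert solve_eta(mean_distance_curve(eta)) == pytest.approx(eta, abs=1e-6)

    def test_antisymmetry_on_grid(self):
        for t in np.linspace(0.01, 0.99, 100):
            assert solve_eta(1 - t) == pytest.approx(-solve_eta(t), abs=1e-12)

    def test_sign_matches_t_bar(self):
        assert solve_eta(0.7) > 0 and solve_eta(0.3) < 0

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            solve_eta(bad)

    @given(st.floats(-200.0, 200.0))
    @settings(deadline=None, derandomize=True)
    def test_round_trip_property(self, eta):
        t = mean_distance_curve(eta)
        if 0.0 < t < 1.0:
            assert solve_eta(t) == pytest.approx(eta, abs=1e-5)


class TestChiContinuous:
    def test_normalization_endpoints(self):
        for eta in (-8.0, 0.0, 3.7, 25.0):
            assert chi_continuous(0.0, eta) == pytest.approx(0.0, abs=1e-12)
            assert chi_continuous(1.0, eta) == pytest.approx(1.0, abs=1e-12)

    def test_reference_value(self):
        assert chi_continuous(0.5, 6.0) == pytest.approx(0.047426, abs=1e-5)

    def test_uniform_limit(self):
        assert chi_continuous(0.3, 0.0) == pytest.approx(0.3, abs=1e-9)

    def test_strictly_increasing_in_t(self):
        for eta in (-10.0, -1.0, 0.0, 1.0, 10.0):
            vals = [chi_continuous(t, eta) for t in np.linspace(0, 1, 101)]
            assert np.all(np.diff(vals) > 0)

    def test_matches_sampling_cdf(self, rng):
        # empirical CDF of the generator's draws follows chi(t; eta)
        eta = 4.0
        t = sample_tie_distances(eta, 20000, rng)
        for q in (0.25, 0.5, 0.75):
            assert np.mean(t <= q) == pytest.approx(chi_continuous(q, eta), abs=0.01)


class TestLogDerivativeChi:
    def test_large_eta_asymptote(self):
        assert log_derivative_chi(1.0, 50.0) == pytest.approx(50.0, rel=1e-10)

    def test_negative_eta_asymptote(self):
        assert abs(log_derivative_chi(1.0, -50.0)) < 1e-10

    def test_reference_value(self):
        expected = 2 * math.e / (math.e - 1)
        assert log_derivative_chi(0.5, 2.0) == pytest.approx(expected, rel=1e-12)

    def test_singular_at_zero(self):
        with pytest.raises(ValueError):
            log_derivative_chi(0.0, 2.0)


class TestLogLikelihood:
    def test_uniform_density_limit(self):
        assert log_likelihood(nd_from_t([0.2, 0.8]), 0.0) == 0.0

    def test_single_point_reference(self):
        # ln(1) + 0.5 - ln(e - 1)
        expected = 0.5 - math.log(math.e - 1)
        assert log_likelihood(nd_from_t([0.5]), 1.0) == pytest.approx(expected, abs=1e-9)

    def test_argmax_coincides_with_implicit_equation(self, rng):
        # independent oracle: numerical maximization of the likelihood
        for _ in range(25):
            eta_true = rng.uniform(-8, 8)
            L = int(rng.integers(10, 500))
            t = sample_tie_distances(eta_true, L, rng)
            nd = nd_from_t(t)
            res = minimize_scalar(
                lambda e: -log_likelihood(nd, e), bounds=(-60, 60), method="bounded",
                options={"xatol": 1e-10},
            )
            assert solve_eta(nd.t_bar) == pytest.approx(res.x, abs=1e-6)

    def test_continuous_through_zero(self):
        nd = nd_from_t([0.2, 0.9, 0.4])
        assert log_likelihood(nd, 1e-9) == pytest.approx(0.0, abs=1e-8)


class TestConfidenceInterval:
    def test_contains_estimate_and_truth_at_large_L(self, rng):
        t = sample_tie_distances(3.0, 10000, rng)
        nd = nd_from_t(t)
        eta_hat = solve_eta(nd.t_bar)
        lo, hi = eta_confidence_interval(nd, eta_hat, delta=0.025)
        assert lo <= eta_hat <= hi
        assert lo <= 3.0 <= hi
        assert hi - lo < 0.2

    def test_width_matches_fisher_information_oracle(self, rng):
        # asymptotically the 95% CI half-width is 1.96 / sqrt(L * I(eta)),
        # with I(eta) = 1/eta^2 - e^eta/(e^eta - 1)^2 for this density
        eta = 3.0
        t = sample_tie_distances(eta, 10000, rng)
        nd = nd_from_t(t)
        eta_hat = solve_eta(nd.t_bar)
        lo, hi = eta_confidence_interval(nd, eta_hat, delta=0.025)
        info = 1 / eta**2 - math.exp(eta) / (math.exp(eta) - 1) ** 2
        expected_half = 1.959964 / math.sqrt(nd.L * info)
        assert (hi - lo) / 2 == pytest.approx(expected_half, rel=0.05)

    def test_nesting_in_delta(self, rng):
        t = sample_tie_distances(2.0, 100, rng)
        nd = nd_from_t(t)
        eta_hat = solve_eta(nd.t_bar)
        lo_wide, hi_wide = eta_confidence_interval(nd, eta_hat, delta=0.025)
        lo_narrow, hi_narrow = eta_confidence_interval(nd, eta_hat, delta=0.25)
        assert lo_wide < lo_narrow <= eta_hat <= hi_narrow < hi_wide

    def test_bad_delta_rejected(self):
        with pytest.raises(ValueError):
            eta_confidence_interval(nd_from_t([0.2, 0.8]), 0.0, delta=0.6)


class TestFitEgo:
    def test_recovers_planted_eta(self):
        rng = np.random.default_rng(4)
        t = sample_tie_distances(6.0, 1000, rng)
        weights = tuple(10.0 - 9.0 * x for x in t)
        fit = fit_ego(TieWeights("e", weights))
        assert abs(fit.eta - 6.0) < 0.3
        assert fit.ci_low <= 6.0 <= fit.ci_high
        assert fit.regime is Regime.NORMAL

    def test_chains_solve_eta_example(self):
        fit = fit_ego(TieWeights("e", [1, 1, 10]))
        assert fit.eta == pytest.approx(2.149, abs=1e-2)
        assert fit.regime is Regime.NORMAL

    def test_mirrored_weights_flip_sign(self):
        w = [1.0, 2.0, 5.0, 9.0, 10.0]
        mirrored = [11.0 - x for x in w]  # sends t -> 1 - t
        assert fit_ego(TieWeights("a", w)).eta == pytest.approx(
            -fit_ego(TieWeights("b", mirrored)).eta, abs=1e-9
        )

    def test_degenerate_propagates(self):
        with pytest.raises(DegenerateWeightsError):
            fit_ego(TieWeights("e", [2, 2, 2, 2, 2]))


class TestDiscreteModel:
    def test_uniform_probs_at_zero(self):
        m = discrete_layer_probs([3.0, 2.0, 1.0], 0.0)
        assert m.probs == pytest.approx([1 / 3] * 3)

    def test_two_category_example(self):
        m = discrete_layer_probs([1.0, 0.0], math.log(2))
        assert m.probs == pytest.approx([1 / 3, 2 / 3])

    def test_probs_sum_to_one(self, rng):
        for _ in range(20):
            costs = np.sort(rng.uniform(0, 10, int(rng.integers(2, 8))))[::-1]
            if len(set(costs)) < len(costs):
                continue
            m = discrete_layer_probs(costs, rng.uniform(-3, 3))
            assert sum(m.probs) == pytest.approx(1.0, abs=1e-12)

    def test_nondecreasing_costs_rejected(self):
        with pytest.raises(ValueError):
            discrete_layer_probs([1.0, 2.0], 0.5)

    def test_chi_closed_form_r4(self):
        chis = [chi_discrete(k, 4, math.log(3)) for k in range(1, 5)]
        assert chis == pytest.approx([0.025, 0.1, 0.325, 1.0], abs=1e-12)

    def test_chi_uniform_limit(self):
        assert [chi_discrete(k, 4, 0.0) for k in range(1, 5)] == pytest.approx(
            [0.25, 0.5, 0.75, 1.0]
        )

    def test_chi_last_is_one_and_nondecreasing(self):
        for mu in (-4.0, -0.5, 0.0, 0.5, 4.0, 12.0):
            chis = [chi_discrete(k, 5, mu) for k in range(1, 6)]
            assert chis[-1] == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(chis) >= 0)

    def test_chi_index_error(self):
        with pytest.raises(IndexError):
            chi_discrete(0, 4, 1.0)

    def test_scaling_ratio_asymptotics(self):
        # consecutive circle sizes scale like e^mu for large mu
        for mu in (5.0, 7.0, 10.0):
            for k in range(1, 6):
                ratio = chi_discrete(k + 1, 6, mu) / chi_discrete(k, 6, mu)
                # bound holds exactly in real arithmetic; floor at the
                # double-precision resolution of the ratio itself
                bound = max(math.exp(-mu * k) * (1 + 1e-9), 1e-13)
                assert abs(ratio / math.exp(mu) - 1) <= bound

    def test_layer_model_mu_relation(self):
        m = discrete_layer_probs([9.0, 6.0, 3.0, 0.0], 0.4)
        assert m.mu == pytest.approx(0.4 * 9.0 / 3.0)
        assert m.circle_sizes[-1] == pytest.approx(1.0)


class TestEtaFromMu:
    def test_canonical_four_layer_value(self):
        assert eta_from_mu(math.log(3), 4) == 6.0

    def test_regime_boundary_maps_to_itself(self):
        for r in (2, 4, 10):
            assert eta_from_mu(0.0, r) == 0.0

    def test_direct_evaluation(self):
        assert eta_from_mu(1.0, 4) == pytest.approx(3 * (math.e - 1), rel=1e-12)
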