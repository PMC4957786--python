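"""Tests for the Gaussian belief algebra and the preference-shift likelihood.

The closed-form posteriors are checked against a brute-force numerical
integration of the underlying three-variable model (self taste, other taste,
latent reference mean with a flat prior), which serves as the independent
oracle throughout.
"""

import math

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

from prefshift.data import ParticipantDataset, Trial
from prefshift.models import OptionPair, apply_lapse, relax_policy
from prefshift.social import (
    GaussianBelief,
    OtherBeliefFilter,
    PSParams,
    other_likelihood_filter,
    posterior_other,
    posterior_self,
    ps_loglik,
    ps_trial_policy,
    ps_trial_probabilities,
)

from conftest import make_pair


def grid_posterior_self(ms, us, ko_hat, uo, sigma_r, n=801, span=8.0):
    """Brute-force oracle: marginalise the latent reference mean and the
    Other's taste numerically, then moment-match the self posterior."""
    lo = min(ms - span * math.sqrt(us), ko_hat - span * math.sqrt(uo + 2 * sigma_r**2))
    hi = max(ms + span * math.sqrt(us), ko_hat + span * math.sqrt(uo + 2 * sigma_r**2))
    ks = np.linspace(lo, hi, n)
    kr = np.linspace(lo - 4 * sigma_r, hi + 4 * sigma_r, n)
    ko = np.linspace(ko_hat - span * math.sqrt(uo + 1e-12) - 4 * sigma_r,
                     ko_hat + span * math.sqrt(uo + 1e-12) + 4 * sigma_r, n)
    # g(kr) = ∫ N(ko; ko_hat, uo) N(ko; kr, sigma_r^2) dko
    like_ko = norm.pdf(ko[None, :], ko_hat, math.sqrt(max(uo, 1e-12)))
    link = norm.pdf(ko[None, :], kr[:, None], sigma_r)
    g = np.trapezoid(like_ko * link, ko, axis=1)
    # f(ks) = N(ks; ms, us) ∫ N(ks; kr, sigma_r^2) g(kr) dkr   (flat prior on kr)
    link2 = norm.pdf(ks[:, None], kr[None, :], sigma_r)
    f = norm.pdf(ks, ms, math.sqrt(us)) * np.trapezoid(link2 * g[None, :], kr, axis=1)
    z = np.trapezoid(f, ks)
    mean = np.trapezoid(ks * f, ks) / z
    var = np.trapezoid((ks - mean) ** 2 * f, ks) / z
    return float(mean), float(var)


class TestPosteriorAlgebra:
    def test_irrelevant_other_leaves_self_unchanged(self):
        b = posterior_self(GaussianBelief(-4.0, 1.5), GaussianBelief(-1.0, 0.2), 1e8)
        assert b.mean == pytest.approx(-4.0, abs=1e-6)
        assert b.var == pytest.approx(1.5, rel=1e-6)

    def test_equal_precision_midpoint(self):
        # self (0, 1); other (2, 0) widened by 2 * 0.5 = 1: equal precisions
        b = posterior_self(GaussianBelief(0.0, 1.0), GaussianBelief(2.0, 0.0),
                           math.sqrt(0.5))
        assert b.mean == pytest.approx(1.0)
        assert b.var == pytest.approx(0.5)

    def test_flat_other_gives_widened_self(self):
        b = posterior_other(GaussianBelief(-5.0, 2.0), GaussianBelief.flat(), 1.13)
        assert b.mean == pytest.approx(-5.0)
        assert b.var == pytest.approx(2.0 + 2 * 1.13**2)

    def test_role_symmetry(self):
        a = GaussianBelief(-5.0, 2.0)
        b = GaussianBelief(-2.7, 0.4)
        assert posterior_other(a, b, 1.13).mean == pytest.approx(
            posterior_self(b, a, 1.13).mean
        )

    def test_both_flat_is_improper(self):
        with pytest.raises(ValueError):
            posterior_self(GaussianBelief.flat(), GaussianBelief.flat(), 1.0)

    def test_matches_grid_integration_oracle(self):
        mean, var = grid_posterior_self(-5.0, 2.0, -2.7, 0.4, 1.13)
        b = posterior_self(GaussianBelief(-5.0, 2.0), GaussianBelief(-2.7, 0.4), 1.13)
        assert b.mean == pytest.approx(mean, abs=1e-3)
        assert b.var == pytest.approx(var, abs=1e-3)

    def test_oracle_sweep(self):
        """Closed form vs numerical integration across a parameter sweep."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            ms = rng.uniform(-8, 0)
            us = rng.uniform(0.1, 4.0)
            ko = ms + rng.uniform(-4, 4)
            uo = rng.uniform(0.05, 2.0)
            sr = rng.uniform(0.3, 3.0)
            mean, var = grid_posterior_self(ms, us, ko, uo, sr)
            b = posterior_self(GaussianBelief(ms, us), GaussianBelief(ko, uo), sr)
            assert b.mean == pytest.approx(mean, abs=1e-3)
            assert b.var == pytest.approx(var, abs=1e-3)

    def test_no_overtaking_and_shift_sign(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ms = rng.uniform(-8, 0)
            us = rng.uniform(0.01, 5.0)
            ko = ms + rng.uniform(-5, 5)
            uo = rng.uniform(0.01, 3.0)
            sr = rng.uniform(0.1, 5.0)
            b = posterior_self(GaussianBelief(ms, us), GaussianBelief(ko, uo), sr)
            shift = b.mean - ms
            assert abs(shift) <= abs(ko - ms) + 1e-12
            if ko != ms:
                assert shift * (ko - ms) >= 0
            assert b.var <= us + 1e-12

    def test_shift_monotone_in_uncertainty_and_relevance(self):
        ms, ko, uo = -5.0, -2.7, 0.3
        shifts_u = [
            posterior_self(GaussianBelief(ms, u), GaussianBelief(ko, uo), 1.0).mean - ms
            for u in np.linspace(0.1, 5.0, 12)
        ]
        assert np.all(np.diff(shifts_u) > 0)
        shifts_sr = [
            posterior_self(GaussianBelief(ms, 1.0), GaussianBelief(ko, uo), sr).mean - ms
            for sr in np.linspace(0.2, 5.0, 12)
        ]
        assert np.all(np.diff(shifts_sr) < 0)


class TestOtherLikelihoodFilter:
    def test_empty_is_flat(self):
        assert other_likelihood_filter([]).is_flat

    def test_calibration_recovers_generating_taste(self, rng):
        """Over replicate simulated choice histories from a fixed partner
        taste, the filtered mean should cover the truth."""
        k_o, n_rep = -2.2, 60
        hits = 0
        for _ in range(n_rep):
            obs = []
            for _ in range(60):
                theta = rng.uniform(-6, 1)
                pair = make_pair(theta, R0=float(rng.uniform(1, 10)))
                pi = 1.0 / (1.0 + math.exp(
                    (pair.R0 - pair.RD / (1 + math.exp(k_o) * pair.D))))
                obs.append((pair, int(rng.random() < pi)))
            b = other_likelihood_filter(obs)
            if abs(b.mean - k_o) <= 2 * math.sqrt(b.var):
                hits += 1
        assert hits / n_rep >= 0.9

    def test_variance_shrinks_with_data(self, rng):
        diffs = []
        for _ in range(40):
            f = OtherBeliefFilter()
            k_o = -3.0

            def observe(n):
                for _ in range(n):
                    pair = make_pair(float(rng.uniform(-6, 0)))
                    pi = 1.0 / (1.0 + math.exp(
                        (pair.R0 - pair.RD / (1 + math.exp(k_o) * pair.D))))
                    f.update(pair, int(rng.random() < pi))

            observe(10)
            v10 = f.belief().var
            observe(10)
            diffs.append(v10 - f.belief().var)
        assert np.mean(diffs) > 0

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            OtherBeliefFilter(grid=(0.0, 0.0, 1))


class TestPSPolicy:
    def test_phase1_reduces_to_ku_with_lapse(self):
        params = PSParams(m_s=-4.0, u_s=1.0, sigma_r=1.0, tau_o=1.0, xi=0.1)
        pair = make_pair(-3.5)
        got = ps_trial_policy(pair, "self", params, GaussianBelief.flat())
        expected = apply_lapse(norm.cdf((-3.5 + 4.0) / 1.0), 0.1)
        assert got == pytest.approx(expected)

    def test_boundary_parameters_collapse_to_ku(self):
        params = PSParams(m_s=-4.0, u_s=1.0, sigma_r=1e6, tau_o=1.0, xi=0.0)
        pair = make_pair(-3.0)
        other_b = GaussianBelief(-1.0, 0.2)
        got_self = ps_trial_policy(pair, "self", params, other_b)
        assert got_self == pytest.approx(norm.cdf(1.0), abs=1e-4)

    def test_invalid_role(self):
        params = PSParams(-4.0, 1.0, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            ps_trial_policy(make_pair(-3.0), "partner", params, GaussianBelief.flat())

    def test_toy_sequence_matches_hand_filter(self, toy_dataset):
        """Per-trial probabilities replicate an explicit step-by-step filter
        written out independently."""
        params = PSParams(m_s=-4.5, u_s=1.5, sigma_r=1.2, tau_o=1.3, xi=0.04)
        pi_s, c_s, pi_o, c_o = ps_trial_probabilities(params, toy_dataset)

        # hand filter: grid product of unit-temperature softmax likelihoods
        nodes = np.linspace(-12, 2, 601)
        cum = np.zeros_like(nodes)

        def belief():
            if not np.any(cum):
                return None
            w = np.exp(cum - cum.max())
            w /= w.sum()
            mu = float(w @ nodes)
            return mu, float(w @ (nodes - mu) ** 2)

        def softmax_pi(pair):
            qd = pair.RD / (1 + np.exp(nodes) * pair.D)
            return expit(qd - pair.R0)

        expect_self, expect_other = [], []
        for t in toy_dataset.trials:
            b = belief()
            theta = t.pair.indifference_k
            if t.role == "self":
                if b is None:
                    mu, var = params.m_s, params.u_s
                else:
                    prec = 1 / params.u_s + 1 / (2 * params.sigma_r**2 + b[1])
                    mu = (params.m_s / params.u_s
                          + b[0] / (2 * params.sigma_r**2 + b[1])) / prec
                    var = 1 / prec
                expect_self.append(
                    apply_lapse(norm.cdf((theta - mu) / math.sqrt(var)), params.xi)
                )
            else:
                if b is None:
                    mu = params.m_s
                    var = params.u_s + 2 * params.sigma_r**2
                else:
                    prec = 1 / b[1] + 1 / (2 * params.sigma_r**2 + params.u_s)
                    mu = (b[0] / b[1]
                          + params.m_s / (2 * params.sigma_r**2 + params.u_s)) / prec
                    var = 1 / prec
                expect_other.append(
                    relax_policy(norm.cdf((theta - mu) / math.sqrt(var)), params.tau_o)
                )
                pi_like = softmax_pi(t.pair)
                cum += np.log(pi_like if t.other_choice == 1 else 1 - pi_like)

        np.testing.assert_allclose(pi_s, expect_self, atol=1e-9)
        np.testing.assert_allclose(pi_o, expect_other, atol=1e-9)


class TestPSLoglik:
    def test_phase1_only_reduces_to_ku(self):
        trials = [
            Trial(phase=1, index=i, role="self", pair=make_pair(th), choice=c)
            for i, (th, c) in enumerate([(-5.0, 0), (-4.0, 1), (-3.0, 1), (-4.5, 0)])
        ]
        ds = ParticipantDataset("p", trials)
        params = PSParams(m_s=-4.2, u_s=1.3, sigma_r=1.0, tau_o=1.0, xi=0.0)
        expected = sum(
            math.log(p if c else 1 - p)
            for p, c in (
                (norm.cdf((th + 4.2) / math.sqrt(1.3)), c)
                for th, c in [(-5.0, 0), (-4.0, 1), (-3.0, 1), (-4.5, 0)]
            )
        )
        assert ps_loglik(params, ds) == pytest.approx(expected)

    def test_missing_feedback_raises(self):
        trials = [
            Trial(phase=2, index=0, role="other", pair=make_pair(-4.0), choice=1),
        ]
        ds = ParticipantDataset("p", trials)
        with pytest.raises(ValueError):
            ps_loglik(PSParams(-4.0, 1.0, 1.0, 1.0, 0.0), ds)

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            ps_loglik(PSParams(-4.0, 1.0, 1.0, 1.0, 0.0), ParticipantDataset("p", []))

    def test_sigma_r_profile_peaks_near_truth(self, simulated_participant, ps_agent):
        """The likelihood at the generating sigma_r exceeds the likelihood at
        values far from it (profile shape)."""
        base = ps_loglik(ps_agent, simulated_participant)
        for far_sr in (0.05, 50.0):
            far = PSParams(ps_agent.m_s, ps_agent.u_s, far_sr, ps_agent.tau_o,
                           ps_agent.xi)
            assert ps_loglik(far, simulated_participant) < base
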