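"""Perceptual filter and response model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from advicehgf import hgf
from advicehgf.hgf import AgentParams, TrajectoryRejection, filter_beliefs, response_probabilities

from reference_oracles import reference_binary_hgf

PRIOR_MEAN_PARAMS = AgentParams()  # Table-of-priors means, sigma*_0 = 1


class TestFilter:
    def test_flat_initial_belief_predicts_half(self):
        traj = filter_beliefs(AgentParams(mu2_0=0.0), [1, 0, 1])
        assert traj.muhat1[0] == pytest.approx(0.5, abs=1e-15)

    def test_two_trial_hand_oracle(self):
        """Frozen values from a step-by-step arithmetic evaluation of the
        update equations at the prior means, u = (1, 0)."""
        traj = filter_beliefs(PRIOR_MEAN_PARAMS, [1, 0], variant="standard")
        assert traj.mu2[0] == pytest.approx(0.46835139950396, abs=1e-10)
        assert traj.mu3[0] == pytest.approx(0.9962762104523802, abs=1e-10)
        assert traj.sigma2[0] == pytest.approx(0.93670279900792, abs=1e-10)
        assert traj.sigma3[0] == pytest.approx(1.4889354312846834, abs=1e-10)
        assert traj.mu2[1] == pytest.approx(-0.09110064614474767, abs=1e-10)
        assert traj.mu3[1] == pytest.approx(1.0014482318368727, abs=1e-10)
        assert traj.muhat1[1] == pytest.approx(0.6149934806130094, abs=1e-10)

    def test_mean_reverting_with_zero_drift_reduces_to_standard(self, rng):
        u = (rng.random(100) < 0.7).astype(int)
        p = AgentParams(phi3=0.0, m3=3.0)
        a = filter_beliefs(p, u, variant="standard")
        b = filter_beliefs(p, u, variant="mean_reverting")
        for name in ("muhat1", "muhat2", "muhat3", "mu2", "mu3", "sigma2", "sigma3", "delta1", "delta2"):
            np.testing.assert_allclose(getattr(a, name), getattr(b, name), atol=1e-10)

    def test_positive_prediction_error_raises_fidelity_belief(self, rng):
        u = (rng.random(50) < 0.6).astype(int)
        traj = filter_beliefs(PRIOR_MEAN_PARAMS, u)
        up = u == 1
        assert np.all(traj.mu2[up] > traj.muhat2[up])
        assert np.all(traj.mu2[~up] < traj.muhat2[~up])

    @pytest.mark.parametrize("variant", ["standard", "mean_reverting"])
    def test_matches_independent_reference_implementation(self, variant, rng):
        """Full trajectories agree with a separately written transcription
        of the published update equations on seeded parameter/input sets."""
        checked = 0
        for _ in range(30):
            if checked == 5:
                break
            p = AgentParams(
                kappa2=float(rng.uniform(0.2, 0.9)),
                omega2=float(rng.normal(-2, 1)),
                mu2_0=float(rng.normal(0, 1)),
                mu3_0=float(rng.normal(1, 0.5)),
                m3=float(rng.normal(1, 0.5)),
            )
            u = (rng.random(153) < rng.uniform(0.2, 0.8)).astype(int)
            try:
                traj = filter_beliefs(p, u, variant=variant)
            except TrajectoryRejection:
                continue  # ill-posed draw; both routes would reject it
            checked += 1
            ref = reference_binary_hgf(
                p.kappa2, p.omega2, p.theta, p.mu2_0, p.sigma2_0, p.mu3_0, p.sigma3_0,
                u, phi3=p.phi3, m3=p.m3, mean_reverting=(variant == "mean_reverting"),
            )
            for name, vals in ref.items():
                np.testing.assert_allclose(getattr(traj, name), vals, atol=1e-6, err_msg=name)
        assert checked == 5

    def test_rejection_reports_offending_trial(self):
        # strong coupling + high initial volatility destabilises level 3
        p = AgentParams(kappa2=1.0, omega2=2.0, mu3_0=6.0)
        u = [1, 0] * 50
        with pytest.raises(TrajectoryRejection) as err:
            filter_beliefs(p, u)
        assert 1 <= err.value.trial <= 100

    def test_higher_volatility_belief_speeds_level2_learning(self):
        """The effective level-2 learning rate 1/pi2 on the first trial
        grows with the initial volatility belief (all else fixed)."""
        updates = []
        for mu3_0 in np.linspace(-1.0, 3.0, 9):
            traj = filter_beliefs(AgentParams(mu3_0=mu3_0), [1])
            updates.append(abs(traj.mu2[0] - traj.muhat2[0]) / abs(traj.delta1[0]))
        assert np.all(np.diff(updates) > 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        kappa2=st.floats(0.05, 1.0),
        omega2=st.floats(-4.0, 0.5),
        mu2_0=st.floats(-2.0, 2.0),
        mu3_0=st.floats(-1.0, 2.5),
        seed=st.integers(0, 1000),
    )
    def test_accepted_trajectories_are_well_formed(self, kappa2, omega2, mu2_0, mu3_0, seed):
        u = (np.random.default_rng(seed).random(60) < 0.7).astype(int)
        p = AgentParams(kappa2=kappa2, omega2=omega2, mu2_0=mu2_0, mu3_0=mu3_0)
        try:
            traj = filter_beliefs(p, u, variant="mean_reverting")
        except TrajectoryRejection:
            return  # rejection is the sanctioned failure mode
        assert np.all(traj.sigma2 > 0) and np.all(traj.sigma3 > 0)
        assert np.all((traj.muhat1 > 0) & (traj.muhat1 < 1))
        np.testing.assert_allclose(traj.muhat1, 1 / (1 + np.exp(-traj.muhat2)), atol=1e-12)


class TestResponseModel:
    def test_indifferent_belief_gives_even_odds(self):
        for nu in (0.0, 2.0, 8.0):
            _, _, p = response_probabilities([0.5], [0.0], [0.5], zeta=0.5, nu=nu)
            assert p[0] == pytest.approx(0.5, abs=1e-12)

    def test_unit_inverse_temperature_is_identity(self):
        b, beta, p = response_probabilities([0.7], [0.0], [0.6], zeta=0.5, nu=0.0)
        assert beta[0] == pytest.approx(1.0)
        assert p[0] == pytest.approx(b[0], abs=1e-12)

    def test_inverse_temperature_at_prior_mean_nu(self):
        _, beta, _ = response_probabilities([0.5], [0.0], [0.5], zeta=0.5, nu=math.log(48))
        assert beta[0] == pytest.approx(48.0, rel=1e-12)

    def test_advice_weight_endpoints(self):
        b, _, _ = response_probabilities([0.8], [0.0], [0.3], zeta=1.0, nu=0.0)
        assert b[0] == pytest.approx(0.8)
        b, _, _ = response_probabilities([0.8], [0.0], [0.3], zeta=0.0, nu=0.0)
        assert b[0] == pytest.approx(0.3)

    def test_normalization_is_exact(self, rng):
        mu1 = rng.uniform(0.01, 0.99, 50)
        mu3 = rng.normal(1, 1, 50)
        c = rng.uniform(0.1, 0.9, 50)
        _, _, p = response_probabilities(mu1, mu3, c, zeta=0.4, nu=1.0)
        # p(not follow) computed by flipping the belief
        _, _, q = response_probabilities(1 - mu1, mu3, 1 - c, zeta=0.4, nu=1.0)
        np.testing.assert_allclose(p + q, 1.0, atol=1e-9)
        assert np.all((p > 0) & (p < 1))


class TestSimulationAndLikelihood:
    def test_same_seed_reproduces_choices(self, default_design):
        from advicehgf import task

        inputs = task.sample_advice_outcomes(default_design, 5)
        a = hgf.simulate_choices(PRIOR_MEAN_PARAMS, inputs.u, inputs.c, rng=9)
        b = hgf.simulate_choices(PRIOR_MEAN_PARAMS, inputs.u, inputs.c, rng=9)
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.win, b.win)

    def test_deterministic_limit_always_follows(self):
        # enormous inverse temperature and belief > 0.5 on every trial
        p = AgentParams(zeta=0.9, nu=60.0, mu2_0=3.0, omega2=-6.0, kappa2=0.05, mu3_0=-2.0)
        u = np.ones(40, dtype=int)
        c = np.full(40, 0.75)
        sess = hgf.simulate_choices(p, u, c, rng=1)
        assert np.all(sess.y == 1)

    def test_follow_rate_matches_probability(self):
        u = np.array([1, 1, 0])
        c = np.array([0.65, 0.55, 0.75])
        traj = filter_beliefs(PRIOR_MEAN_PARAMS, u)
        _, _, p = response_probabilities(traj.muhat1, traj.muhat3, c,
                                         PRIOR_MEAN_PARAMS.zeta, PRIOR_MEAN_PARAMS.nu)
        n = 10_000
        rng = np.random.default_rng(77)
        follows = np.zeros(3)
        for _ in range(n):
            follows += hgf.simulate_choices(PRIOR_MEAN_PARAMS, u, c, rng=rng).y
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(follows / n - p) < 3 * se + 1e-9)

    def test_even_odds_log_likelihood_closed_form(self):
        from advicehgf.task import SessionData

        n = 153
        u = (np.arange(n) % 2).astype(int)
        sess = SessionData(u=u, c=np.full(n, 0.5), phase=("volatile",) * n,
                           y=np.ones(n, dtype=int), win=u)
        p = AgentParams(zeta=1e-9)  # belief fully on the 0.5 cue
        ll = hgf.session_log_likelihood(p, sess)
        assert ll == pytest.approx(n * math.log(0.5), abs=1e-6)

    def test_generating_parameters_beat_perturbed_on_long_sessions(self, rng):
        from advicehgf import task

        design = task.make_task_design(
            n_trials=500, blocks=[(100, 0.9), (100, 0.2), (100, 0.8), (100, 0.2), (100, 0.8)], rng=0,
            probe_trials=[],
        )
        gen = AgentParams(zeta=0.7, nu=math.log(20))
        worse = AgentParams(zeta=0.15, nu=math.log(20), omega2=-5.0, mu2_0=-1.5)
        wins = 0
        for seed in range(20):
            inputs = task.sample_advice_outcomes(design, seed)
            sess = hgf.simulate_choices(gen, inputs.u, inputs.c, rng=seed + 1000)
            wins += hgf.session_log_likelihood(gen, sess) > hgf.session_log_likelihood(worse, sess)
        assert wins >= 18
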