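"""Task designs, advice sampling, cohorts and probe reports."""

import numpy as np
import pytest

from advicehgf import task
from advicehgf.hgf import AgentParams, filter_beliefs
from advicehgf.psychometrics import icc_a1
from advicehgf.task import CohortSpec, ConfigError, SessionData, TaskDesign


class TestMakeTaskDesign:
    def test_default_design_structure(self, default_design):
        d = default_design
        assert d.n_trials == 153
        assert d.probe_trials == (14, 49, 73, 99, 134)
        assert d.pre_task_probe
        assert d.stable_length == 35
        assert all(p == "stable" for p in d.phase[:35])
        assert d.phase[35] == "volatile"
        assert set(np.unique(d.cue_prob)) <= set(task.DEFAULT_CUE_SET)

    def test_single_block_degenerate_design(self):
        d = task.make_task_design(n_trials=10, blocks=[(10, 1.0)], probe_trials=[])
        assert np.all(d.fidelity == 1.0)
        assert all(p == "stable" for p in d.phase)

    def test_block_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            task.make_task_design(n_trials=153, blocks=[(35, 0.9), (100, 0.2)])

    def test_same_seed_reproduces_design(self):
        a = task.make_task_design(rng=4)
        b = task.make_task_design(rng=4)
        np.testing.assert_array_equal(a.cue_prob, b.cue_prob)

    def test_design_csv_round_trip(self, default_design, tmp_path):
        p = tmp_path / "design.csv"
        default_design.to_csv(p)
        back = TaskDesign.from_csv(p)
        np.testing.assert_allclose(back.fidelity, default_design.fidelity)
        np.testing.assert_allclose(back.cue_prob, default_design.cue_prob)
        assert back.phase == default_design.phase

    def test_invalid_phase_structures_rejected(self):
        with pytest.raises(ConfigError):
            TaskDesign(fidelity=[0.9, 0.9], cue_prob=[0.6, 0.6],
                       phase=("volatile", "stable"), probe_trials=())
        with pytest.raises(ConfigError):
            TaskDesign(fidelity=[0.9], cue_prob=[0.6], phase=("stable",),
                       probe_trials=(3,))


class TestSampleAdviceOutcomes:
    def test_perfect_fidelity_means_all_accurate(self):
        d = task.make_task_design(n_trials=20, blocks=[(20, 1.0)], probe_trials=[])
        s = task.sample_advice_outcomes(d, 0)
        assert np.all(s.u == 1)

    def test_advice_accuracy_rate_matches_fidelity(self):
        d = task.make_task_design(n_trials=10_000, blocks=[(10_000, 0.8)], probe_trials=[])
        s = task.sample_advice_outcomes(d, 0)
        se = np.sqrt(0.8 * 0.2 / 10_000)
        assert abs(s.u.mean() - 0.8) < 3 * se

    def test_same_seed_reproduces_inputs(self, default_design):
        a = task.sample_advice_outcomes(default_design, 7)
        b = task.sample_advice_outcomes(default_design, 7)
        np.testing.assert_array_equal(a.u, b.u)
        np.testing.assert_allclose(a.c, b.c)

    def test_advised_cue_prob_reflects_cue_set(self, default_design):
        s = task.sample_advice_outcomes(default_design, 3)
        cue = default_design.cue_prob
        assert np.all((s.c == cue) | (np.isclose(s.c, 1 - cue)))

    def test_session_csv_round_trip(self, played_session, tmp_path):
        p = tmp_path / "session.csv"
        played_session.to_csv(p)
        back = SessionData.from_csv(p)
        np.testing.assert_array_equal(back.u, played_session.u)
        np.testing.assert_allclose(back.c, played_session.c)
        np.testing.assert_array_equal(back.y, played_session.y)
        np.testing.assert_array_equal(back.win, played_session.win)


class TestRetestCohort:
    def test_zero_perturbation_keeps_parameters(self, short_design):
        spec = CohortSpec(n_subjects=5, seed=1)
        cohort = task.generate_retest_cohort(spec, short_design)
        assert len(cohort) == 5
        for entry in cohort:
            assert entry["params1"] == entry["params2"]
            assert entry["session1"].n_trials == short_design.n_trials

    def test_deterministic_practice_shift(self, short_design):
        dist = {"kappa2": (0.5, 0.0), "omega2": (-2.0, 0.5), "mu2_0": (0.0, 0.5),
                "mu3_0": (1.0, 0.2), "m3": (1.0, 0.2), "zeta": (0.5, 0.05),
                "nu": (3.0, 0.3)}
        spec = CohortSpec(n_subjects=12, seed=2, param_distribution=dist,
                          practice_shift={"zeta": 0.1})
        cohort = task.generate_retest_cohort(spec, short_design)
        deltas = [e["params2"]["zeta"] - e["params1"]["zeta"] for e in cohort]
        assert np.allclose(deltas, 0.1)

    def test_same_seed_reproduces_cohort(self, short_design):
        spec = CohortSpec(n_subjects=3, seed=9)
        a = task.generate_retest_cohort(spec, short_design)
        b = task.generate_retest_cohort(spec, short_design)
        for ea, eb in zip(a, b):
            assert ea["params1"] == eb["params1"]
            np.testing.assert_array_equal(ea["session2"].y, eb["session2"].y)

    def test_within_subject_sd_dials_generating_icc(self, short_design):
        """With between- and within-subject sd equal, the generating-value
        ICC of omega2 should sit near 0.5 (bivariate-normal closed form)."""
        dist = {"omega2": (-2.0, 2.0), "zeta": (0.5, 0.05), "nu": (3.0, 0.3),
                "kappa2": (0.5, 0.05), "mu2_0": (0.0, 0.3), "mu3_0": (1.0, 0.2),
                "m3": (1.0, 0.2)}
        iccs = []
        for seed in range(20):
            spec = CohortSpec(n_subjects=39, seed=seed, param_distribution=dist,
                              within_subject_sd={"omega2": 2.0})
            cohort = task.generate_retest_cohort(spec, short_design)
            g1 = [e["params1"]["omega2"] for e in cohort]
            g2 = [e["params2"]["omega2"] for e in cohort]
            iccs.append(icc_a1(g1, g2).icc)
        assert abs(np.mean(iccs) - 0.5) < 0.15

    def test_generating_icc_decreases_with_within_subject_sd(self, short_design):
        dist = {"omega2": (-2.0, 2.0), "zeta": (0.5, 0.05), "nu": (3.0, 0.3),
                "kappa2": (0.5, 0.05), "mu2_0": (0.0, 0.3), "mu3_0": (1.0, 0.2),
                "m3": (1.0, 0.2)}
        means = []
        for sd in (0.5, 2.0, 6.0):
            iccs = []
            for seed in range(10):
                spec = CohortSpec(n_subjects=39, seed=seed, param_distribution=dist,
                                  within_subject_sd={"omega2": sd})
                cohort = task.generate_retest_cohort(spec, short_design)
                iccs.append(icc_a1([e["params1"]["omega2"] for e in cohort],
                                   [e["params2"]["omega2"] for e in cohort]).icc)
            means.append(np.mean(iccs))
        assert means[0] > means[1] > means[2]

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigError):
            CohortSpec(n_subjects=5, within_subject_sd={"zeta": -0.1})

    def test_cohort_spec_json_round_trip(self, tmp_path):
        spec = CohortSpec(n_subjects=7, seed=3, practice_shift={"zeta": 0.05},
                          param_distribution={"omega2": (-2.0, 1.0)})
        p = tmp_path / "spec.json"
        spec.to_json(p)
        assert CohortSpec.from_json(p) == spec


class TestProbeResponses:
    def test_dead_zone_reports_random(self, short_design):
        traj = _traj_with_muhat2(np.zeros(short_design.n_trials))
        resp = task.generate_probe_responses(traj, short_design, tau=0.5)
        assert all(r.category == "random" for r in resp)

    def test_threshold_mapping(self, short_design):
        m = np.zeros(short_design.n_trials)
        m[4] = 2.0   # probe trial 5
        m[14] = -2.0  # probe trial 15
        resp = {r.trial: r.category for r in task.generate_probe_responses(_traj_with_muhat2(m), short_design, tau=0.5)}
        assert resp[5] == "helpful"
        assert resp[15] == "misleading"
        assert resp[1] == "random"  # pre-task probe

    def test_probe_beyond_trajectory_rejected(self, short_design):
        traj = _traj_with_muhat2(np.zeros(10))
        with pytest.raises(IndexError):
            task.generate_probe_responses(traj, short_design)

    def test_trusting_agents_report_helpful_in_stable_phase(self, default_design):
        """Agents with strong advice reliance mostly report the adviser
        helpful at the early (stable-phase) probes."""
        agent = AgentParams(zeta=0.9)
        helpful = total = 0
        for seed in range(20):
            inputs = task.sample_advice_outcomes(default_design, seed)
            traj = filter_beliefs(agent, inputs.u, variant="mean_reverting")
            for r in task.generate_probe_responses(traj, default_design):
                if r.trial > 1 and default_design.phase[r.trial - 1] == "stable":
                    total += 1
                    helpful += r.category == "helpful"
        assert total and helpful / total > 0.5


def _traj_with_muhat2(values):
    class _T:
        muhat2 = np.asarray(values, dtype=float)

    return _T()
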