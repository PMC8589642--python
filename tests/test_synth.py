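"""Generator contracts: Markov dwell structure, observation model, couplings."""

import numpy as np
import pytest

from statedyn import metrics, synth
from statedyn.hmm import stationary_distribution


class TestStateSequence:
    def test_single_state_is_constant(self):
        seq = synth.simulate_state_sequence([[1.0]], [1.0], 50, seed=0)
        assert np.all(seq == 0)

    def test_absorbing_chain_stays_put(self):
        seq = synth.simulate_state_sequence(np.eye(3), [0, 1, 0], 80, seed=1)
        assert np.all(seq == 1)

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_state_sequence([[0.5, 0.2], [0.1, 0.9]],
                                          [0.5, 0.5], 10, seed=0)

    def test_occupancy_and_dwell_match_chain_theory(self):
        # symmetric sticky chain: occupancy 1/2, mean dwell 1/(1-0.9) = 10
        pi = [[0.9, 0.1], [0.1, 0.9]]
        seq = synth.simulate_state_sequence(pi, [0.5, 0.5], 100_000, seed=3)
        occ = metrics.occupancy_rate(seq, n_states=2)
        assert np.all(np.abs(occ - 0.5) < 0.01)
        life = metrics.mean_lifetime(seq, n_states=2)["lifetime_trs"]
        assert np.all(np.abs(life - 10.0) < 0.5)

    def test_reproducible_under_seed(self):
        pi = synth.default_transition_matrix(4)
        a = synth.simulate_state_sequence(pi, np.full(4, 0.25), 500, seed=9)
        b = synth.simulate_state_sequence(pi, np.full(4, 0.25), 500, seed=9)
        assert np.array_equal(a, b)


class TestROITimeseries:
    def test_zero_loading_gives_pure_observation_noise(self):
        r_var = np.full(11, 0.7)
        cfg = synth.SimulationConfig(n_subjects=1, loading=np.zeros((11, 3)),
                                     obs_noise=r_var, seed=0)
        seq = np.zeros(50_000, dtype=int)
        y, _ = synth.simulate_roi_timeseries(cfg, seq, seed=4)
        emp = y.var(axis=0)
        assert np.all(np.abs(emp - r_var) / r_var < 0.05)

    def test_white_latent_state_has_closed_form_covariance(self):
        # A = 0, Q = I: observed covariance is C C' + R_obs exactly
        rng = np.random.default_rng(0)
        c = rng.standard_normal((6, 2))
        a = np.zeros((1, 2, 2))
        q = np.eye(2)[None]
        cfg = synth.SimulationConfig(n_subjects=1, n_rois=6, n_states=1,
                                     latent_dim=2, transition_matrix=[[1.0]],
                                     state_dynamics=(a, q), loading=c,
                                     obs_noise=np.full(6, 0.5), seed=0)
        seq = np.zeros(50_000, dtype=int)
        y, _ = synth.simulate_roi_timeseries(cfg, seq, seed=5)
        target = c @ c.T + 0.5 * np.eye(6)
        emp = np.cov(y.T)
        assert np.all(np.abs(np.diag(emp) - np.diag(target))
                      / np.diag(target) < 0.05)

    def test_distinct_white_states_match_model_implied_covariance(self):
        # two A=0 states with different Q: within-state covariance equals the
        # model-implied covariance, and the two matrices clearly differ
        a = np.zeros((2, 2, 2))
        q = np.stack([np.diag([2.0, 0.2]), np.diag([0.2, 2.0])])
        c = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        cfg = synth.SimulationConfig(
            n_subjects=1, n_rois=3, n_states=2, latent_dim=2,
            transition_matrix=[[0.99, 0.01], [0.01, 0.99]],
            state_dynamics=(a, q), loading=c, obs_noise=np.full(3, 0.1),
            seed=0)
        seq = synth.simulate_state_sequence(cfg.transition_matrix, [0.5, 0.5],
                                            30_000, seed=6)
        y, _ = synth.simulate_roi_timeseries(cfg, seq, seed=6)
        implied = [cfg.state_observed_cov(k) for k in range(2)]
        assert np.linalg.norm(implied[0] - implied[1]) > 0.5
        for k in range(2):
            sel = seq == k
            assert sel.sum() > 5000
            emp = np.cov(y[sel].T)
            rel = (np.linalg.norm(emp - implied[k])
                   / np.linalg.norm(implied[k]))
            assert rel < 0.1

    def test_unstable_dynamics_rejected(self):
        a = np.eye(2)[None] * 1.01
        q = np.eye(2)[None]
        with pytest.raises(ValueError, match="unstable"):
            synth.SimulationConfig(n_subjects=1, n_rois=3, n_states=1,
                                   latent_dim=2, transition_matrix=[[1.0]],
                                   state_dynamics=(a, q),
                                   loading=np.ones((3, 2)))

    def test_snr_sets_signal_to_noise_trace_ratio(self):
        cfg = synth.easy_preset(n_subjects=1)
        p = stationary_distribution(cfg.transition_matrix)
        c = cfg.loading
        sig = sum(p[k] * np.trace(c @ cfg.stationary_latent_cov(k) @ c.T)
                  for k in range(cfg.n_states))
        noise = cfg.obs_noise_variances().sum()
        assert sig / noise == pytest.approx(1.0, rel=1e-10)


class TestMotionRegressors:
    def test_shape_and_standardization(self):
        m = synth.simulate_motion_regressors(300, seed=2)
        assert m.shape == (300, 6)
        assert np.all(np.abs(m.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(m.std(axis=0) - 1.0) < 1e-9)

    def test_random_walk_is_smooth(self):
        m = synth.simulate_motion_regressors(700, seed=3)
        for j in range(6):
            r = np.corrcoef(m[:-1, j], m[1:, j])[0, 1]
            assert r > 0.9


class TestBehaviorCoupling:
    @staticmethod
    def _occupancies(n, seed):
        rng = np.random.default_rng(seed)
        return rng.dirichlet(np.full(4, 8.0), size=n)

    def test_null_coupling_gives_zero_correlation(self):
        occ = self._occupancies(500, 1)
        cfg = synth.SimulationConfig(
            n_subjects=500, coupling=[synth.Coupling(0, "v", noise_sd=0.55,
                                                     slope=0.0)], seed=0)
        params, _ = synth.simulate_behavior(cfg, occ, seed=11,
                                            simulate_trials=False)
        r = np.corrcoef(occ[:, 0], params["v"])[0, 1]
        assert abs(r) < 0.09

    def test_target_correlation_is_induced(self):
        occ = self._occupancies(500, 2)
        cfg = synth.SimulationConfig(
            n_subjects=500,
            coupling=[synth.Coupling(0, "v", noise_sd=0.55, target_r=0.5)],
            seed=0)
        params, _ = synth.simulate_behavior(cfg, occ, seed=12,
                                            simulate_trials=False)
        r = np.corrcoef(occ[:, 0], params["v"])[0, 1]
        assert abs(r - 0.5) < 0.08

    def test_invalid_occupancy_rejected(self):
        cfg = synth.SimulationConfig(n_subjects=2)
        with pytest.raises(ValueError):
            synth.simulate_behavior(cfg,
                                    np.array([[0.5, 0.6, 0.0, 0.0],
                                              [0.25, 0.25, 0.25, 0.25]]),
                                    seed=0)

    def test_symmetric_diffusion_choice_proportion(self):
        from statedyn import behavior as bh
        _, correct = bh.simulate_ddm_trials(1.5, 0.0, 0.2, n_trials=10_000,
                                            seed=5)
        assert abs(correct.mean() - 0.5) < 0.02


class TestCohort:
    def test_bit_reproducible(self):
        cfg = synth.SimulationConfig(n_subjects=3, n_timepoints=120,
                                     n_trials=24, seed=42)
        a = synth.generate_cohort(cfg)
        b = synth.generate_cohort(cfg)
        for i in range(3):
            assert np.array_equal(a.timeseries[i], b.timeseries[i])
            assert np.array_equal(a.motion[i], b.motion[i])
        assert a.participants.equals(b.participants)
        for s in a.subjects:
            assert a.trials[s].equals(b.trials[s])

    def test_ground_truth_occupancy_sums_to_one(self, tiny_cohort):
        occ = tiny_cohort.ground_truth["occupancy"]
        assert np.allclose(occ.sum(axis=1), 1.0)

    def test_adhd_group_prefers_nonoptimal_state(self):
        pi = synth.default_transition_matrix(4)
        pi_adhd = synth.adhd_transition_matrix(pi)
        p_td = stationary_distribution(pi)
        p_ad = stationary_distribution(pi_adhd)
        assert p_ad[0] < p_td[0]       # less task-optimal state
        assert p_ad[1] > p_td[1]       # more non-optimal state
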