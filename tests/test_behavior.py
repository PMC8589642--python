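"""ex-Gaussian and drift-diffusion models against analytic oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from statedyn import behavior as bh


class TestExGaussianDensity:
    def test_matches_scipy_exponnorm(self):
        x = np.linspace(-0.3, 2.0, 60)
        mu, sigma, tau = 0.4, 0.05, 0.1
        ref = stats.exponnorm.logpdf(x, K=tau / sigma, loc=mu, scale=sigma)
        assert np.abs(bh.exgauss_logpdf(x, mu, sigma, tau) - ref).max() < 1e-10

    def test_gaussian_limit_as_tau_vanishes(self):
        mu, sigma = 0.4, 0.05
        x = 0.42
        d = abs(bh.exgauss_logpdf(x, mu, sigma, 1e-6 * sigma)
                - stats.norm.logpdf(x, mu, sigma))
        assert d < 1e-5

    def test_density_integrates_to_one(self):
        mu, sigma, tau = 0.4, 0.05, 0.1
        total = integrate.quad(
            lambda x: np.exp(bh.exgauss_logpdf(x, mu, sigma, tau)),
            -np.inf, np.inf)[0]
        assert abs(total - 1.0) < 1e-8

    def test_mode_lies_between_mu_and_mu_plus_tau(self):
        mu, sigma, tau = 0.4, 0.05, 0.1
        x = np.linspace(mu - 0.2, mu + 0.5, 4000)
        xm = x[np.argmax(bh.exgauss_logpdf(x, mu, sigma, tau))]
        assert mu < xm < mu + tau

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            bh.exgauss_logpdf(0.5, 0.4, -0.1, 0.1)


class TestExGaussianFit:
    def test_large_sample_recovery(self):
        rng = np.random.default_rng(4)
        mu, sigma, tau = 0.35, 0.05, 0.12
        rts = rng.normal(mu, sigma, 5000) + rng.exponential(tau, 5000)
        fit = bh.fit_exgauss(rts)
        assert abs(fit.mu - mu) / mu < 0.05
        assert abs(fit.sigma - sigma) / sigma < 0.05
        assert abs(fit.tau - tau) / tau < 0.05

    def test_implied_mean_matches_sample_mean(self):
        rng = np.random.default_rng(5)
        rts = rng.normal(0.35, 0.05, 2000) + rng.exponential(0.12, 2000)
        fit = bh.fit_exgauss(rts)
        se = rts.std(ddof=1) / np.sqrt(rts.size)
        assert abs(fit.implied_mean - rts.mean()) < 2 * se
        assert fit.implied_var == pytest.approx(fit.sigma**2 + fit.tau**2)

    def test_task_sized_tau_recovery(self):
        # n = 96 trials: median absolute tau error < 0.03 s at truth 0.1
        errs = []
        for s in range(200):
            rng = np.random.default_rng(1000 + s)
            rts = rng.normal(0.35, 0.05, 96) + rng.exponential(0.1, 96)
            errs.append(abs(bh.fit_exgauss(rts).tau - 0.1))
        assert np.median(errs) < 0.03

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            bh.fit_exgauss(np.full(10, 0.4))


class TestWienerDensity:
    def test_zero_drift_splits_mass_equally(self):
        for bdy in ("upper", "lower"):
            mass = integrate.quad(
                lambda t: bh.wfpt_density(t, 1.5, 0.0, boundary=bdy),
                0, 100, limit=200)[0]
            assert abs(mass - 0.5) < 1e-6

    def test_total_mass_is_one(self):
        total = sum(integrate.quad(
            lambda t, b=b: bh.wfpt_density(t, 1.5, 1.0, boundary=b),
            0, 60, limit=200)[0] for b in ("upper", "lower"))
        assert abs(total - 1.0) < 1e-6

    def test_boundary_mass_matches_closed_form(self):
        a, v = 1.2, 0.8
        up = integrate.quad(lambda t: bh.wfpt_density(t, a, v, "upper"),
                            0, 80, limit=200)[0]
        assert abs(up - bh.wfpt_boundary_prob(a, v, "upper")) < 1e-6

    def test_mean_decision_time_closed_form_and_simulator(self):
        a, v = 1.5, 1.0
        m1, _, _ = bh.ddm_decision_moments(a, v)
        assert m1 == pytest.approx((a / (2 * v)) * np.tanh(a * v / 2))
        rt, _ = bh.simulate_ddm_trials(a, v, 0.0, n_trials=100_000, seed=9)
        se = np.nanstd(rt) / np.sqrt(np.isfinite(rt).sum())
        # Euler-Maruyama with bridge correction: small O(dt) bias remains
        assert abs(np.nanmean(rt) - m1) < 3 * se + 2e-3

    def test_invalid_boundary_separation_rejected(self):
        with pytest.raises(ValueError):
            bh.wfpt_density(0.5, -1.0, 1.0)

    def test_nonpositive_times_have_zero_density(self):
        d = bh.wfpt_density(np.array([-0.1, 0.0, 0.3]), 1.5, 1.0, "upper")
        assert d[0] == 0.0 and d[1] == 0.0 and d[2] > 0.0


class TestDDMFit:
    def test_large_sample_recovery(self):
        a, v, t0 = 1.4, 2.5, 0.25
        rt, corr = bh.simulate_ddm_trials(a, v, t0, n_trials=5000, seed=3)
        fit = bh.fit_ddm(pd.DataFrame({"rt_s": rt, "correct": corr}))
        assert abs(fit.a - a) / a < 0.05
        assert abs(fit.v - v) / v < 0.05
        assert abs(fit.t - t0) / t0 < 0.05

    def test_agrees_with_ez_diffusion_at_large_n(self):
        a, v, t0 = 1.4, 2.0, 0.25
        rt, corr = bh.simulate_ddm_trials(a, v, t0, n_trials=5000, seed=6)
        df = pd.DataFrame({"rt_s": rt, "correct": corr})
        fit = bh.fit_ddm(df)
        acc = corr.mean()
        ez_a, ez_v, ez_t, _ = bh.ez_diffusion(acc, np.nanmean(rt),
                                              np.nanvar(rt, ddof=1),
                                              n_trials=5000)
        assert abs(fit.a - ez_a) / ez_a < 0.10
        assert abs(fit.v - ez_v) / ez_v < 0.10

    def test_likelihood_at_mle_beats_truth(self):
        a, v, t0 = 1.4, 2.5, 0.25
        rt, corr = bh.simulate_ddm_trials(a, v, t0, n_trials=2000, seed=8)
        df = pd.DataFrame({"rt_s": rt, "correct": corr})
        fit = bh.fit_ddm(df)
        keep = np.isfinite(rt) & (rt >= bh.RT_CONTAMINANT_FLOOR)
        nll_true = bh._ddm_nll([a, v, t0], rt[keep & (corr == 1)],
                               rt[keep & (corr == 0)])
        assert fit.loglik >= -nll_true - 1e-6

    def test_all_correct_subject_flagged(self):
        rng = np.random.default_rng(2)
        rt = 0.3 + rng.exponential(0.1, 60)
        fit = bh.fit_ddm(pd.DataFrame({"rt_s": rt, "correct": np.ones(60,
                                                                     int)}))
        assert "all_correct_v_weakly_identified" in fit.flags

    def test_shrinkage_pulls_toward_cohort_mean(self):
        rng = np.random.default_rng(11)
        trials = {}
        for i, v in enumerate([1.2, 2.4, 3.6]):
            rt, corr = bh.simulate_ddm_trials(1.4, v, 0.25, n_trials=96,
                                              seed=100 + i)
            keep = np.isfinite(rt)
            trials[f"s{i}"] = pd.DataFrame({"rt_s": rt[keep],
                                            "correct": corr[keep]})
        plain = bh.fit_ddm_cohort(trials, hierarchical="off")
        shrunk = bh.fit_ddm_cohort(trials, hierarchical="shrinkage")
        v_plain = np.array([f.v for f in plain.values()])
        v_shrunk = np.array([f.v for f in shrunk.values()])
        assert v_shrunk.std() <= v_plain.std() + 1e-9
        _ = rng


class TestEZDiffusion:
    def test_round_trip_from_analytic_moments(self):
        a, v, t0 = 1.4, 2.5, 0.25
        m1, var, _ = bh.ddm_decision_moments(a, v)
        acc = float(bh.ddm_accuracy(a, v))
        ez_a, ez_v, ez_t, flags = bh.ez_diffusion(acc, m1 + t0, var)
        assert abs(ez_a - a) < 1e-8
        assert abs(ez_v - v) < 1e-8
        assert abs(ez_t - t0) < 1e-8
        assert flags == []

    def test_perfect_accuracy_edge_corrected(self):
        a, v, t0, flags = bh.ez_diffusion(1.0, 0.45, 0.02, n_trials=96)
        assert "accuracy_edge_corrected" in flags
        assert a > 0 and v > 0

    def test_chance_accuracy_edge_corrected(self):
        a, v, t0, flags = bh.ez_diffusion(0.5, 0.45, 0.02, n_trials=96)
        assert "accuracy_at_chance_corrected" in flags

    def test_drift_sign_follows_accuracy(self):
        _, v_hi, _, _ = bh.ez_diffusion(0.8, 0.5, 0.02, n_trials=96)
        _, v_lo, _, _ = bh.ez_diffusion(0.2, 0.5, 0.02, n_trials=96)
        assert v_hi > 0 > v_lo


class TestSummaries:
    def test_hand_computed_example(self):
        df = pd.DataFrame({"rt_s": [0.4, 0.6], "correct": [1, 1]})
        s = bh.rt_summaries(df)
        assert s["accuracy"] == 1.0
        assert s["rt_mean"] == pytest.approx(0.5)
        assert s["rt_std"] == pytest.approx(np.std([0.4, 0.6], ddof=1))

    def test_omissions_count_as_errors(self):
        df = pd.DataFrame({"rt_s": [0.4, np.nan, 0.5, 0.45],
                           "correct": [1, 0, 1, 0]})
        s = bh.rt_summaries(df)
        assert s["accuracy"] == 0.5
        assert s["n_omissions"] == 1

    def test_cohort_outlier_rule(self, rng):
        table = pd.DataFrame({
            "accuracy": np.clip(rng.normal(0.95, 0.02, 40), 0, 1),
            "rt_mean": rng.normal(0.48, 0.03, 40)})
        table.loc[0, "accuracy"] = 0.5    # gross outlier
        flags = bh.flag_outliers(table, z=2.5)
        assert flags.iloc[0]
        assert flags.sum() <= 4

    def test_tau_and_drift_negatively_coupled_in_cohort(self):
        # moment-matched ex-Gaussian truth: higher drift -> thinner tail
        from statedyn import synth
        rng = np.random.default_rng(3)
        occ = rng.dirichlet(np.full(4, 8.0), size=200)
        cfg = synth.SimulationConfig(n_subjects=200, seed=0)
        params, _ = synth.simulate_behavior(cfg, occ, seed=21,
                                            simulate_trials=False)
        r = np.corrcoef(params["tau"], params["v"])[0, 1]
        assert r < 0

    def test_millisecond_column_converted_on_read(self, tmp_path):
        from statedyn import io as sio
        df = pd.DataFrame({"trial": [1, 2], "rt_ms": [450.0, 520.0],
                           "correct": [1, 1]})
        df.to_csv(tmp_path / "sub-x_trials.csv", index=False)
        back = sio.read_trials(tmp_path, "x")
        assert np.allclose(back["rt_s"], [0.45, 0.52])
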