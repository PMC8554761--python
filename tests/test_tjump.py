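"""First-passage extraction, survival fits, two-state algebra, trace fits."""

import numpy as np
import pytest
import scipy.stats
from scipy.integrate import solve_ivp

from duplexkin import build_preset, simulate_relaxation
from duplexkin import constants as C
from duplexkin import tjump
from duplexkin.duplex_synth import RelaxationEnsemble, Trajectory


def held_h_trajectory(preset, n_frames, dt=1.0):
    idx = preset.state_index("H")
    frames = np.repeat(preset.templates[idx][None], n_frames, axis=0)
    labels = np.array(["H"] * n_frames, dtype=object)
    return Trajectory(frames=frames.astype(np.float32), dt_save=dt,
                      seed=0, truth_labels=labels)


class TestExtractFirstPassage:
    def test_held_trajectory_censored(self, gc_mix):
        traj = held_h_trajectory(gc_mix, 500)
        ens = RelaxationEnsemble([traj], 0.0, t_max=500.0)
        fps = tjump.extract_first_passage(ens, "dissociation")
        assert fps.n_censored == 1
        assert len(fps.event_times) == 0

    def test_constructed_crossing_at_frame_137(self, gc_mix):
        traj = held_h_trajectory(gc_mix, 500, dt=0.5)
        d_idx = gc_mix.state_index("D")
        traj.frames[137:] = gc_mix.templates[d_idx]
        ens = RelaxationEnsemble([traj], 0.0, t_max=250.0)
        fps = tjump.extract_first_passage(ens, "dissociation")
        assert len(fps.event_times) == 1
        assert fps.event_times[0] == pytest.approx(137 * 0.5)

    def test_not_starting_hybridized_rejected(self, gc_mix):
        d_idx = gc_mix.state_index("D")
        frames = np.repeat(gc_mix.templates[d_idx][None], 10, axis=0)
        traj = Trajectory(frames=frames.astype(np.float32), dt_save=1.0,
                          seed=0, truth_labels=None)
        ens = RelaxationEnsemble([traj], 0.0, t_max=10.0)
        with pytest.raises(ValueError, match="hybridized"):
            tjump.extract_first_passage(ens, "dissociation")

    def test_event_times_exponential(self, gc_mix):
        """Oracle: the generating chain's exit rate under the u = 1 bias."""
        u = 1.0
        hot = gc_mix.with_temperature(u)
        rate = hot.rate_matrix[hot.state_index("H"), hot.state_index("D")]
        ens = simulate_relaxation(
            gc_mix, u, 1000, 12_000.0, seed=31, dt_save=2.0
        )
        fps = tjump.extract_first_passage(ens, "dissociation")
        assert fps.n_censored < 10
        stat = scipy.stats.kstest(
            fps.event_times, "expon", args=(0.0, 1.0 / rate)
        )
        assert stat.pvalue > 0.01


class TestFitSurvivalRate:
    def test_recovers_known_rate(self):
        """Sampling oracle: exponential times at k = 1e-3 / ns (1 us^-1)."""
        rng = np.random.default_rng(0)
        times = rng.exponential(1000.0, size=10_000)
        fps = tjump.FirstPassageSet(times, 0, t_max=times.max() + 1,
                                    event_kind="dissociation")
        k, (lo, hi) = tjump.fit_survival_rate(fps, seed=1)
        assert abs(k - 1e-3) / 1e-3 < 0.05
        assert lo <= k <= hi

    def test_rescaling_halves_rate(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(500.0, size=2000)
        f1 = tjump.FirstPassageSet(times, 0, times.max() + 1, "dissociation")
        f2 = tjump.FirstPassageSet(2 * times, 0, 2 * times.max() + 1,
                                    "dissociation")
        k1, _ = tjump.fit_survival_rate(f1, n_boot=0)
        k2, _ = tjump.fit_survival_rate(f2, n_boot=0)
        assert k2 == pytest.approx(0.5 * k1, rel=1e-6)

    def test_heavy_censoring(self):
        """90% administrative censoring, truth recovered within 15%."""
        rng = np.random.default_rng(3)
        k_true = 1e-3
        all_times = rng.exponential(1.0 / k_true, size=10_000)
        t_max = np.quantile(all_times, 0.1)
        events = all_times[all_times <= t_max]
        n_censored = int((all_times > t_max).sum())
        fps = tjump.FirstPassageSet(events, n_censored, t_max, "dissociation")
        k, _ = tjump.fit_survival_rate(fps, n_boot=0)
        assert abs(k - k_true) / k_true < 0.15

    def test_all_censored_rejected(self):
        fps = tjump.FirstPassageSet(np.array([]), 10, 100.0, "dissociation")
        with pytest.raises(ValueError, match="no uncensored"):
            tjump.fit_survival_rate(fps)


class TestTwoStateRates:
    def test_theta_to_one_limit(self):
        out = tjump.two_state_rates(
            tjump.TwoStateInputs(theta=1.0, c_tot=2.0, lambda_slow=1e5)
        )
        assert out["K_d"] == 0.0
        out = tjump.two_state_rates(
            tjump.TwoStateInputs(theta=0.999999, c_tot=2.0, lambda_slow=1e5)
        )
        assert out["K_d"] < 1e-10

    def test_s_to_zero_limit(self):
        out = tjump.rates_from_kd(K_d=1.0, S_Tf=0.0, lambda_slow=1e5)
        assert out["k_d_slow"] == pytest.approx(1e5)

    def test_theta_zero_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|K_d"):
            tjump.two_state_rates(
                tjump.TwoStateInputs(theta=0.0, c_tot=2.0, lambda_slow=1e5)
            )

    def test_mass_action_oracle(self):
        """Independent ODE oracle: 2S <-> D with the returned rates must
        equilibrate at theta = 0.5 and relax at lambda_slow within 0.1%."""
        c_tot, lam = 2.0, 1e5  # mM, 1/s
        out = tjump.two_state_rates(
            tjump.TwoStateInputs(theta=0.5, c_tot=c_tot, lambda_slow=lam)
        )
        k_d, k_a = out["k_d_slow"], out["k_a_slow"]

        def rhs(t, y):
            D = y[0]
            S = c_tot - 2.0 * D
            return [k_a * S * S - k_d * D]

        # equilibrium duplex fraction
        d_eq = 0.25 * c_tot  # theta = 2 D / c = 0.5
        assert rhs(0, [d_eq])[0] == pytest.approx(0.0, abs=1e-8)
        # linearized relaxation rate from a 0.05% perturbation
        d0 = d_eq * 1.0005
        t_span = (0.0, 3.0 / lam)
        sol = solve_ivp(rhs, t_span, [d0], rtol=1e-12, atol=1e-14,
                        dense_output=True)
        ts = np.linspace(0.2 / lam, 2.0 / lam, 50)
        dev = np.abs(sol.sol(ts)[0] - d_eq)
        slope, _ = np.polyfit(ts, np.log(dev), 1)
        assert abs(-slope - lam) / lam < 1e-3

    def test_round_trip_lambda(self):
        """Invariant: lambda = k_d + 4 k_a [S] reproduced to 1e-10."""
        for theta in (0.2, 0.5, 0.8):
            inp = tjump.TwoStateInputs(theta=theta, c_tot=2.0, lambda_slow=3e4)
            out = tjump.two_state_rates(inp)
            lam = out["k_d_slow"] + 4.0 * out["k_a_slow"] * out["S_Tf"]
            assert abs(lam - inp.lambda_slow) / inp.lambda_slow < 1e-10

    def test_kd_consistency(self):
        out = tjump.two_state_rates(
            tjump.TwoStateInputs(theta=0.5, c_tot=2.0, lambda_slow=1e5)
        )
        assert out["K_d"] == pytest.approx(2.0)
        assert out["S_Tf"] == pytest.approx(1.0)
        assert out["k_d_slow"] / out["k_a_slow"] == pytest.approx(out["K_d"])


def make_trace(t, A, B, Cc, tf, ts, tc, beta):
    return (A * np.exp(-((t / tf) ** beta))
            + B * np.exp(-t / ts) + Cc * np.exp(-t / tc))


class TestFitTjumpTrace:
    def test_beta_one_reduces_to_exponential(self):
        t = np.logspace(0, 7, 150)
        y = make_trace(t, 1.0, 0.5, 0.3, 100.0, 2e4, 5e6, 1.0)
        fit = tjump.fit_tjump_trace(t, y, seed=1)
        assert fit.beta_fast >= 0.95

    def test_noiseless_parameter_recovery(self):
        """Self-consistency: (beta, tau) recovered within 1% on clean data."""
        t = np.logspace(0, 7.2, 250)
        truth = dict(A=1.0, B=0.6, Cc=0.4, tf=100.0, ts=2e4, tc=5e6,
                     beta=0.3)
        y = make_trace(t, **truth)
        fit = tjump.fit_tjump_trace(t, y, seed=2, n_starts=15)
        assert fit.beta_fast == pytest.approx(0.3, rel=0.01)
        assert fit.tau_fast == pytest.approx(100.0, rel=0.01)
        assert fit.tau_slow == pytest.approx(2e4, rel=0.01)
        assert fit.tau_cool == pytest.approx(5e6, rel=0.01)
        assert fit.A == pytest.approx(1.0, rel=0.01)

    def test_time_constants_ordered(self):
        t = np.logspace(0, 6, 120)
        y = make_trace(t, 1.0, -0.5, 0.2, 50.0, 5e3, 5e5, 0.6)
        fit = tjump.fit_tjump_trace(t, y, seed=3)
        assert 0 < fit.tau_fast < fit.tau_slow < fit.tau_cool

    def test_beta_discriminates_generators(self):
        """Simulation study: beta-hat IQRs for beta = 0.3 vs 0.6 generators
        do not overlap at 1% additive noise."""
        t = np.logspace(0, 7, 120)
        rng = np.random.default_rng(4)
        betas = {0.3: [], 0.6: []}
        for beta in betas:
            for rep in range(50):
                y = make_trace(t, 1.0, 0.5, 0.3, 100.0, 2e4, 5e6, beta)
                y = y + 0.01 * rng.standard_normal(len(t))
                fit = tjump.fit_tjump_trace(t, y, seed=rep, n_starts=4,
                                            init={"tau_fast": 50.0,
                                                  "tau_slow": 1e4,
                                                  "tau_cool": 1e6})
                betas[beta].append(fit.beta_fast)
        q1_lo, q3_lo = np.percentile(betas[0.3], [25, 75])
        q1_hi, q3_hi = np.percentile(betas[0.6], [25, 75])
        assert q3_lo < q1_hi

    def test_non_monotone_grid_rejected(self):
        t = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 1000.0])
        with pytest.raises(ValueError, match="increasing"):
            tjump.fit_tjump_trace(t, np.ones(8))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="8 samples"):
            tjump.fit_tjump_trace(np.logspace(0, 3, 5), np.ones(5))


class TestCalibration:
    def _sim_curve(self):
        T = np.linspace(300.0, 330.0, 13)
        rate = 1e6 * np.exp(0.15 * (T - 300.0))
        return np.stack([T, rate], axis=1)

    def test_identity(self):
        sim = self._sim_curve()
        res = tjump.calibrate_to_experiment(sim, sim.copy())
        assert res["time_scale"] == pytest.approx(1.0, abs=1e-6)
        assert res["temp_shift"] == pytest.approx(0.0, abs=1e-6)

    def test_constructed_distortion_recovered(self):
        """Inverse problem: exp = sim rates x0.1 at T + 4 K -> (10, -4)."""
        sim = self._sim_curve()
        exp = sim.copy()
        exp[:, 0] = sim[:, 0] + 4.0
        exp[:, 1] = sim[:, 1] * 0.1
        res = tjump.calibrate_to_experiment(sim, exp)
        assert res["time_scale"] == pytest.approx(10.0, rel=1e-4)
        assert res["temp_shift"] == pytest.approx(-4.0, abs=1e-4)

    def test_single_point_rejected(self):
        one = np.array([[310.0, 1e5]])
        with pytest.raises(ValueError, match="3 points"):
            tjump.calibrate_to_experiment(one, one)


class TestRateInvariants:
    def test_dissociation_rate_monotone_in_u(self, gc_mix):
        """Mirrors the exponential rise of the slow rate with temperature."""
        ks = []
        for u in (0.5, 1.0, 2.0):
            ens = simulate_relaxation(
                gc_mix, u, 250, 15_000.0, seed=41, dt_save=5.0
            )
            fps = tjump.extract_first_passage(ens, "dissociation")
            k, _ = tjump.fit_survival_rate(fps, n_boot=0)
            ks.append(k)
        assert ks[0] < ks[1] < ks[2]

    @pytest.mark.parametrize("name", ["AT-all", "GC-end", "GC-core", "GC-mix"])
    def test_fraying_faster_than_dissociation(self, name):
        """Fast fraying response separates from slow dissociation at u=0."""
        p = build_preset(name)
        ens_f = simulate_relaxation(p, 0.0, 120, 60.0, seed=43, dt_save=0.2)
        k_fray, _ = tjump.fit_survival_rate(
            tjump.extract_first_passage(ens_f, "fraying"), n_boot=0
        )
        ens_d = simulate_relaxation(p, 0.0, 120, 6000.0, seed=44, dt_save=3.0)
        fps_d = tjump.extract_first_passage(ens_d, "dissociation")
        if len(fps_d.event_times):
            k_diss, _ = tjump.fit_survival_rate(fps_d, n_boot=0)
        else:
            k_diss = 1.0 / 6000.0  # censoring bound: slower than 1/t_max
        assert k_fray > 10 * k_diss
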