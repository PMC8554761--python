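"""MSM estimation, CK validation, PCCA+ and bootstrap tests."""

import numpy as np
import pytest

from duplexkin import msm


def simulate_chain(T, n, seed, start=0):
    """Exact discrete-chain sampling (test oracle helper)."""
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    out = np.empty(n, dtype=np.int64)
    s = start
    u = rng.random(n)
    for i in range(n):
        out[i] = s
        s = int(np.searchsorted(cum[s], u[i]))
    return out


def make_assignment(labels, k, dt=1.0):
    return msm.MicrostateAssignment(
        labels=labels, centers=np.zeros((k, 1)), k=k, seed=0, dt_save=dt
    )


class TestClusterMicrostates:
    def test_separated_clouds_recovered(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        pts = np.concatenate([
            c + 0.1 * rng.standard_normal((200, 2)) for c in centers
        ])
        asn = msm.cluster_microstates(pts, k=3, seed=1)
        labels = asn.labels[0]
        for i in range(3):
            block = labels[200 * i: 200 * (i + 1)]
            assert len(np.unique(block)) == 1
        assert len(np.unique(labels)) == 3

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((2000, 3))
        a = msm.cluster_microstates(pts, k=10, seed=7)
        b = msm.cluster_microstates(pts, k=10, seed=7)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.labels[0], b.labels[0])

    def test_objective_beats_random_assignment(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((1500, 2))
        asn = msm.cluster_microstates(pts, k=8, seed=3)
        inertia = sum(
            ((pts[asn.labels[0] == c] - asn.centers[c]) ** 2).sum()
            for c in range(8)
        )
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            rand_labels = r.integers(0, 8, size=len(pts))
            rand_centers = np.stack([
                pts[rand_labels == c].mean(axis=0) if (rand_labels == c).any()
                else np.zeros(2)
                for c in range(8)
            ])
            rand_inertia = sum(
                ((pts[rand_labels == c] - rand_centers[c]) ** 2).sum()
                for c in range(8)
            )
            assert inertia <= rand_inertia

    def test_too_many_clusters(self):
        pts = np.zeros((100, 2))
        with pytest.raises(ValueError, match="distinct"):
            msm.cluster_microstates(pts, k=3, seed=0)


class TestReversibleMLE:
    def test_symmetric_counts_row_normalized(self):
        """Oracle: symmetric counts make the MLE the row-normalized counts."""
        counts = np.array([[90.0, 10.0], [10.0, 90.0]])
        T, pi = msm.reversible_mle(counts)
        assert np.abs(T - np.array([[0.9, 0.1], [0.1, 0.9]])).max() < 1e-9
        assert np.abs(pi - 0.5).max() < 1e-9

    def test_detailed_balance_enforced(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 200, size=(6, 6)).astype(float)
        T, pi = msm.reversible_mle(counts)
        flux = pi[:, None] * T
        assert np.abs(flux - flux.T).max() < 1e-10
        assert np.abs(T.sum(axis=1) - 1.0).max() < 1e-12
        assert np.abs(pi @ T - pi).max() < 1e-10

    def test_implied_timescale_closed_form(self):
        """Oracle: -1.2 / ln 0.8 = 5.3777 ns."""
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        labels = simulate_chain(T, 200_000, seed=4)
        asn = make_assignment(labels, 2, dt=1.2)
        model = msm.estimate_reversible_msm(asn, lag=1.2)
        lam2 = model.eigenvalues[1]
        assert model.implied_timescales[0] == pytest.approx(
            -1.2 / np.log(abs(lam2))
        )
        # the chain itself has lambda_2 = 0.8
        assert abs(lam2 - 0.8) < 0.01
        assert model.implied_timescales[0] == pytest.approx(5.3777, abs=0.3)

    def test_eigenvalue_one_leading(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 50, size=(4, 4)).astype(float)
        T, pi = msm.reversible_mle(counts)
        model_evals, _ = np.linalg.eig(T)
        assert np.max(np.real(model_evals)) == pytest.approx(1.0)

    def test_counts_never_cross_trajectory_boundaries(self):
        a = np.array([0, 0, 0, 0], dtype=np.int64)
        b = np.array([1, 1, 1, 1], dtype=np.int64)
        counts = msm.count_transitions([a, b], 2, 1)
        assert counts[0, 1] == 0 and counts[1, 0] == 0

    def test_ergodic_trimming(self):
        # state 2 is disconnected (appears in its own trajectory only)
        a = np.array([0, 1, 0, 1, 0, 1], dtype=np.int64)
        b = np.array([2, 2, 2], dtype=np.int64)
        asn = make_assignment([a, b], 3)
        model = msm.estimate_reversible_msm(asn, lag=1.0)
        assert set(model.active_set) == {0, 1}
        assert model.discarded_frame_fraction == pytest.approx(3 / 9)

    def test_lag_longer_than_trajectories(self):
        asn = make_assignment([np.array([0, 1], dtype=np.int64)], 2)
        with pytest.raises(ValueError):
            msm.estimate_reversible_msm(asn, lag=10.0)


class TestCKTest:
    def test_k1_zero_deviation(self):
        T = np.array([[0.95, 0.05], [0.05, 0.95]])
        labels = simulate_chain(T, 100_000, seed=6)
        asn = make_assignment(labels, 2)
        model = msm.estimate_reversible_msm(asn, lag=1.0)
        res = msm.ck_test(asn, model, k_max=2)
        assert np.abs(res.predicted[0] - res.estimated[0]).max() < 1e-12

    def test_markovian_chain_passes_to_k6(self):
        """Oracle: data generated from a known reversible Markov chain."""
        # built from a symmetric flux matrix with uniform pi -> reversible
        T = np.array([
            [0.90, 0.08, 0.02],
            [0.08, 0.87, 0.05],
            [0.02, 0.05, 0.93],
        ])
        labels = [simulate_chain(T, 100_000, seed=s) for s in range(4)]
        asn = make_assignment(labels, 3)
        model = msm.estimate_reversible_msm(asn, lag=1.0)
        res = msm.ck_test(asn, model, k_max=6)
        assert res.passed
        # and the predictions agree with the analytically propagated truth
        for k in range(1, 7):
            Tk = np.linalg.matrix_power(T, k)
            assert np.abs(res.estimated[k - 1] - Tk).max() < 0.02

    def test_non_markovian_counterexample_flagged(self):
        """Hidden two-timescale process with merged states must fail."""
        # 3-state chain: 0 <-> 1 slow, 1 <-> 2 faster; merging (0, 1) hides
        # a slow internal relaxation -> merged dynamics are non-Markovian
        T = np.array([
            [0.997, 0.003, 0.000],
            [0.003, 0.907, 0.090],
            [0.000, 0.090, 0.910],
        ])
        labels = [simulate_chain(T, 200_000, seed=s) for s in range(3)]
        merged = [np.where(l == 2, 1, 0).astype(np.int64) for l in labels]
        asn = make_assignment(merged, 2)
        model = msm.estimate_reversible_msm(asn, lag=1.0)
        res = msm.ck_test(asn, model, k_max=6)
        assert not res.passed

    def test_insufficient_data(self):
        labels = np.array([0, 1, 0, 1], dtype=np.int64)
        asn = make_assignment(labels, 2)
        model = msm.estimate_reversible_msm(asn, lag=1.0)
        with pytest.raises(ValueError, match="insufficient|k_max"):
            msm.ck_test(asn, model, k_max=10)


class TestPCCA:
    def test_two_block_chain_recovered(self):
        """Oracle: sign structure of the second eigenvector."""
        eps = 1e-3
        T = np.array([
            [0.80 - eps, 0.20, eps, 0.0],
            [0.20, 0.80 - eps, 0.0, eps],
            [eps, 0.0, 0.70 - eps, 0.30],
            [0.0, eps, 0.30, 0.70 - eps],
        ])
        labels = simulate_chain(T, 300_000, seed=8)
        asn = make_assignment(labels, 4)
        model = msm.estimate_reversible_msm(asn, lag=1.0)
        mm = msm.pcca_coarse_grain(model, 2, assignment=asn)
        crisp = mm.crisp
        assert crisp[0] == crisp[1]
        assert crisp[2] == crisp[3]
        assert crisp[0] != crisp[2]
        # matches the sign structure of the lambda_2 eigenvector
        evals, evecs = np.linalg.eig(model.T.T)
        order = np.argsort(np.real(evals))[::-1]
        v2 = np.real(np.linalg.eig(model.T)[1][:, order[1]])
        sign_split = (v2 > 0).astype(int)
        agree = (sign_split == crisp).mean()
        assert agree in (0.0, 1.0)

    def test_membership_rows_normalized(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(1, 100, size=(8, 8)).astype(float)
        T, pi = msm.reversible_mle(counts)
        model = msm.ReversibleMSM(
            lag=1.0, T=T, pi=pi,
            eigenvalues=np.sort(np.linalg.eigvals(T).real)[::-1],
            implied_timescales=np.array([]), active_set=np.arange(8),
        )
        mm = msm.pcca_coarse_grain(model, 3)
        assert np.abs(mm.memberships.sum(axis=1) - 1.0).max() < 1e-10
        assert mm.memberships.min() >= 0.0
        assert mm.memberships.max() <= 1.0

    def test_single_macrostate(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        model = msm.ReversibleMSM(
            lag=1.0, T=T, pi=np.array([0.5, 0.5]),
            eigenvalues=np.array([1.0, 0.8]),
            implied_timescales=np.array([4.48]), active_set=np.arange(2),
        )
        mm = msm.pcca_coarse_grain(model, 1)
        assert mm.P.shape == (1, 1)
        assert mm.P[0, 0] == 1.0
        assert mm.pi_macro[0] == pytest.approx(1.0)


def _dummy_msm(timescales, lag=1.2):
    n = len(timescales) + 1
    return msm.ReversibleMSM(
        lag=lag, T=np.eye(n), pi=np.full(n, 1.0 / n),
        eigenvalues=np.ones(n),
        implied_timescales=np.asarray(timescales, dtype=float),
        active_set=np.arange(n),
    )


class TestSelectNMacrostates:
    def test_single_dominant_gap(self):
        assert msm.select_n_macrostates(
            _dummy_msm([5000.0, 40.0, 38.0, 35.0]), gap_ratio=3.0
        ) == 2

    def test_all_below_lag(self):
        assert msm.select_n_macrostates(
            _dummy_msm([1.0, 0.5, 0.2]), gap_ratio=3.0
        ) == 1

    def test_five_separated_timescales(self):
        assert msm.select_n_macrostates(
            _dummy_msm([10_000.0, 2_000.0, 400.0, 80.0, 16.0, 0.4]),
            gap_ratio=3.0,
        ) == 6

    def test_no_gap_above_ratio(self):
        assert msm.select_n_macrostates(
            _dummy_msm([2.4, 1.8, 1.5]), gap_ratio=3.0
        ) == 1


class TestBootstrap:
    def test_identical_trajectories_zero_width(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        base = simulate_chain(T, 5_000, seed=10)
        res = msm.bootstrap_uncertainty(
            [base.copy() for _ in range(5)], k=2, lag=1.0, n_boot=20, seed=0
        )
        lo, hi = res["pi"]
        assert np.abs(hi - lo).max() < 1e-12

    def test_deterministic(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        labels = [simulate_chain(T, 3_000, seed=s) for s in range(6)]
        a = msm.bootstrap_uncertainty(labels, k=2, lag=1.0, n_boot=30, seed=3)
        b = msm.bootstrap_uncertainty(labels, k=2, lag=1.0, n_boot=30, seed=3)
        assert np.array_equal(a["pi"], b["pi"])
        assert np.array_equal(a["timescales"], b["timescales"])

    def test_coverage_of_true_stationary(self):
        """Coverage study against the generating chain (reduced n)."""
        T = np.array([
            [0.85, 0.10, 0.05],
            [0.10, 0.80, 0.10],
            [0.05, 0.10, 0.85],
        ])
        evals = np.linalg.eigvals(T.T)
        idx = np.argmax(np.real(evals))
        pi_true = np.real(np.linalg.eig(T.T)[1][:, idx])
        pi_true = np.abs(pi_true) / np.abs(pi_true).sum()
        hits = 0
        n_outer = 200
        for rep in range(n_outer):
            labels = [
                simulate_chain(T, 400, seed=1000 * rep + j, start=j % 3)
                for j in range(20)
            ]
            try:
                res = msm.bootstrap_uncertainty(
                    labels, k=3, lag=1.0, n_boot=50, seed=rep
                )
            except ValueError:
                continue
            lo, hi = res["pi"][0][0], res["pi"][1][0]
            if lo <= pi_true[0] <= hi:
                hits += 1
        coverage = hits / n_outer
        assert 0.85 <= coverage <= 0.99
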