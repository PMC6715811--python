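"""Loop-anchored chain: connectivity, normal-mode analytics, Langevin sampling."""

import numpy as np
import pytest

from grmc.simulate import (
    GRMCSystem,
    LoopSet,
    Trajectory,
    TrajectoryStats,
    analytic_mean_distance,
    analytic_pair_sigma,
    binned_P_vs_R,
    build_connectivity,
    estimate_stats,
    langevin_run,
    sample_equilibrium,
)
from grmc.theory import contact_prob_chi


class TestConnectivity:
    def test_three_bead_chain_matrix(self):
        k = 2.5
        A = build_connectivity(GRMCSystem(N=3, kappa=k))
        expected = np.array([[-k, k, 0.0], [k, -2 * k, k], [0.0, k, -k]])
        assert np.allclose(A, expected)

    def test_three_bead_eigenvalues(self):
        k = 2.5
        A = build_connectivity(GRMCSystem(N=3, kappa=k))
        vals = np.sort(np.linalg.eigvalsh(A))
        assert np.allclose(vals, [-3 * k, -k, 0.0], atol=1e-10)

    def test_row_sums_zero_with_loops(self):
        loops = LoopSet([(0, 5), (2, 9), (3, 7)])
        A = build_connectivity(GRMCSystem(N=10, loops=loops, kappa=3.0, omega=7.0))
        assert np.allclose(A.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(A, A.T)
        assert A[0, 5] == 7.0 and A[1, 2] == 3.0

    def test_negative_semidefinite_single_zero_mode(self):
        loops = LoopSet([(0, 5), (2, 9)])
        A = build_connectivity(GRMCSystem(N=10, loops=loops))
        vals = np.linalg.eigvalsh(A)
        assert np.sum(np.abs(vals) < 1e-9 * 100 * 10) == 1
        assert np.all(vals < 1e-6)

    def test_out_of_range_loop_rejected(self):
        with pytest.raises(ValueError):
            GRMCSystem(N=5, loops=LoopSet([(0, 7)]))

    def test_adjacent_and_self_pairs_rejected(self):
        with pytest.raises(ValueError):
            LoopSet([(3, 4)])
        with pytest.raises(ValueError):
            LoopSet([(3, 3)])


class TestAnalytics:
    def test_dimer_variance(self):
        # N=2 spring kappa: eigenpair (0, -2 kappa), sigma^2 = kT/kappa
        s = GRMCSystem(N=2, kappa=4.0, kT=1.5)
        assert analytic_pair_sigma(s)[0, 1] ** 2 == pytest.approx(1.5 / 4.0)

    def test_free_chain_linear_variance_growth(self):
        # Rouse chain: sigma_mn^2 = |m-n| kT / kappa
        s = GRMCSystem(N=30, kappa=2.0)
        sig = analytic_pair_sigma(s)
        m, n = 3, 17
        assert sig[m, n] ** 2 == pytest.approx(abs(m - n) / 2.0, rel=1e-9)

    def test_loop_stiffens_anchored_pair(self):
        base = GRMCSystem(N=40, kappa=3.0, omega=3.0)
        looped = GRMCSystem(N=40, kappa=3.0, omega=3.0, loops=LoopSet([(5, 30)]))
        assert analytic_pair_sigma(looped)[5, 30] < analytic_pair_sigma(base)[5, 30]

    def test_loops_never_soften_any_pair(self):
        base = GRMCSystem(N=30, kappa=3.0, omega=5.0)
        looped = GRMCSystem(N=30, kappa=3.0, omega=5.0, loops=LoopSet([(4, 20), (10, 25)]))
        assert np.all(analytic_pair_sigma(looped) <= analytic_pair_sigma(base) + 1e-12)

    def test_disconnected_graph_rejected(self, monkeypatch):
        # a broken chain has two zero modes; the mode analysis must refuse it
        import grmc.simulate as sim

        orig = sim.build_connectivity

        def cut(system):
            B = orig(system)
            B[2, 3] = B[3, 2] = 0.0
            np.fill_diagonal(B, 0.0)
            np.fill_diagonal(B, -B.sum(axis=1))
            return B

        monkeypatch.setattr(sim, "build_connectivity", cut)
        with pytest.raises(ValueError, match="connected"):
            analytic_pair_sigma(GRMCSystem(N=6, kappa=3.0))


class TestLangevin:
    def test_same_seed_bit_identical(self):
        s = GRMCSystem(N=10, kappa=3.0)
        t1 = langevin_run(s, n_steps=2000, save_every=500, seed=42)
        t2 = langevin_run(s, n_steps=2000, save_every=500, seed=42)
        assert np.array_equal(t1.positions, t2.positions)

    def test_different_seeds_differ(self):
        s = GRMCSystem(N=10, kappa=3.0)
        t1 = langevin_run(s, n_steps=2000, save_every=500, seed=1)
        t2 = langevin_run(s, n_steps=2000, save_every=500, seed=2)
        assert not np.array_equal(t1.positions, t2.positions)

    def test_frozen_dynamics_static(self):
        s = GRMCSystem(N=8, kappa=3.0, kT=0.0)
        x0 = np.zeros((8, 3))  # mechanical equilibrium of zero-rest-length springs
        t = langevin_run(s, n_steps=1000, save_every=100, seed=0, x0=x0)
        assert np.allclose(t.positions, 0.0, atol=1e-14)

    def test_equipartition(self):
        s = GRMCSystem(N=20, kappa=3.0, xi=0.1, kT=1.0)
        t = langevin_run(s, n_steps=100_000, save_every=200, seed=3)
        assert t.kinetic_temperature() == pytest.approx(1.0, rel=0.05)

    def test_rouse_sigma_matches_analytics(self):
        s = GRMCSystem(N=30, kappa=3.0, xi=0.1)
        trajs = [
            langevin_run(s, n_steps=150_000, save_every=1500, seed=10 + i)
            for i in range(6)
        ]
        stats = estimate_stats(trajs, r_c=1.0)
        sig_th = analytic_pair_sigma(s)
        for m, n in [(0, 29), (5, 20), (10, 12)]:
            per_traj = stats.per_traj_R2_mean[:, m, n] / 3.0
            se = per_traj.std(ddof=1) / np.sqrt(len(trajs))
            assert abs(per_traj.mean() - sig_th[m, n] ** 2) < 3 * se + 1e-12

    def test_isotropy_of_equilibrium_sampler(self, rng):
        s = GRMCSystem(N=25, kappa=3.0)
        X = np.array([sample_equilibrium(s, rng) for _ in range(300)])
        d = X[:, 0] - X[:, 24]  # pair vectors across samples
        var = d.var(axis=0)
        assert var.max() / var.min() < 1.3
        assert np.allclose(var.mean(), analytic_pair_sigma(s)[0, 24] ** 2, rtol=0.15)

    def test_divergence_detected(self):
        s = GRMCSystem(N=10, kappa=3.0)
        with pytest.raises(FloatingPointError):
            langevin_run(s, n_steps=5000, dt=50.0, save_every=100, seed=0)


class TestEstimators:
    @staticmethod
    def _single_snapshot(distance):
        s = GRMCSystem(N=2, kappa=1.0)
        pos = np.zeros((1, 2, 3))
        pos[0, 1, 0] = distance
        return Trajectory(positions=pos, dt=0.01, save_every=1, seed=0, system=s)

    def test_single_snapshot_contact(self):
        stats = estimate_stats(self._single_snapshot(0.5), r_c=1.0)
        assert stats.P[0, 1] == 1.0
        assert stats.R_mean[0, 1] == pytest.approx(0.5)

    def test_single_snapshot_no_contact(self):
        stats = estimate_stats(self._single_snapshot(2.0), r_c=1.0)
        assert stats.P[0, 1] == 0.0

    def test_contact_prob_matches_chi_prediction(self):
        s = GRMCSystem(N=20, kappa=3.0, xi=0.1)
        trajs = [
            langevin_run(s, n_steps=120_000, save_every=1200, seed=50 + i)
            for i in range(6)
        ]
        stats = estimate_stats(trajs, r_c=1.5)
        sig = analytic_pair_sigma(s)
        for m, n in [(0, 19), (3, 12)]:
            expected = contact_prob_chi(sig[m, n], 1.5)
            per_traj = stats.per_traj_P[:, m, n]
            se = per_traj.std(ddof=1) / np.sqrt(len(trajs))
            assert abs(stats.P[m, n] - expected) < 3 * se + 0.01

    def test_estimator_consistency_with_depth(self):
        # the P estimator approaches the chi value as T*M grows
        s = GRMCSystem(N=10, kappa=3.0, xi=0.1)
        sig = analytic_pair_sigma(s)
        expected = contact_prob_chi(sig[0, 9], 1.5)
        errs = []
        for n_steps in (20_000, 400_000):
            trajs = [
                langevin_run(s, n_steps=n_steps, save_every=1000, seed=90 + i)
                for i in range(4)
            ]
            stats = estimate_stats(trajs, r_c=1.5)
            errs.append(abs(stats.P[0, 9] - expected))
        assert errs[1] < max(errs[0], 0.02)


class TestBinnedCurve:
    @staticmethod
    def _stats_from_matrices(P, R):
        N = P.shape[0]
        z = np.zeros_like(P)
        return TrajectoryStats(
            M=1, T=1, r_c=1.0, P=P, R_mean=R, R2_mean=z,
            per_traj_R_mean=R[None], per_traj_R2_mean=z[None], per_traj_P=P[None],
        )

    def test_identical_pairs_single_bin(self):
        P = np.full((3, 3), 0.2)
        R = np.full((3, 3), 1.7)
        binned = binned_P_vs_R(self._stats_from_matrices(P, R))
        assert len(binned) == 1
        assert binned.R_mean.iloc[0] == pytest.approx(1.7)
        assert binned["count"].iloc[0] == 3

    def test_two_bins_hand_computed_means(self):
        P = np.zeros((4, 4))
        R = np.zeros((4, 4))
        vals = {(0, 1): (0.1, 1.0), (0, 2): (0.12, 2.0), (0, 3): (0.9, 5.0),
                (1, 2): (0.11, 3.0), (1, 3): (0.85, 7.0), (2, 3): (0.88, 6.0)}
        for (m, n), (p, r) in vals.items():
            P[m, n] = P[n, m] = p
            R[m, n] = R[n, m] = r
        binned = binned_P_vs_R(self._stats_from_matrices(P, R), bin_width=0.5, log=True)
        assert len(binned) == 2
        assert binned.R_mean.iloc[0] == pytest.approx(2.0)  # mean of 1, 2, 3
        assert binned.R_mean.iloc[1] == pytest.approx(6.0)  # mean of 5, 7, 6
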