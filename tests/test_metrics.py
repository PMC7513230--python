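import numpy as np
import pytest

from lmechem.metrics import (ComparisonReport, boundary_mass, compare_lme_to_ssa,
                             kl_divergence, kl_sampling_floor, moment_error)
from lmechem.maxent import MaxentWorkspace, distribution_from_lambda
from lmechem.moments import MomentBasis
from lmechem.networks import StateSpace


class TestKL:
    def test_identical_is_zero(self):
        P = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(P, P) == 0.0

    def test_point_vs_fair_coin(self):
        assert kl_divergence(np.array([1.0, 0.0]), np.array([0.5, 0.5])) \
            == pytest.approx(np.log(2))

    def test_matches_hand_sum_uniform_vs_geometric(self):
        ws = MaxentWorkspace(MomentBasis.degree_graded(1, 1), StateSpace((0,), (20,)))
        Q = distribution_from_lambda(np.array([0.5]), ws)
        P = np.full(21, 1 / 21)
        hand = sum(p * np.log(p / q) for p, q in zip(P, Q))
        assert kl_divergence(P, Q) == pytest.approx(hand, rel=1e-12)

    def test_nonnegative_random(self, rng):
        for _ in range(20):
            P = rng.dirichlet(np.ones(15))
            Q = rng.dirichlet(np.ones(15)) + 1e-9
            Q /= Q.sum()
            assert kl_divergence(P, Q) >= 0.0

    def test_support_violation(self):
        with pytest.raises(ValueError):
            kl_divergence(np.array([0.5, 0.5]), np.array([1.0, 0.0]))

    def test_sampling_floor(self):
        counts = np.array([5, 0, 3, 2])
        assert kl_sampling_floor(counts, 10) == pytest.approx(100 * 2 / 20)


class TestMomentError:
    def test_identity(self):
        assert moment_error([3.0, 4.0], [3.0, 4.0]) == 0.0

    def test_uniform_scaling(self):
        assert moment_error([3.0, 4.0], [3.03, 4.04]) == pytest.approx(1.0)

    def test_single_component(self):
        assert moment_error([38.01], [38.10]) == pytest.approx(100 * 0.09 / 38.01)

    def test_zero_reference(self):
        with pytest.raises(ValueError):
            moment_error([0.0], [1.0])


class TestComparisonReport:
    def _report(self):
        times = np.array([0.0, 1.0, 2.0, 3.0])
        return ComparisonReport(times, kl=np.array([0.0, 1e-3, 2e-3, 3e-3]),
                                err_order1=np.array([0.0, 1.0, 2.0, 3.0]),
                                err_order2=np.array([0.0, 2.0, 4.0, 6.0]),
                                window=(0.0, 3.0))

    def test_averages_are_window_means(self):
        rep = self._report()
        assert rep.avg_kl_percent == pytest.approx(100 * 1.5e-3)
        assert rep.avg_err_order1 == pytest.approx(1.5)
        assert rep.avg_err_order2 == pytest.approx(3.0)

    def test_window_restriction(self):
        rep = self._report()
        rep.window = (1.0, 2.0)
        assert rep.avg_err_order1 == pytest.approx(1.5)

    def test_tsv_roundtrip_shape(self):
        text = self._report().to_tsv()
        rows = [l.split("\t") for l in text.strip().splitlines()]
        assert rows[0] == ["time", "kl_nats", "err_order1_pct", "err_order2_pct"]
        assert len(rows) == 5


class TestCompareLmeToSsa:
    def test_self_comparison_is_zero(self, birth_death):
        # LME trajectory compared against an 'ensemble' built from its own
        # distributions: all error columns must vanish
        import lmechem as lc
        from lmechem.ssa import EnsembleSummary
        from lmechem.moments import evaluate_monomials
        ws = MaxentWorkspace(MomentBasis.degree_graded(1, 2), StateSpace((0,), (60,)))
        lam = np.zeros(2)
        lam[0] = 2.0
        st = lc.LagrangeState(lam, lc.lambda0_from_lambdas(lam, ws))
        cfg = lc.SolverConfig(output_times=(0.5, 1.5))
        traj = lc.integrate(st, birth_death, ws, cfg, store_distributions=True)

        n = 10**9  # fake exact counts
        counts = np.rint(traj.distributions * n).astype(np.int64)
        basis = ws.basis
        F = evaluate_monomials(ws.states, basis.active)
        msum = traj.distributions @ F * n
        ens = EnsembleSummary(times=traj.times, omega=ws.omega, counts=counts,
                              overflow=np.zeros(2, dtype=np.int64),
                              n_trajectories=n, basis=basis,
                              moment_sum=msum, moment_sumsq=msum * 0 + 1)
        rep = compare_lme_to_ssa(traj, ens, basis)
        assert rep.avg_kl_percent < 1e-8
        assert rep.avg_err_order1 < 1e-6
        assert rep.avg_err_order2 < 1e-6

    def test_grid_mismatch_rejected(self, birth_death):
        import lmechem as lc
        from lmechem.ssa import SSAConfig, simulate_ensemble
        ws = MaxentWorkspace(MomentBasis.degree_graded(1, 2), StateSpace((0,), (60,)))
        lam = np.array([2.0, 0.0])
        st = lc.LagrangeState(lam, lc.lambda0_from_lambdas(lam, ws))
        traj = lc.integrate(st, birth_death, ws,
                            lc.SolverConfig(output_times=(0.5, 1.5)),
                            store_distributions=True)
        ens = simulate_ensemble(birth_death, ws.omega,
                                SSAConfig(n_trajectories=100, seed=0,
                                          output_times=(0.5, 2.0), initial_state=(0,)))
        with pytest.raises(ValueError, match="grids differ"):
            compare_lme_to_ssa(traj, ens, ws.basis)


class TestBoundaryMass:
    def test_counts_only_truncating_faces(self):
        omega = StateSpace((0,), (3,))
        P = np.array([0.4, 0.3, 0.2, 0.1])
        assert boundary_mass(P, omega) == pytest.approx(0.1)


class TestExperimentDrivers:
    def test_oscillation_experiment_writes_artifacts(self, tmp_path):
        from lmechem.metrics import run_experiment
        res = run_experiment("fig3", seed=1, outdir=tmp_path, n_trajectories=2000)
        assert all(np.isfinite(v) for v in res["report"].values())
        assert (tmp_path / "brusselator_errors.tsv").exists()
        assert (tmp_path / "brusselator_first_moments.tsv").exists()

    def test_unknown_experiment(self):
        from lmechem.metrics import run_experiment
        with pytest.raises(KeyError):
            run_experiment("fig9")


class TestBirthDeathBenchmarkAccuracy:
    def test_linear_network_lme_matches_ssa(self, birth_death):
        # moment equations are exact for linear networks: LME vs SSA
        # first-moment differences are pure sampling noise
        import lmechem as lc
        from lmechem.ssa import SSAConfig, simulate_ensemble
        omega = StateSpace((0,), (60,))
        ws = MaxentWorkspace(MomentBasis.degree_graded(1, 2), omega)
        lam = np.array([14.0, 0.0])
        st = lc.LagrangeState(lam, lc.lambda0_from_lambdas(lam, ws))
        grid = (1.0, 2.0, 4.0, 8.0)
        traj = lc.integrate(st, birth_death, ws,
                            lc.SolverConfig(output_times=grid),
                            store_distributions=True)
        ens = simulate_ensemble(birth_death, omega,
                                SSAConfig(n_trajectories=100_000, seed=5,
                                          output_times=grid, initial_state=(0,)))
        rep = compare_lme_to_ssa(traj, ens, ws.basis)
        assert rep.avg_err_order1 < 0.5
        assert np.isfinite(rep.avg_kl_percent)
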