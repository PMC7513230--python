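import numpy as np
import pytest
from scipy.stats import poisson

from lmechem.maxent import LagrangeState, MaxentWorkspace, jacobian, lambda0_from_lambdas
from lmechem.moments import MomentBasis, derive_moment_equations, moments_from_distribution
from lmechem.networks import Reaction, ReactionNetwork, SpeciesSet, StateSpace
from lmechem.solver import SolverConfig, build_generator_action, integrate, lme_rhs, \
    steady_state_oracle


@pytest.fixture(scope="module")
def bd_ws():
    return MaxentWorkspace(MomentBasis.degree_graded(1, 2), StateSpace((0,), (60,)))


def _concentrated_state(ws, lam1=14.0):
    lam = np.zeros(ws.M)
    lam[0] = lam1
    return LagrangeState(lam, lambda0_from_lambdas(lam, ws))


class TestLmeRhs:
    def test_chain_rule_identity(self, birth_death, bd_ws, rng):
        # J (dlambda/dt) must reproduce d(mu)/dt = A mu + mu_c exactly
        sysm = derive_moment_equations(birth_death, bd_ws.basis)
        lam = bd_ws.lambda_raw(rng.normal(0, 0.4, 2))
        st = LagrangeState(lam, lambda0_from_lambdas(lam, bd_ws))
        from lmechem.maxent import moments_from_lambda
        mu = moments_from_lambda(st, bd_ws)
        dmu = sysm.rhs(mu)
        dlam = lme_rhs(st, sysm, bd_ws)
        J = jacobian(st, bd_ws)
        assert np.linalg.norm(J @ dlam - dmu) <= 1e-8 * np.linalg.norm(dmu)
        # first-moment equation: d mu1/dt = kb - kd mu1
        assert (J @ dlam)[0] == pytest.approx(10.0 - mu[0], rel=1e-8)

    def test_zero_at_stationary_state(self, birth_death, bd_ws):
        # moments of the exact stationary law make d(mu)/dt vanish, hence dlambda/dt
        from lmechem.initfit import fit_lambda_from_moments
        p_ss = steady_state_oracle(birth_death, bd_ws.omega)
        mu_ss = moments_from_distribution(p_ss, bd_ws.basis, bd_ws.omega)
        fit = fit_lambda_from_moments(mu_ss, bd_ws, tol=1e-13)
        sysm = derive_moment_equations(birth_death, bd_ws.basis)
        dlam = lme_rhs(fit.state, sysm, bd_ws)
        assert np.abs(dlam).max() < 1e-6

    def test_direct_and_matrix_routes_agree(self, birth_death, bd_ws, rng):
        sysm = derive_moment_equations(birth_death, bd_ws.basis)
        lam = bd_ws.lambda_raw(rng.normal(0, 0.4, 2))
        st = LagrangeState(lam, lambda0_from_lambdas(lam, bd_ws))
        d1 = lme_rhs(st, sysm, bd_ws, method="matrix")
        d2 = lme_rhs(st, sysm, bd_ws, network=birth_death, method="direct")
        assert np.allclose(d1, d2, rtol=1e-8)

    def test_lambda0_rate_diagnostic(self, birth_death, bd_ws):
        sysm = derive_moment_equations(birth_death, bd_ws.basis)
        st = _concentrated_state(bd_ws, 2.0)
        from lmechem.maxent import moments_from_lambda
        dlam, dlam0 = lme_rhs(st, sysm, bd_ws, with_lambda0_rate=True)
        mu = moments_from_lambda(st, bd_ws)
        assert dlam0 == pytest.approx(-mu @ dlam, rel=1e-12)


class TestIntegrate:
    def test_birth_death_closed_form(self, birth_death, bd_ws):
        # linear network: the moment equations close, so mu1(t) must follow
        # (kb/kd)(1 - e^{-kd t}) from a (numerically) empty initial state
        st = _concentrated_state(bd_ws)
        cfg = SolverConfig(output_times=tuple(np.linspace(0.5, 5.0, 10)))
        traj = integrate(st, birth_death, bd_ws, cfg)
        ref = 10.0 * (1.0 - np.exp(-traj.times))
        rel = np.abs(traj.moments[:, 0] - ref) / ref
        assert rel.max() <= 1e-6

    def test_frozen_network_keeps_lambda_constant(self, bd_ws):
        sp = SpeciesSet(("X",))
        net = ReactionNetwork(sp, (Reaction((0,), (1,), 1e-300),))
        st = _concentrated_state(bd_ws, 2.0)
        traj = integrate(st, net, bd_ws, SolverConfig(output_times=(1.0, 5.0)))
        drift = max(np.abs(s.lambdas - st.lambdas).max() for s in traj.states)
        assert drift < 1e-9

    def test_normalization_exact_at_outputs(self, birth_death, bd_ws):
        st = _concentrated_state(bd_ws, 3.0)
        cfg = SolverConfig(output_times=(0.5, 1.5))
        traj = integrate(st, birth_death, bd_ws, cfg, store_distributions=True)
        for P in traj.distributions:
            assert P.sum() == pytest.approx(1.0, abs=1e-12)
        assert traj.n_accepted > 0

    def test_tolerance_halving_consistency(self, birth_death, bd_ws):
        st = _concentrated_state(bd_ws, 3.0)
        outs = (1.0, 3.0)
        mus = []
        for rtol in (1e-6, 5e-7):
            cfg = SolverConfig(output_times=outs, rel_tol=rtol, abs_tol=1e-9)
            mus.append(integrate(st, birth_death, bd_ws, cfg).moments[:, 0])
        assert np.abs(mus[0] - mus[1]).max() <= 1e-5 * np.abs(mus[1]).max()

    def test_matches_scipy_rk45_on_same_rhs(self, birth_death, bd_ws):
        # independent integrator cross-check of the hand-rolled embedded pair
        from scipy.integrate import solve_ivp
        from lmechem.solver import _TildeRHS
        st = _concentrated_state(bd_ws, 3.0)
        rhs = _TildeRHS(bd_ws, birth_death)
        y0 = bd_ws.lambda_tilde(st.lambdas)
        sol = solve_ivp(lambda t, y: rhs(y), (0.0, 2.0), y0, method="RK45",
                        rtol=1e-10, atol=1e-12)
        cfg = SolverConfig(output_times=(2.0,), rel_tol=1e-10, abs_tol=1e-12)
        traj = integrate(st, birth_death, bd_ws, cfg)
        lam_scipy = bd_ws.lambda_raw(sol.y[:, -1])
        assert np.allclose(traj.states[-1].lambdas, lam_scipy, rtol=1e-6, atol=1e-8)

    def test_output_times_validated(self):
        with pytest.raises(ValueError):
            SolverConfig(output_times=(2.0, 1.0))
        with pytest.raises(ValueError):
            SolverConfig(output_times=(1.0,), rel_tol=-1.0)


class TestGeneratorAction:
    def test_matches_direct_moment_rhs(self, birth_death, bd_ws, rng):
        # D^T P must equal the generator expectation of the orthonormal basis
        from lmechem.moments import moment_rhs_direct
        D = build_generator_action(bd_ws, birth_death)
        P = rng.dirichlet(np.ones(bd_ws.n_states))
        dmu_t = D.T @ P
        dmu_raw = moment_rhs_direct(birth_death, P, bd_ws.basis, bd_ws.omega)
        assert np.allclose(dmu_t, bd_ws.T @ dmu_raw, rtol=1e-9, atol=1e-12)


class TestExactEvolution:
    def test_matches_ssa_burn_in_moments(self, birth_death):
        # matrix-exponential transient vs an SSA burn-in from the same start
        from lmechem.solver import evolve_distribution
        from lmechem.ssa import make_initial_condition
        from lmechem.moments import MomentBasis, moments_from_distribution, \
            monomial_to_factorial
        omega = StateSpace((0,), (40,))
        start = np.zeros(41)
        start[0] = 1.0
        P = evolve_distribution(birth_death, omega, start, 1.0)
        mu_exact = moments_from_distribution(P, MomentBasis.degree_graded(1, 1), omega)
        # closed form for the linear network
        assert mu_exact[0] == pytest.approx(10 * (1 - np.exp(-1.0)), rel=1e-8)
        _, fact, _ = make_initial_condition(birth_death, omega, (0,), 1.0, 40000, 1)
        assert fact[0] == pytest.approx(mu_exact[0], abs=3 * 2.5 / np.sqrt(40000))

    def test_zero_time_is_identity(self, birth_death):
        from lmechem.solver import evolve_distribution
        omega = StateSpace((0,), (10,))
        P0 = np.full(11, 1 / 11)
        assert np.array_equal(evolve_distribution(birth_death, omega, P0, 0.0), P0)


class TestSteadyStateOracle:
    def test_birth_death_truncated_poisson(self, birth_death):
        omega = StateSpace((0,), (200,))
        p = steady_state_oracle(birth_death, omega)
        ref = poisson.pmf(np.arange(201), 10.0)
        ref /= ref.sum()
        assert 0.5 * np.abs(p - ref).sum() <= 1e-10

    def test_independent_birth_death_product_poisson(self):
        sp = SpeciesSet(("X", "Y"))
        net = ReactionNetwork(sp, (
            Reaction((0, 0), (1, 0), 4.0), Reaction((1, 0), (0, 0), 1.0),
            Reaction((0, 0), (0, 1), 6.0), Reaction((0, 1), (0, 0), 2.0),
        ))
        omega = StateSpace((0, 0), (25, 25))
        p = steady_state_oracle(net, omega)
        px = poisson.pmf(np.arange(26), 4.0)
        py = poisson.pmf(np.arange(26), 3.0)
        ref = np.outer(px / px.sum(), py / py.sum()).ravel()
        assert 0.5 * np.abs(p - ref).sum() <= 1e-8

    def test_schlogl_is_bimodal_with_modes_near_fixed_points(self):
        from lmechem.networks import builtin_network
        net, omega, _ = builtin_network("schlogl")
        p = steady_state_oracle(net, omega)
        # local maxima of the stationary law
        interior = (p[1:-1] > p[:-2]) & (p[1:-1] > p[2:])
        modes = np.where(interior)[0] + 1
        assert len(modes) == 2
        assert abs(modes[0] - 10) <= 3 and abs(modes[1] - 72) <= 6
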