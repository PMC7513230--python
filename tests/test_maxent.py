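import itertools

import numpy as np
import pytest

from lmechem.maxent import (LagrangeState, MaxentNumericsError, MaxentWorkspace,
                            combined_moment, distribution_from_lambda, jacobian,
                            lambda0_from_lambdas, moments_from_lambda, shannon_entropy)
from lmechem.moments import MomentBasis, moments_from_distribution
from lmechem.networks import StateSpace
from lmechem.initfit import fit_lambda_from_moments


@pytest.fixture(scope="module")
def ws151():
    return MaxentWorkspace(MomentBasis.degree_graded(1, 2), StateSpace((0,), (150,)))


class TestLambda0:
    def test_uniform(self, ws151):
        assert lambda0_from_lambdas(np.zeros(2), ws151) == pytest.approx(np.log(151))

    def test_two_states(self):
        ws = MaxentWorkspace(MomentBasis.degree_graded(1, 1), StateSpace((0,), (1,)))
        assert lambda0_from_lambdas(np.zeros(1), ws) == pytest.approx(np.log(2))

    def test_geometric_closed_form(self):
        # lambda1 = 0.5 on a large box: Z ~ 1/(1 - e^-0.5)
        ws = MaxentWorkspace(MomentBasis.degree_graded(1, 1), StateSpace((0,), (400,)))
        lam0 = lambda0_from_lambdas(np.array([0.5]), ws)
        assert lam0 == pytest.approx(np.log(1.0 / (1.0 - np.exp(-0.5))), rel=1e-12)

    def test_pathological_lambda_fails(self, ws151):
        with pytest.raises((MaxentNumericsError, ValueError)):
            lambda0_from_lambdas(np.array([np.nan, 0.0]), ws151)


class TestDistribution:
    def test_uniform(self, ws151):
        P = distribution_from_lambda(np.zeros(2), ws151)
        assert np.allclose(P, 1.0 / 151)
        assert P.sum() == pytest.approx(1.0, abs=1e-12)

    def test_geometric_shape(self):
        ws = MaxentWorkspace(MomentBasis.degree_graded(1, 1), StateSpace((0,), (100,)))
        p = 0.7
        P = distribution_from_lambda(np.array([-np.log(p)]), ws)
        ratios = P[1:] / P[:-1]
        assert np.allclose(ratios, p, rtol=1e-10)

    def test_normalization_exact_via_lambda0(self, ws151, rng):
        lam = ws151.lambda_raw(rng.normal(0, 0.5, 2))
        st = LagrangeState(lam, lambda0_from_lambdas(lam, ws151))
        P_direct = np.exp(-st.lambda0 + ws151.log_weights_raw(st.lambdas))
        assert P_direct.sum() == pytest.approx(1.0, abs=1e-12)


class TestMoments:
    def test_uniform_mean(self, ws151):
        mu = moments_from_lambda(np.zeros(2), ws151)
        assert mu[0] == pytest.approx(75.0)

    def test_concentration_limit(self):
        ws = MaxentWorkspace(MomentBasis.degree_graded(1, 1), StateSpace((0,), (50,)))
        mu = moments_from_lambda(np.array([12.0]), ws)
        assert mu[0] < 1e-4        # mass collapses onto min(Omega) = 0

    def test_composition_identity(self, ws151, rng):
        lam = ws151.lambda_raw(rng.normal(0, 0.5, 2))
        mu1 = moments_from_lambda(lam, ws151)
        P = distribution_from_lambda(lam, ws151)
        mu2 = moments_from_distribution(P, ws151.basis, ws151.omega)
        assert np.allclose(mu1, mu2, rtol=1e-12)


class TestCombinedMoments:
    def test_zeroth_is_normalization(self, ws151):
        assert combined_moment(np.zeros(2), 0, 0, ws151) == pytest.approx(1.0)

    def test_symmetry_and_reduction(self, ws151, rng):
        lam = ws151.lambda_raw(rng.normal(0, 0.4, 2))
        m12 = combined_moment(lam, 1, 2, ws151)
        m21 = combined_moment(lam, 2, 1, ws151)
        assert m12 == m21
        mu = moments_from_lambda(lam, ws151)
        assert combined_moment(lam, 0, 2, ws151) == pytest.approx(mu[1], rel=1e-12)

    def test_index_range(self, ws151):
        with pytest.raises(IndexError):
            combined_moment(np.zeros(2), 0, 3, ws151)


class TestJacobian:
    def test_two_state_uniform_is_minus_quarter(self):
        ws = MaxentWorkspace(MomentBasis.degree_graded(1, 1), StateSpace((0,), (1,)))
        J = jacobian(np.zeros(1), ws)
        assert J[0, 0] == pytest.approx(-0.25)

    def test_matches_finite_differences(self, rng):
        ws = MaxentWorkspace(MomentBasis.degree_graded(1, 3), StateSpace((0,), (30,)))
        lam = ws.lambda_raw(rng.normal(0, 0.5, 3))
        J = jacobian(lam, ws)
        scale = np.abs(ws.F).max(axis=0)
        Jfd = np.zeros((3, 3))
        for j in range(3):
            h = 1e-7 / scale[j]
            e = np.zeros(3)
            e[j] = h
            Jfd[:, j] = (moments_from_lambda(lam + e, ws)
                         - moments_from_lambda(lam - e, ws)) / (2 * h)
        assert np.abs(J - Jfd).max() <= 1e-6 * np.abs(J).max()
        assert np.abs(J - J.T).max() <= 1e-12 * np.abs(J).max()


class TestEntropy:
    def test_point_mass(self):
        P = np.zeros(10)
        P[3] = 1.0
        assert shannon_entropy(P) == 0.0

    def test_uniform_is_maximal(self):
        assert shannon_entropy(np.full(151, 1 / 151)) == pytest.approx(np.log(151))

    def test_maxent_distribution_maximizes_entropy_under_moment_constraint(self):
        # exhaustive check on a 4-state space with a mean constraint:
        # among all tables with the same mean, the fitted exponential family
        # member has the largest entropy
        omega = StateSpace((0,), (3,))
        basis = MomentBasis.degree_graded(1, 1)
        ws = MaxentWorkspace(basis, omega)
        target = np.array([1.2])
        fit = fit_lambda_from_moments(target, ws, tol=1e-12)
        P_me = distribution_from_lambda(fit.state, ws)
        S_me = shannon_entropy(P_me)
        grid = np.linspace(0.0, 1.0, 61)
        x = np.arange(4)
        best = -1.0
        for p1, p2, p3 in itertools.product(grid, grid, grid):
            p0 = 1.0 - p1 - p2 - p3
            if p0 < 0:
                continue
            P = np.array([p0, p1, p2, p3])
            if abs(P @ x - target[0]) > 5e-3:
                continue
            best = max(best, shannon_entropy(P))
        assert S_me >= best - 5e-3


class TestWorkspace:
    def test_orthonormal_representation_is_equivalent(self, rng):
        ws = MaxentWorkspace(MomentBasis.degree_graded(2, 4), StateSpace((0, 0), (20, 20)))
        lt = rng.normal(0, 0.4, ws.M)
        lam = ws.lambda_raw(lt)
        assert np.allclose(ws.lambda_tilde(lam), lt, atol=1e-9)
        P1 = ws.distribution_tilde(lt)
        P2 = distribution_from_lambda(lam, ws)
        assert np.allclose(P1, P2, atol=1e-12)
        # Q is the orthonormal value table evaluated on Omega
        assert np.allclose(ws.orthonormal_values_at(ws.states), ws.Q, atol=1e-10)

    def test_uniform_gram_is_identity(self):
        ws = MaxentWorkspace(MomentBasis.degree_graded(1, 10), StateSpace((0,), (150,)))
        G = ws.Q.T @ ws.Q / ws.n_states
        assert np.abs(G - np.eye(ws.M)).max() < 1e-8

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            MaxentWorkspace(MomentBasis.degree_graded(2, 2), StateSpace((0,), (9,)))
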