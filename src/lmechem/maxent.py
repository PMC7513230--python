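"""Maximum-entropy machinery: multipliers -> distribution -> moments.

The maxent distribution constrained by M moments has exponential-family form

    P(X) = exp( - sum_{j=0..M} lambda_j f_j(X) ),    f_0 = 1,

with the zeroth multiplier eliminated by normalization,

    lambda_0 = log sum_Omega exp( - sum_{j>=1} lambda_j f_j(X) ).

Moments, combined moments mu_{i,j} = E[f_i f_j] and the Jacobian identity

    d(mu_i)/d(lambda_j) = -mu_{i,j} + mu_i mu_j = -Cov(f_i, f_j)

are all evaluated by direct summation over the truncated state space.

Conditioning.  Raw monomials up to order ~10 on boxes of a few hundred
molecules give covariance matrices with astronomical condition numbers, so a
:class:`MaxentWorkspace` carries a second, numerically equivalent
representation of the same polynomial span: species counts are affinely
mapped to z in [-1, 1], monomials in z are centered and whitened (Cholesky of
their uniform-distribution Gram matrix), yielding functions g = T f + g0 that
are orthonormal under the uniform distribution on Omega.  Newton solves and
the multiplier ODEs operate on the g-representation; the raw-monomial lambda
and mu remain the public interface, related by the exact triangular linear
map T.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .moments import MomentBasis, evaluate_monomials
from .networks import StateSpace

__all__ = [
    "LagrangeState",
    "MaxentWorkspace",
    "MaxentNumericsError",
    "lambda0_from_lambdas",
    "distribution_from_lambda",
    "moments_from_lambda",
    "combined_moment",
    "jacobian",
    "shannon_entropy",
]


class MaxentNumericsError(FloatingPointError):
    """A maxent evaluation failed numerically (overflow/underflow/indefinite J)."""


@dataclass(frozen=True)
class LagrangeState:
    """Multiplier vector (raw monomial basis) plus the eliminated lambda_0."""

    lambdas: np.ndarray          # shape (M,), aligned with MomentBasis.active
    lambda0: float
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lambdas", np.asarray(self.lambdas, dtype=float))
        if not np.all(np.isfinite(self.lambdas)) or not np.isfinite(self.lambda0):
            raise ValueError("non-finite Lagrange multipliers")


def _zmonomial_expansion(exponents: Sequence[tuple[int, ...]],
                         center: np.ndarray, half: np.ndarray):
    """Exact coefficients of z^alpha = sum_beta C[alpha,beta] X^beta + c0[alpha],
    where z_s = (X_s - center_s)/half_s and beta ranges over ``exponents``."""
    pos = {e: i for i, e in enumerate(exponents)}
    M = len(exponents)
    C = np.zeros((M, M))
    c0 = np.zeros(M)
    for i, alpha in enumerate(exponents):
        scale = 1.0
        for s, a in enumerate(alpha):
            scale /= half[s] ** a
        for beta in itertools.product(*[range(a + 1) for a in alpha]):
            coeff = scale
            for s, (a, b) in enumerate(zip(alpha, beta)):
                coeff *= comb(a, b) * (-center[s]) ** (a - b)
            if sum(beta) == 0:
                c0[i] += coeff
            else:
                C[i, pos[beta]] += coeff
    return C, c0


class MaxentWorkspace:
    """Precomputed basis tables for one (basis, Omega) pair.

    Caches the raw monomial value table F, the orthonormalized table Q and
    the triangular map between the two representations.  Invalidate by
    constructing a new workspace whenever basis or Omega changes.
    """

    def __init__(self, basis: MomentBasis, omega: StateSpace):
        if basis.N != omega.N:
            raise ValueError("basis and state space dimensionality differ")
        self.basis = basis
        self.omega = omega
        self.states = omega.states()
        n = self.states.shape[0]
        if n <= basis.M:
            raise ValueError("state space smaller than the number of moments")
        self.F = evaluate_monomials(self.states, basis.active)          # (n, M)

        lo = np.array(omega.lower, dtype=float)
        hi = np.array(omega.upper, dtype=float)
        self._center = (lo + hi) / 2.0
        self._half = np.maximum((hi - lo) / 2.0, 1.0)
        Z = evaluate_monomials((self.states - self._center) / self._half,
                               [tuple(e) for e in basis.active])
        # Z columns are z-monomials; whiten under the uniform distribution.
        self._zmean = Z.mean(axis=0)
        Zc = Z - self._zmean
        G = Zc.T @ Zc / n
        jitter = 0.0
        for _ in range(6):
            try:
                self._L = cholesky(G + jitter * np.eye(basis.M), lower=True)
                break
            except np.linalg.LinAlgError:
                jitter = max(jitter * 100.0, 1e-14)
        else:
            raise MaxentNumericsError("could not factorize uniform Gram matrix")
        self.Q = solve_triangular(self._L, Zc.T, lower=True).T          # (n, M)

        C, c0 = _zmonomial_expansion(basis.active, self._center, self._half)
        # g = T f + g0 with T lower triangular in the graded basis order.
        self.T = solve_triangular(self._L, C, lower=True)
        self.g0 = solve_triangular(self._L, c0 - self._zmean, lower=True)
        self._ext_cache: dict = {}
        # scratch buffers for the hot per-step evaluations (large Omega)
        self._buf_w = np.empty(n)
        self._buf_nm = np.empty_like(self.Q)

    # -- representation conversions -------------------------------------
    @property
    def M(self) -> int:
        return self.basis.M

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    def lambda_raw(self, lam_tilde: np.ndarray) -> np.ndarray:
        return self.T.T @ np.asarray(lam_tilde, dtype=float)

    def lambda_tilde(self, lam_raw: np.ndarray) -> np.ndarray:
        return solve_triangular(self.T.T, np.asarray(lam_raw, dtype=float), lower=False)

    def mu_tilde_from_raw(self, mu_raw: np.ndarray) -> np.ndarray:
        return self.T @ np.asarray(mu_raw, dtype=float) + self.g0

    # -- evaluation in the orthonormal representation --------------------
    def tilde_log_weights(self, lam_tilde: np.ndarray) -> np.ndarray:
        return -(self.Q @ lam_tilde)

    def distribution_tilde(self, lam_tilde: np.ndarray) -> np.ndarray:
        w = self._buf_w
        np.matmul(self.Q, lam_tilde, out=w)
        np.negative(w, out=w)
        m = w.max()
        if not np.isfinite(m):
            raise MaxentNumericsError("non-finite exponent in maxent weights")
        w -= m
        P = np.exp(w)
        Z = P.sum()
        if not np.isfinite(Z) or Z <= 0.0:
            raise MaxentNumericsError("maxent normalization underflowed to zero")
        P /= Z
        return P

    def mu_tilde(self, P: np.ndarray) -> np.ndarray:
        return self.Q.T @ P

    def neg_jacobian_tilde(self, P: np.ndarray, mu_t: np.ndarray | None = None) -> np.ndarray:
        """Covariance matrix of the orthonormal basis functions under P (= -J).

        Formed from centered values, E[(g - E g)(g - E g)^T]: for sharply
        concentrated distributions the uncentered two-pass formula cancels
        catastrophically, and the small eigenvalues are exactly what the
        multiplier dynamics divide by.
        """
        if mu_t is None:
            mu_t = self.mu_tilde(P)
        Qc = np.subtract(self.Q, mu_t, out=self._buf_nm)
        return (Qc * P[:, None]).T @ Qc

    def solve_neg_jacobian(self, negJ: np.ndarray, b: np.ndarray,
                           rel_cutoff: float = 1e-13,
                           smooth: bool = False) -> np.ndarray:
        """Solve (-J) x = b by symmetric eigendecomposition.

        Eigenvalue directions far below the dominant one correspond to basis
        functions (nearly) linearly dependent on the effective support; they
        influence the distribution by the same small factor, but inverted
        verbatim they produce arbitrarily fast spurious dynamics.  With
        ``smooth=False`` eigenvalues below ``rel_cutoff * wmax`` get the
        minimal-norm solution 0 (a hard pseudo-inverse, right for Newton
        steps); with ``smooth=True`` a Tikhonov filter w/(w^2 + (c wmax)^2)
        damps them continuously, which an ODE right-hand side needs --- a
        hard threshold makes the vector field discontinuous whenever an
        eigenvalue drifts across it.  Raises if -J is not positive
        semidefinite (beyond roundoff).
        """
        w, V = np.linalg.eigh(negJ)
        wmax = float(w[-1])
        if not np.isfinite(wmax) or wmax <= 0.0:
            raise MaxentNumericsError("-J has no positive spectrum")
        if w[0] < -1e-8 * wmax:
            raise MaxentNumericsError("-J indefinite beyond roundoff")
        wc = np.maximum(w, 0.0)
        if smooth:
            reg = rel_cutoff * wmax
            winv = wc / (wc * wc + reg * reg)
        else:
            winv = np.where(w > rel_cutoff * wmax, 1.0 / np.maximum(wc, 1e-300), 0.0)
        return V @ (winv * (V.T @ b))

    def factorize_neg_jacobian(self, negJ: np.ndarray):
        """Cholesky of -J with additive jitter escalation; raises on failure.

        The jitter scale follows the matrix trace (a degenerate, nearly
        point-mass distribution makes -J vanish; the absolute floor keeps
        the escalation finite there).
        """
        base = max(float(np.trace(negJ)) / negJ.shape[0], 1e-300)
        jitter = 0.0
        for _ in range(5):
            try:
                return cho_factor(negJ + jitter * np.eye(negJ.shape[0]), lower=True)
            except np.linalg.LinAlgError:
                jitter = 1e-12 * base if jitter == 0.0 else jitter * 100.0
        raise MaxentNumericsError(
            "-J not positive definite even after jitter escalation")

    # -- raw-basis evaluation --------------------------------------------
    def log_weights_raw(self, lam_raw: np.ndarray) -> np.ndarray:
        return -(self.F @ np.asarray(lam_raw, dtype=float))

    def moments_raw(self, P: np.ndarray) -> np.ndarray:
        return self.F.T @ P

    def orthonormal_values_at(self, states: np.ndarray) -> np.ndarray:
        """Evaluate the orthonormalized basis functions g at arbitrary states.

        States may lie (slightly) outside Omega; the polynomials extend there.
        """
        Z = evaluate_monomials((np.asarray(states, dtype=float) - self._center) / self._half,
                               [tuple(e) for e in self.basis.active])
        return solve_triangular(self._L, (Z - self._zmean).T, lower=True).T

    def extended_values(self, exponents: tuple[tuple[int, ...], ...]) -> np.ndarray:
        """Value table of extra (higher-order) monomials over Omega, cached."""
        if exponents not in self._ext_cache:
            self._ext_cache[exponents] = evaluate_monomials(self.states, exponents)
        return self._ext_cache[exponents]


# ---------------------------------------------------------------------------
# Public raw-basis operations
# ---------------------------------------------------------------------------

def _as_lambdas(state) -> np.ndarray:
    if isinstance(state, LagrangeState):
        return state.lambdas
    return np.asarray(state, dtype=float)


def lambda0_from_lambdas(lambdas, ws: MaxentWorkspace) -> float:
    """Normalizing multiplier lambda_0 = log sum_Omega exp(-sum_j lambda_j f_j)."""
    w = ws.log_weights_raw(_as_lambdas(lambdas))
    if not np.all(np.isfinite(w)):
        raise MaxentNumericsError("non-finite exponent (pathological lambda)")
    m = w.max()
    s = np.exp(w - m).sum()
    if not np.isfinite(s) or s <= 0.0:
        raise MaxentNumericsError("normalization sum underflowed")
    return float(m + np.log(s))


def distribution_from_lambda(state, ws: MaxentWorkspace) -> np.ndarray:
    """Probability table P(X) = exp(-sum_{j>=0} lambda_j f_j(X)), normalized."""
    w = ws.log_weights_raw(_as_lambdas(state))
    m = w.max()
    if not np.isfinite(m):
        raise MaxentNumericsError("non-finite exponent (pathological lambda)")
    P = np.exp(w - m)
    Z = P.sum()
    if Z <= 0.0 or not np.isfinite(Z):
        raise MaxentNumericsError("distribution underflowed to an all-zero table")
    return P / Z


def moments_from_lambda(state, ws: MaxentWorkspace) -> np.ndarray:
    """mu_i = E[f_i] under the maxent distribution of the given multipliers."""
    return ws.moments_raw(distribution_from_lambda(state, ws))


def combined_moment(state, i: int, j: int, ws: MaxentWorkspace) -> float:
    """mu_{i,j} = E[f_i f_j]; indices 0..M with f_0 = 1."""
    M = ws.M
    if not (0 <= i <= M and 0 <= j <= M):
        raise IndexError(f"combined-moment index out of range 0..{M}")
    P = distribution_from_lambda(state, ws)
    fi = np.ones(ws.n_states) if i == 0 else ws.F[:, i - 1]
    fj = np.ones(ws.n_states) if j == 0 else ws.F[:, j - 1]
    return float(np.sum(fi * fj * P))


def jacobian(state, ws: MaxentWorkspace) -> np.ndarray:
    """J_ij = d(mu_i)/d(lambda_j) = -mu_{i,j} + mu_i mu_j (raw monomial basis)."""
    P = distribution_from_lambda(state, ws)
    mu = ws.moments_raw(P)
    S = (ws.F * P[:, None]).T @ ws.F
    return -(S - np.outer(mu, mu))


def shannon_entropy(P: np.ndarray) -> float:
    """Shannon entropy -sum P log P in nats, with 0 log 0 := 0."""
    P = np.asarray(P, dtype=float)
    nz = P > 0.0
    return float(-np.sum(P[nz] * np.log(P[nz])))
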