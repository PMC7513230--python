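"""Moment bases, moment equations and their brute-force oracle.

The package works internally with raw monomial moments mu_alpha = E[prod_s X_s^alpha_s]
over a degree-graded basis; factorial moments {X^(a)} = E[prod_s ff(X_s, a_s)]
(ff = falling factorial) are an exactly invertible triangular reporting
conversion via Stirling numbers.

For any mass-action network the monomial moments obey a linear ODE system

    d(mu)/dt = A mu + A' mu' + mu_c,

where mu collects basis moments of total degree 1..k and mu' whatever
higher-degree monomials the reactions couple in.  The matrices are derived
symbolically (exact integer arithmetic per reaction, scaled by the float rate
constants) by expanding, for every basis monomial f,

    sum_r a_r(X) * [f(X + nu_r) - f(X)]

into monomials.  :func:`moment_rhs_direct` evaluates the same generator
expectation state-by-state against an explicit probability table and serves as
an independent oracle: the two agree as a polynomial identity.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import sympy
from sympy.functions.combinatorial.numbers import stirling

from .networks import ReactionNetwork, StateSpace, propensity_table

__all__ = [
    "MomentBasis",
    "MomentODESystem",
    "basis_size",
    "evaluate_monomials",
    "moments_from_distribution",
    "monomial_to_factorial",
    "factorial_to_monomial",
    "derive_moment_equations",
    "moment_rhs_direct",
]


def basis_size(N: int, k: int) -> int:
    """Number M of moments up to total degree k for N species (zeroth excluded)."""
    if N < 1 or k < 1:
        raise ValueError("need N >= 1 and k >= 1")
    return comb(N + k, k) - 1


def _graded_exponents(N: int, k: int) -> list[tuple[int, ...]]:
    out: list[tuple[int, ...]] = []
    for deg in range(k + 1):
        level = [e for e in itertools.product(range(deg + 1), repeat=N) if sum(e) == deg]
        out.extend(sorted(level))
    return out


@dataclass(frozen=True)
class MomentBasis:
    """Degree-graded monomial basis: the all-zero index first, then ascending
    total degree with lexicographic tie-break on the exponent tuples."""

    exponents: tuple[tuple[int, ...], ...]
    closure_order: int

    @classmethod
    def degree_graded(cls, N: int, k: int) -> "MomentBasis":
        return cls(tuple(_graded_exponents(N, k)), k)

    def __post_init__(self) -> None:
        if not self.exponents or any(sum(e) == 0 for e in self.exponents[1:]) \
                or sum(self.exponents[0]) != 0:
            raise ValueError("basis must start with the zero multi-index, once")
        if len(set(self.exponents)) != len(self.exponents):
            raise ValueError("duplicate basis exponents")

    @property
    def N(self) -> int:
        return len(self.exponents[0])

    @property
    def M(self) -> int:
        """Moment count excluding the zeroth entry."""
        return len(self.exponents) - 1

    @property
    def active(self) -> tuple[tuple[int, ...], ...]:
        """Exponents 1..M (the constrained moments)."""
        return self.exponents[1:]

    def index(self, e: tuple[int, ...]) -> int:
        """Position of exponent ``e`` among the active entries (0-based)."""
        return self.active.index(e)


def evaluate_monomials(states: np.ndarray, exponents: Sequence[tuple[int, ...]]) -> np.ndarray:
    """(n_states, len(exponents)) table of prod_s X_s^e_s, in float64."""
    S = np.asarray(states, dtype=float)
    out = np.empty((S.shape[0], len(exponents)))
    for j, e in enumerate(exponents):
        col = np.ones(S.shape[0])
        for s, a in enumerate(e):
            if a:
                col = col * S[:, s] ** a
        out[:, j] = col
    return out


def moments_from_distribution(P: np.ndarray, basis: MomentBasis, omega: StateSpace,
                              check: bool = True) -> np.ndarray:
    """Active moments mu_i = sum_Omega f_i(X) P(X), i = 1..M."""
    P = np.asarray(P, dtype=float)
    if P.shape != (omega.n_states,):
        raise ValueError(f"P has shape {P.shape}, expected ({omega.n_states},)")
    if check:
        if np.any(P < -1e-12):
            raise ValueError("probability table has negative entries")
        if abs(P.sum() - 1.0) > 1e-8:
            raise ValueError(f"probability table sums to {P.sum()}, not 1")
    F = evaluate_monomials(omega.states(), basis.active)
    return F.T @ P


# ---------------------------------------------------------------------------
# Monomial <-> factorial conversion (triangular, Stirling numbers)
# ---------------------------------------------------------------------------

def _conversion_matrix(basis: MomentBasis, kind: int) -> np.ndarray:
    """Matrix C with factorial = C @ monomial (kind=1) or its inverse (kind=2).

    kind=1 uses signed Stirling numbers of the first kind
    (ff(x, n) = sum_k s(n, k) x^k); kind=2 the second kind.
    """
    act = basis.active
    pos = {e: i for i, e in enumerate(act)}
    M = basis.M
    C = np.zeros((M, M))
    for i, alpha in enumerate(act):
        ranges = [range(a + 1) for a in alpha]
        for beta in itertools.product(*ranges):
            if sum(beta) == 0:
                continue  # ff products have no constant term for alpha != 0
            coeff = 1
            for a, b in zip(alpha, beta):
                coeff *= int(stirling(a, b, kind=kind, signed=(kind == 1)))
            if coeff == 0:
                continue
            j = pos.get(beta)
            if j is None:
                raise ValueError(f"basis lacks prerequisite monomial {beta} for {alpha}")
            C[i, j] += coeff
    return C


def monomial_to_factorial(mu: np.ndarray, basis: MomentBasis) -> np.ndarray:
    """Convert active monomial moments to factorial moments {X^(a)}."""
    mu = np.asarray(mu, dtype=float)
    return _conversion_matrix(basis, kind=1) @ mu


def factorial_to_monomial(mu_fact: np.ndarray, basis: MomentBasis) -> np.ndarray:
    """Inverse of :func:`monomial_to_factorial` (exact triangular identity)."""
    mu_fact = np.asarray(mu_fact, dtype=float)
    return _conversion_matrix(basis, kind=2) @ mu_fact


# ---------------------------------------------------------------------------
# Symbolic moment equations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MomentODESystem:
    """d(mu)/dt = A mu + A' mu' + mu_c over a fixed basis.

    ``higher_exponents`` lists the multi-indices of mu' (total degree above
    the closure order) in degree-graded order; it may be empty for networks
    whose moment equations close (all reactions of order <= 1).
    """

    basis: MomentBasis
    A: np.ndarray
    A_prime: np.ndarray
    mu_c: np.ndarray
    higher_exponents: tuple[tuple[int, ...], ...]

    @property
    def M(self) -> int:
        return self.basis.M

    @property
    def M_prime(self) -> int:
        return len(self.higher_exponents)

    def rhs(self, mu: np.ndarray, mu_prime: np.ndarray | None = None) -> np.ndarray:
        out = self.A @ mu + self.mu_c
        if self.M_prime:
            if mu_prime is None:
                raise ValueError("system has higher-order terms; mu_prime required")
            out = out + self.A_prime @ mu_prime
        return out

    def to_json(self) -> str:
        """Serializable bundle of the matrices and the basis layout."""
        return json.dumps({
            "closure_order": self.basis.closure_order,
            "basis_exponents": [list(e) for e in self.basis.active],
            "higher_exponents": [list(e) for e in self.higher_exponents],
            "A": self.A.tolist(),
            "A_prime": self.A_prime.tolist(),
            "mu_c": self.mu_c.tolist(),
        }, indent=1)


def _reaction_polynomials(network: ReactionNetwork, basis: MomentBasis):
    """Per-reaction exact expansion of sum_i a_r(X) [f_i(X+nu)-f_i(X)].

    Returns, for each reaction, a list over basis rows of {exponent: int coeff}
    dictionaries (rate constant NOT included).
    """
    N = network.N
    xs = sympy.symbols(f"x0:{N}", integer=True)
    per_reaction = []
    for rx in network.reactions:
        prop = sympy.Integer(1)
        for s, m in enumerate(rx.reactant_stoich):
            if m:
                prop *= sympy.ff(xs[s], m)
        nu = rx.net_change
        rows = []
        for alpha in basis.active:
            f_here = sympy.Integer(1)
            f_shift = sympy.Integer(1)
            for s, a in enumerate(alpha):
                if a:
                    f_here *= xs[s] ** a
                    f_shift *= (xs[s] + nu[s]) ** a
            poly = sympy.Poly(sympy.expand(prop * (f_shift - f_here)), *xs, domain="ZZ")
            rows.append({tuple(int(m) for m in mon): int(c)
                         for mon, c in zip(poly.monoms(), poly.coeffs())})
        per_reaction.append(rows)
    return per_reaction


def derive_moment_equations(network: ReactionNetwork, basis: MomentBasis) -> MomentODESystem:
    """Build the exact moment-equation matrices for ``network`` over ``basis``."""
    if basis.N != network.N:
        raise ValueError("basis and network species counts differ")
    M = basis.M
    k = basis.closure_order
    pos = {e: i for i, e in enumerate(basis.active)}
    rates = network.rate_constants()
    per_reaction = _reaction_polynomials(network, basis)

    higher: dict[tuple[int, ...], int] = {}
    for rows in per_reaction:
        for row in rows:
            for e in row:
                if sum(e) > k and e not in higher:
                    higher[e] = -1
    higher_exps = sorted(higher, key=lambda e: (sum(e), e))
    hpos = {e: j for j, e in enumerate(higher_exps)}

    A = np.zeros((M, M))
    A_prime = np.zeros((M, len(higher_exps)))
    mu_c = np.zeros(M)
    for rate, rows in zip(rates, per_reaction):
        for i, row in enumerate(rows):
            for e, coeff in row.items():
                val = float(coeff) * rate
                deg = sum(e)
                if deg == 0:
                    mu_c[i] += val
                elif deg <= k:
                    A[i, pos[e]] += val
                else:
                    A_prime[i, hpos[e]] += val
    return MomentODESystem(basis, A, A_prime, mu_c, tuple(higher_exps))


def moment_rhs_direct(network: ReactionNetwork, P: np.ndarray, basis: MomentBasis,
                      omega: StateSpace) -> np.ndarray:
    """Brute-force generator expectation d(mu_i)/dt = E_P[a_r(X)(f_i(X+nu)-f_i(X))].

    Independent of :func:`derive_moment_equations`; equals its matrix form for
    any probability table (polynomial identity on the untruncated lattice,
    with basis polynomials evaluated wherever X+nu lands).
    """
    P = np.asarray(P, dtype=float)
    if P.shape != (omega.n_states,):
        raise ValueError("P / Omega shape mismatch")
    S = omega.states()
    F = evaluate_monomials(S, basis.active)
    a = propensity_table(network, S)
    out = np.zeros(basis.M)
    for r, rx in enumerate(network.reactions):
        nu = np.array(rx.net_change, dtype=np.int64)
        F_shift = evaluate_monomials(S + nu, basis.active)
        out += (a[:, r] * P) @ (F_shift - F)
    return out
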