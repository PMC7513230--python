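"""Time integration of the Lagrange multiplier equations (LMEs).

Assuming the distribution stays maximum-entropy at all times, the multipliers
obey the closed ODE system

    J(lambda) d(lambda)/dt = d(mu)/dt = A mu + A' mu' + mu_c,

with J the moment/multiplier Jacobian (-J is the basis-function covariance).
Each right-hand-side evaluation materializes P from lambda, forms d(mu)/dt,
and solves the linear system through a symmetric eigendecomposition of -J
(the basis-function covariance; directions degenerate on the effective
support get the minimal-norm solution) -- never an explicit inverse.
lambda_0 is not integrated: it is recovered
algebraically from the normalization identity whenever a state is emitted, so
sum P = 1 holds exactly by construction.

Two equivalent routes compute d(mu)/dt:

* ``direct`` (default): a precomputed generator-action table
  D[x, i] = sum_r a_r(x) (g_i(x + nu_r) - g_i(x)) over the orthonormalized
  basis gives d(mu~)/dt = D^T P with every intermediate of order unity.
* ``matrix``: the symbolically derived (A, A', mu_c) system evaluated on raw
  moments and mapped into the orthonormal coordinates.  Raw moments of high
  order are astronomically large and the mapping cancels them, so this route
  loses relative precision at high closure order; it is retained as an exact
  polynomial-identity cross-check and is the natural choice at low order.

The integrator is the Dormand-Prince RK5(4)7M embedded pair with standard
mixed absolute/relative per-component error control and step-size selection
h <- h * clip(safety * err^(-1/5), min_shrink, max_growth); output points are
hit by shortening steps.  A failed -J factorization inside a trial step is
treated as a step rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .maxent import (LagrangeState, MaxentNumericsError, MaxentWorkspace,
                     lambda0_from_lambdas)
from .moments import MomentODESystem, derive_moment_equations, moments_from_distribution
from .networks import ReactionNetwork, StateSpace, propensity_table

__all__ = [
    "SolverConfig",
    "LMETrajectory",
    "build_generator_action",
    "build_cme_generator",
    "evolve_distribution",
    "lme_rhs",
    "integrate",
    "steady_state_oracle",
]


@dataclass(frozen=True)
class SolverConfig:
    output_times: tuple[float, ...]
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    h_init: float = 1e-4
    h_min: float = 1e-13
    h_max: float = np.inf
    safety: float = 0.9
    min_shrink: float = 0.2
    max_growth: float = 5.0
    # Tikhonov scale (relative to the dominant eigenvalue) of the smooth
    # spectral filter in the -J solve; near-degenerate covariance
    # directions influence the distribution by O(cutoff) but, inverted
    # verbatim, would inject arbitrarily fast spurious modes
    j_cutoff: float = 1e-9

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not (self.h_min <= self.h_init <= self.h_max):
            raise ValueError("need h_min <= h_init <= h_max")
        times = tuple(float(t) for t in self.output_times)
        if len(times) == 0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("output_times must be nonempty and strictly increasing")
        object.__setattr__(self, "output_times", times)


@dataclass
class LMETrajectory:
    """LME solution sampled on the output grid (raw-basis states and moments)."""

    times: np.ndarray
    states: list[LagrangeState]
    moments: np.ndarray                       # (T, M) raw monomial moments
    distributions: np.ndarray | None          # (T, n_states) if stored
    n_accepted: int
    n_rejected: int

    def to_tsv(self) -> str:
        M = self.moments.shape[1]
        header = ["time", "lambda_0"] + [f"lambda_{i}" for i in range(1, M + 1)] \
            + [f"mu_{i}" for i in range(1, M + 1)]
        lines = ["\t".join(header)]
        for t, st, mu in zip(self.times, self.states, self.moments):
            row = [f"{t:.10g}", f"{st.lambda0:.10g}"]
            row += [f"{v:.10g}" for v in st.lambdas]
            row += [f"{v:.10g}" for v in mu]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def build_generator_action(ws: MaxentWorkspace, network: ReactionNetwork) -> np.ndarray:
    """(n_states, M) table D with D[x, i] = sum_r a_r(x) (g_i(x+nu_r) - g_i(x)).

    d(mu~)/dt = D^T P for the orthonormalized moments mu~; time-independent,
    so it is computed once per (network, workspace).
    """
    S = ws.states
    a = propensity_table(network, S)
    D = np.zeros_like(ws.Q)
    for r, rx in enumerate(network.reactions):
        nu = np.array(rx.net_change, dtype=np.int64)
        Q_shift = ws.orthonormal_values_at(S + nu)
        D += a[:, r, None] * (Q_shift - ws.Q)
    return D


class _TildeRHS:
    """d(lambda~)/dt evaluator in the orthonormalized representation."""

    def __init__(self, ws: MaxentWorkspace, network: ReactionNetwork,
                 system: MomentODESystem | None = None, method: str = "direct",
                 j_cutoff: float = 1e-10):
        if method not in ("direct", "matrix"):
            raise ValueError("method must be 'direct' or 'matrix'")
        self.ws = ws
        self.method = method
        self.j_cutoff = j_cutoff
        if method == "direct":
            self.D = build_generator_action(ws, network)
            self.system = system
        else:
            self.system = system if system is not None \
                else derive_moment_equations(network, ws.basis)

    def dmu_tilde(self, P: np.ndarray) -> np.ndarray:
        if self.method == "direct":
            return self.D.T @ P
        sysm = self.system
        mu = self.ws.moments_raw(P)
        mu_p = self.ws.extended_values(sysm.higher_exponents).T @ P if sysm.M_prime else None
        return self.ws.T @ sysm.rhs(mu, mu_p)

    def __call__(self, lam_tilde: np.ndarray) -> np.ndarray:
        ws = self.ws
        P = ws.distribution_tilde(lam_tilde)
        mu_t = ws.mu_tilde(P)
        negJ = ws.neg_jacobian_tilde(P, mu_t)
        dmu_t = self.dmu_tilde(P)
        dlam = -ws.solve_neg_jacobian(negJ, dmu_t, rel_cutoff=self.j_cutoff,
                                      smooth=True)
        if not np.all(np.isfinite(dlam)):
            raise MaxentNumericsError("non-finite LME right-hand side")
        return dlam


def lme_rhs(state: LagrangeState, system: MomentODESystem, ws: MaxentWorkspace,
            network: ReactionNetwork | None = None, method: str = "matrix",
            with_lambda0_rate: bool = False):
    """d(lambda)/dt in the raw monomial basis for a single state.

    Uses the (A, A', mu_c) matrix route by default; ``method='direct'``
    switches to the generator-action route (requires ``network``).  With
    ``with_lambda0_rate`` the normalization-consistency diagnostic
    d(lambda_0)/dt = -sum_j mu_j d(lambda_j)/dt is returned as well.
    """
    if method == "direct" and network is None:
        raise ValueError("direct method needs the network")
    rhs = _TildeRHS(ws, network, system=system, method=method)
    dlt = rhs(ws.lambda_tilde(state.lambdas))
    dlam_raw = ws.T.T @ dlt
    if not with_lambda0_rate:
        return dlam_raw
    mu = ws.moments_raw(ws.distribution_tilde(ws.lambda_tilde(state.lambdas)))
    return dlam_raw, float(-mu @ dlam_raw)


# Dormand-Prince RK5(4)7M tableau.
_DP_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = [
    [],
    [1 / 5],
    [3 / 40, 9 / 40],
    [44 / 45, -56 / 15, 32 / 9],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656],
    [35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84],
]
_DP_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_DP_B4 = np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640,
                   -92097 / 339200, 187 / 2100, 1 / 40])
_DP_E = _DP_B5 - _DP_B4


def integrate(initial: LagrangeState, network: ReactionNetwork, ws: MaxentWorkspace,
              config: SolverConfig, method: str = "direct",
              system: MomentODESystem | None = None,
              store_distributions: bool = False) -> LMETrajectory:
    """Integrate the LMEs from ``initial.time`` through ``config.output_times``."""
    rhs = _TildeRHS(ws, network, system=system, method=method,
                    j_cutoff=config.j_cutoff)
    t = float(initial.time)
    outs = [ot for ot in config.output_times if ot >= t - 1e-15]
    if not outs:
        raise ValueError("all output times precede the initial time")
    y = ws.lambda_tilde(initial.lambdas)

    times: list[float] = []
    states: list[LagrangeState] = []
    moments: list[np.ndarray] = []
    dists: list[np.ndarray] = []

    def emit(t_now: float, y_now: np.ndarray) -> None:
        lam_raw = ws.lambda_raw(y_now)
        st = LagrangeState(lam_raw, lambda0_from_lambdas(lam_raw, ws), time=t_now)
        P = ws.distribution_tilde(y_now)
        times.append(t_now)
        states.append(st)
        moments.append(ws.moments_raw(P))
        if store_distributions:
            dists.append(P)

    i_out = 0
    if abs(outs[0] - t) <= 1e-15:
        emit(t, y)
        i_out = 1

    n_acc = n_rej = 0
    h_ctrl = min(config.h_init, config.h_max)
    f = rhs(y)
    K = np.empty((7, y.size))
    A_rows = [np.array(row) for row in _DP_A]
    while i_out < len(outs):
        t_target = outs[i_out]
        failed_here = 0
        while True:
            h = min(h_ctrl, t_target - t)
            clipped = h < h_ctrl
            if t + h == t:
                raise RuntimeError(f"LME step size stagnated at t={t:.6g} "
                                   f"({n_acc} accepted / {n_rej} rejected steps)")
            try:
                K[0] = f
                for s in range(1, 7):
                    ys = y + h * (A_rows[s] @ K[:s])
                    K[s] = rhs(ys)
                y_new = y + h * (_DP_B5 @ K)
                err_vec = h * (_DP_E @ K)
                scale = config.abs_tol + config.rel_tol * np.maximum(np.abs(y), np.abs(y_new))
                err = float(np.sqrt(np.mean((err_vec / scale) ** 2)))
            except MaxentNumericsError:
                err = np.inf
            if err <= 1.0:
                n_acc += 1
                t = t + h
                y = y_new
                f = K[6]  # FSAL
                factor = config.max_growth if err == 0.0 else \
                    min(config.max_growth, max(config.min_shrink,
                                               config.safety * err ** -0.2))
                # Do not let a clipped (output-hitting) step shrink the controller.
                h_ctrl = min(max(h * factor, h_ctrl if clipped else 0.0), config.h_max)
                break
            n_rej += 1
            failed_here += 1
            factor = config.min_shrink if not np.isfinite(err) else \
                max(config.min_shrink, config.safety * err ** -0.2)
            h_ctrl = h * min(factor, 0.5)
            if h_ctrl < config.h_min or failed_here > 60:
                raise RuntimeError(
                    f"LME step size underflow at t={t:.6g} (h={h_ctrl:.3g}, "
                    f"{n_acc} accepted / {n_rej} rejected steps)")
        if t >= t_target - 1e-12 * max(1.0, abs(t_target)):
            t = t_target
            emit(t, y)
            i_out += 1

    return LMETrajectory(np.array(times), states, np.array(moments),
                         np.array(dists) if store_distributions else None,
                         n_acc, n_rej)


def build_cme_generator(network: ReactionNetwork, omega: StateSpace) -> sp.csr_matrix:
    """Sparse truncated-CME generator on Omega with reflecting boundary.

    Transitions that would leave the box have their propensity set to zero
    (no outflow), conserving probability on Omega.  dP/dt = Q P.
    """
    S = omega.states()
    n = S.shape[0]
    idx = np.arange(n)
    a = propensity_table(network, S)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    data: list[np.ndarray] = []
    for r, rx in enumerate(network.reactions):
        nu = np.array(rx.net_change, dtype=np.int64)
        target = S + nu
        ok = omega.contains(target) & (a[:, r] > 0)
        tgt = omega.ravel_index(target[ok])
        rows.append(tgt)
        cols.append(idx[ok])
        data.append(a[ok, r])
        rows.append(idx[ok])
        cols.append(idx[ok])
        data.append(-a[ok, r])
    return sp.csr_matrix((np.concatenate(data),
                          (np.concatenate(rows), np.concatenate(cols))),
                         shape=(n, n))


def evolve_distribution(network: ReactionNetwork, omega: StateSpace,
                        P0: np.ndarray, t: float) -> np.ndarray:
    """Exact truncated-CME evolution of a probability table by time ``t``.

    Matrix-exponential action of the generator; the deterministic limit of
    an SSA burn-in from the same initial table.
    """
    P0 = np.asarray(P0, dtype=float)
    if P0.shape != (omega.n_states,):
        raise ValueError("P0 / Omega shape mismatch")
    if t == 0.0:
        return P0.copy()
    Q = build_cme_generator(network, omega)
    P = spla.expm_multiply(Q * t, P0)
    P = np.maximum(P, 0.0)
    return P / P.sum()


def steady_state_oracle(network: ReactionNetwork, omega: StateSpace) -> np.ndarray:
    """Stationary distribution of the truncated CME on Omega (reflecting boundary).

    Returns the normalized solution of Q p = 0; an independent validation
    oracle for the long-time LME solution.
    """
    n = omega.n_states
    Q = build_cme_generator(network, omega)
    # Replace one balance row with the normalization constraint.
    A = sp.vstack([Q[:-1, :], sp.csr_matrix(np.ones((1, n)))]).tocsc()
    b = np.zeros(n)
    b[-1] = 1.0
    p = spla.spsolve(A, b)
    resid = np.abs(Q @ p).max()
    if not np.all(np.isfinite(p)) or p.min() < -1e-9 or resid > 1e-8 * max(1.0, np.abs(Q).max()):
        raise RuntimeError("stationary solve failed (disconnected chain or "
                           f"non-unique nullspace; residual {resid:.3g})")
    p = np.maximum(p, 0.0)
    return p / p.sum()
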