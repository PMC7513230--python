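"""Initial multipliers from known moments: damped Newton on G(lambda) - mu = 0.

The map G takes multipliers to the moments of their maxent distribution; its
Jacobian is the negated basis-function covariance, so every Newton linear
solve is a symmetric positive-definite factorization of -J.  Iterations run
in the workspace's orthonormalized representation (see :mod:`lmechem.maxent`)
where -J is well conditioned; the fitted multipliers are reported in the raw
monomial basis.

Residuals are measured in the orthonormalized moment coordinates (second
norm); because the basis functions have unit scale under the uniform
distribution, the default tolerance 1e-9 means "moments matched to ~1e-9 of
a basis-function standard deviation" uniformly across moment orders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maxent import LagrangeState, MaxentNumericsError, MaxentWorkspace, lambda0_from_lambdas
from .moments import MomentBasis
from .networks import StateSpace

__all__ = ["FitResult", "fit_lambda_from_moments", "extend_closure", "fit_lambda_ladder"]

_BACKTRACK_FLOOR = 1e-4


@dataclass(frozen=True)
class FitResult:
    state: LagrangeState
    residual_norm: float
    iterations: int
    converged: bool


def _residual(ws: MaxentWorkspace, lam_tilde: np.ndarray, mu_t_target: np.ndarray):
    P = ws.distribution_tilde(lam_tilde)
    mu_t = ws.mu_tilde(P)
    return mu_t - mu_t_target, P, mu_t


def fit_lambda_from_moments(mu_target: np.ndarray, ws: MaxentWorkspace,
                            initial_guess: np.ndarray | None = None,
                            tol: float = 1e-9, max_iter: int = 200) -> FitResult:
    """Newton-Raphson solve of G(lambda) = mu_target with backtracking damping.

    ``mu_target`` are raw monomial moments aligned with the workspace basis;
    ``initial_guess`` (raw lambdas) defaults to zero, i.e. the uniform
    distribution.  Non-convergence returns the best iterate with
    ``converged=False``; an infeasible target typically manifests as
    diverging multipliers and is reported the same way.
    """
    mu_target = np.asarray(mu_target, dtype=float)
    if mu_target.shape != (ws.M,):
        raise ValueError(f"target moment vector must have length {ws.M}")
    mu_t_target = ws.mu_tilde_from_raw(mu_target)

    lt = np.zeros(ws.M) if initial_guess is None else ws.lambda_tilde(initial_guess)
    r, P, mu_t = _residual(ws, lt, mu_t_target)
    rnorm = float(np.linalg.norm(r))
    best = (lt.copy(), rnorm)
    iterations = 0
    converged = rnorm <= tol
    while not converged and iterations < max_iter:
        iterations += 1
        negJ = ws.neg_jacobian_tilde(P, mu_t)
        try:
            # Newton direction: lambda <- lambda - J^{-1} r = lambda + (-J)^{-1} r
            step = ws.solve_neg_jacobian(negJ, r)
        except MaxentNumericsError:
            break
        alpha = 1.0
        accepted = False
        while alpha >= _BACKTRACK_FLOOR:
            try:
                r_new, P_new, mu_t_new = _residual(ws, lt + alpha * step, mu_t_target)
            except MaxentNumericsError:
                alpha *= 0.5
                continue
            rnorm_new = float(np.linalg.norm(r_new))
            if rnorm_new < rnorm:
                lt = lt + alpha * step
                r, P, mu_t, rnorm = r_new, P_new, mu_t_new, rnorm_new
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        if rnorm < best[1]:
            best = (lt.copy(), rnorm)
        converged = rnorm <= tol

    lt, rnorm = best if best[1] < rnorm else (lt, rnorm)
    lam_raw = ws.lambda_raw(lt)
    state = LagrangeState(lam_raw, lambda0_from_lambdas(lam_raw, ws))
    return FitResult(state, rnorm, iterations, converged)


def _pad_lambdas(lam_low: np.ndarray, basis_low: MomentBasis, basis_high: MomentBasis) -> np.ndarray:
    if basis_high.active[:basis_low.M] != basis_low.active:
        raise ValueError("low-order basis is not a prefix of the high-order basis")
    out = np.zeros(basis_high.M)
    out[:basis_low.M] = lam_low
    return out


def extend_closure(fit_low: FitResult, basis_low: MomentBasis, mu_target_low: np.ndarray,
                   ws_high: MaxentWorkspace, tol: float = 1e-9,
                   max_iter: int = 200) -> FitResult:
    """Extend a converged order-k fit to a higher closure order k'.

    The order-k' Newton solve starts from the order-k multipliers padded with
    zeros; the higher-order targets are the moments of the order-k maxent
    distribution itself (a maxent-consistent extension), so the lower moments
    of the result still match ``mu_target_low``.
    """
    mu_target_low = np.asarray(mu_target_low, dtype=float)
    lam0_padded = _pad_lambdas(fit_low.state.lambdas, basis_low, ws_high.basis)
    # Padding leaves the distribution unchanged, so its own moments supply
    # the higher-order targets.
    P = ws_high.distribution_tilde(ws_high.lambda_tilde(lam0_padded))
    mu_full = ws_high.moments_raw(P)
    target = mu_full.copy()
    target[:basis_low.M] = mu_target_low
    return fit_lambda_from_moments(target, ws_high, initial_guess=lam0_padded,
                                   tol=tol, max_iter=max_iter)


def fit_lambda_ladder(mu_target: np.ndarray, ws: MaxentWorkspace,
                      orders: list[int] | None = None, tol: float = 1e-9,
                      max_iter: int = 200) -> FitResult:
    """Fit a high-order target by laddering through intermediate closure orders.

    Undamped Newton from the uniform guess is fragile for high-order bases;
    fitting order 2 first and re-using each fit (zero-padded) as the next
    initial guess keeps every solve in the Newton basin.  ``mu_target`` is the
    full raw moment vector for the workspace basis; intermediate targets are
    its degree-truncated prefixes.
    """
    mu_target = np.asarray(mu_target, dtype=float)
    k_final = ws.basis.closure_order
    if orders is None:
        orders = list(range(2, k_final + 1, 2))
        if not orders or orders[-1] != k_final:
            orders.append(k_final)
    if orders[-1] != k_final:
        raise ValueError("ladder must end at the workspace closure order")

    guess: np.ndarray | None = None
    basis_prev: MomentBasis | None = None
    result: FitResult | None = None
    for k in orders:
        if k == k_final:
            ws_k, basis_k = ws, ws.basis
        else:
            basis_k = MomentBasis.degree_graded(ws.basis.N, k)
            ws_k = MaxentWorkspace(basis_k, ws.omega)
        target_k = mu_target[:basis_k.M]
        if result is not None:
            guess = _pad_lambdas(result.state.lambdas, basis_prev, basis_k)
        result = fit_lambda_from_moments(target_k, ws_k, initial_guess=guess,
                                         tol=tol, max_iter=max_iter)
        basis_prev = basis_k
    assert result is not None
    return result
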