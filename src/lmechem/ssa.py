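"""Gillespie direct-method ensemble simulator (exact SSA baseline).

At each event the waiting time is exponential with rate a0 = sum_r a_r(X) and
the firing reaction is chosen with probability a_r/a0.  Trajectories are
exact samples of the chemical master equation on the *untruncated* lattice;
only histogramming clips states to the finite box Omega, with an overflow
counter quantifying how much probability the truncation misses.

Reproducibility: every trajectory runs on its own RNG substream whose seed is
derived from the master seed with a splitmix64 counter hash, so results are
identical regardless of how trajectories are batched or ordered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .moments import MomentBasis, monomial_to_factorial
from .networks import ReactionNetwork, StateSpace

__all__ = ["SSAConfig", "EnsembleSummary", "simulate_ensemble", "make_initial_condition"]


@dataclass(frozen=True)
class SSAConfig:
    n_trajectories: int
    seed: int
    output_times: tuple[float, ...]
    initial_state: tuple[int, ...] | None = None
    initial_distribution: np.ndarray | None = None   # sampled over Omega

    def __post_init__(self) -> None:
        if self.n_trajectories < 1:
            raise ValueError("need at least one trajectory")
        times = tuple(float(t) for t in self.output_times)
        if any(t < 0 for t in times) or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("output_times must be nonnegative and strictly increasing")
        object.__setattr__(self, "output_times", times)
        if (self.initial_state is None) == (self.initial_distribution is None):
            raise ValueError("specify exactly one of initial_state / initial_distribution")


def _substream_seeds(master: int, n: int) -> np.ndarray:
    """splitmix64 hash of (master, trajectory index) -> 31-bit stream seeds."""
    idx = np.arange(1, n + 1, dtype=np.uint64)
    with np.errstate(over="ignore"):
        x = np.uint64(master & 0xFFFFFFFFFFFFFFFF) + np.uint64(0x9E3779B97F4A7C15) * idx
        z = x
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
    return (z & np.uint64(0x7FFFFFFF)).astype(np.int64)


@njit(cache=True, fastmath=True)
def _ssa_kernel(reactant, net_change, rates, init_states, out_times, seeds,
                lower, upper, strides, expmat,
                counts, overflow, msum, msumsq):  # pragma: no cover - jitted
    n_traj, N = init_states.shape
    R = reactant.shape[0]
    T = out_times.shape[0]
    K = expmat.shape[0]
    props = np.empty(R)
    x = np.empty(N, dtype=np.int64)
    for i in range(n_traj):
        np.random.seed(seeds[i])
        for s in range(N):
            x[s] = init_states[i, s]
        t = 0.0
        k = 0
        t_out = out_times[0]
        while True:
            a0 = 0.0
            for r in range(R):
                a = rates[r]
                for s in range(N):
                    m = reactant[r, s]
                    xs = float(x[s])
                    for l in range(m):
                        a *= xs - l
                if a < 0.0:
                    a = 0.0
                props[r] = a
                a0 += a
            if a0 <= 0.0:
                t_next = out_times[T - 1] + 1.0   # frozen (absorbing) trajectory
            else:
                t_next = t - np.log(1.0 - np.random.random()) / a0
            while t_out < t_next:
                # record the pre-event state at every output time passed
                inside = True
                flat = 0
                for s in range(N):
                    if x[s] < lower[s] or x[s] > upper[s]:
                        inside = False
                        break
                    flat += (x[s] - lower[s]) * strides[s]
                if inside:
                    counts[i & 1, k, flat] += 1
                else:
                    overflow[k] += 1
                for j in range(K):
                    v = 1.0
                    for s in range(N):
                        e = expmat[j, s]
                        xs = float(x[s])
                        for l in range(e):
                            v *= xs
                    msum[k, j] += v
                    msumsq[k, j] += v * v
                k += 1
                if k >= T:
                    break
                t_out = out_times[k]
            if k >= T or a0 <= 0.0:
                break
            u2 = np.random.random() * a0
            acc = 0.0
            chosen = R - 1
            for r in range(R):
                acc += props[r]
                if u2 <= acc:
                    chosen = r
                    break
            for s in range(N):
                x[s] += net_change[chosen, s]
            t = t_next


@dataclass
class EnsembleSummary:
    """Empirical histograms and moment estimates on the output time grid."""

    times: np.ndarray
    omega: StateSpace
    counts: np.ndarray          # (T, n_states) int64, clipped to Omega
    overflow: np.ndarray        # (T,) states outside Omega
    n_trajectories: int
    basis: MomentBasis          # exponents used for the moment accumulators
    moment_sum: np.ndarray      # (T, M) sums of monomials over trajectories
    moment_sumsq: np.ndarray
    # (2, T, n_states) even/odd-trajectory half-ensembles, summing to counts;
    # used to debias plug-in divergence estimates by Richardson extrapolation
    counts_halves: np.ndarray | None = None

    def distributions(self) -> np.ndarray:
        """(T, n_states) empirical probability tables (overflow mass excluded)."""
        return self.counts / self.n_trajectories

    def overflow_fraction(self) -> np.ndarray:
        return self.overflow / self.n_trajectories

    def monomial_moments(self) -> np.ndarray:
        """(T, M) empirical raw moments (computed from untruncated states)."""
        return self.moment_sum / self.n_trajectories

    def monomial_moment_se(self) -> np.ndarray:
        m = self.monomial_moments()
        var = self.moment_sumsq / self.n_trajectories - m ** 2
        return np.sqrt(np.maximum(var, 0.0) / self.n_trajectories)

    def factorial_moments(self) -> np.ndarray:
        """(T, M) factorial moments converted from the raw moment estimates."""
        return np.vstack([monomial_to_factorial(m, self.basis)
                          for m in self.monomial_moments()])


def simulate_ensemble(network: ReactionNetwork, omega: StateSpace, config: SSAConfig,
                      basis: MomentBasis | None = None) -> EnsembleSummary:
    """Run the direct-method ensemble and summarize it on the output grid."""
    if basis is None:
        basis = MomentBasis.degree_graded(network.N, 2)
    n = config.n_trajectories
    T = len(config.output_times)
    if config.initial_state is not None:
        x0 = np.asarray(config.initial_state, dtype=np.int64)
        if x0.shape != (network.N,) or np.any(x0 < 0):
            raise ValueError("initial state must be a nonnegative vector of length N")
        init_states = np.broadcast_to(x0, (n, network.N)).copy()
    else:
        P = np.asarray(config.initial_distribution, dtype=float)
        if P.shape != (omega.n_states,):
            raise ValueError("initial distribution / Omega shape mismatch")
        rng = np.random.Generator(np.random.PCG64(
            int(_substream_seeds(config.seed ^ 0x5EED, 1)[0])))
        flat = rng.choice(omega.n_states, size=n, p=P / P.sum())
        init_states = np.stack(np.unravel_index(flat, omega.shape), axis=1).astype(np.int64)
        init_states += np.array(omega.lower, dtype=np.int64)

    shape = omega.shape
    strides = np.ones(network.N, dtype=np.int64)
    for s in range(network.N - 2, -1, -1):
        strides[s] = strides[s + 1] * shape[s + 1]
    counts_halves = np.zeros((2, T, omega.n_states), dtype=np.int32)
    overflow = np.zeros(T, dtype=np.int64)
    expmat = np.array([list(e) for e in basis.active], dtype=np.int64)
    msum = np.zeros((T, basis.M))
    msumsq = np.zeros((T, basis.M))
    _ssa_kernel(network.reactant_matrix(), network.net_change_matrix(),
                network.rate_constants(), init_states,
                np.array(config.output_times, dtype=float),
                _substream_seeds(config.seed, n),
                np.array(omega.lower, dtype=np.int64),
                np.array(omega.upper, dtype=np.int64),
                strides, expmat, counts_halves, overflow, msum, msumsq)
    return EnsembleSummary(np.array(config.output_times), omega,
                           counts_halves.sum(axis=0, dtype=np.int64), overflow,
                           n, basis, msum, msumsq, counts_halves=counts_halves)


def make_initial_condition(network: ReactionNetwork, omega: StateSpace,
                           start_state: Sequence[int], t_burn: float,
                           n_trajectories: int, seed: int,
                           basis: MomentBasis | None = None):
    """SSA burn-in: evolve a point mass for ``t_burn`` seconds and return the
    empirical distribution with its factorial moments.

    Returns ``(P, factorial_moments, summary)`` where ``P`` is the empirical
    table on Omega (overflow excluded and renormalized; the summary records
    the overflow fraction) and the moments are estimated from the
    untruncated trajectory states.
    """
    cfg = SSAConfig(n_trajectories=n_trajectories, seed=seed,
                    output_times=(float(t_burn),),
                    initial_state=tuple(int(v) for v in start_state))
    summary = simulate_ensemble(network, omega, cfg, basis=basis)
    counts = summary.counts[0].astype(float)
    if counts.sum() == 0:
        raise RuntimeError("burn-in left no probability mass inside Omega")
    P = counts / counts.sum()
    return P, summary.factorial_moments()[0], summary
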