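# Methods

## The model

A well-mixed chemical reaction network with species counts
X = (X_1 … X_N) evolves stochastically according to the chemical master
equation (CME): a linear ODE system for the probability P(X, t) of every
lattice state, driven by mass-action propensities

    a_r(X) = c_r · Π_s X_s (X_s − 1) ⋯ (X_s − m_{r,s} + 1),

the falling-factorial convention with no division by m!.  On a finite
truncation box Ω the CME is a large but ordinary linear system; its
nullspace is the stationary law and the action of its matrix exponential
gives exact transients.  Both are implemented sparsely
(`steady_state_oracle`, `evolve_distribution`) and serve as independent
references — never as the method itself.

The package's core is a closure of the *moment equations*.  Monomial
moments μ_α = E[Π X^α] up to total degree k obey

    dμ/dt = A μ + A′ μ′ + μ_c ,

where μ′ collects the higher-degree moments that nonlinear reactions
couple in.  The closure assumes the distribution has maximum Shannon
entropy subject to the current M = C(N+k, k) − 1 moments, i.e. the
exponential-family form

    P(X) = exp( − Σ_{j=0..M} λ_j f_j(X) ),   f_0 ≡ 1,

with λ_0 eliminated by normalization (λ_0 = log Σ_Ω exp(−Σ_{j≥1} λ_j f_j)).
Differentiating moments along the family yields the Jacobian identity
∂μ_i/∂λ_j = −μ_{i,j} + μ_i μ_j = −Cov(f_i, f_j), which closes the moment
system into the Lagrange-multiplier equations (LMEs)

    J(λ) dλ/dt = dμ/dt ,      J = −Cov(f, f) under P(λ).

Initial multipliers come from a damped Newton solve of G(λ) = μ_target
(the same covariance matrix is the Newton Jacobian); the LMEs are then
integrated with an embedded Dormand–Prince RK5(4) pair, recomputing λ_0
algebraically at every emitted state so that Σ P = 1 holds exactly.

## Numerical formulation

Raw monomials up to degree 10 on boxes of a few hundred molecules are a
numerically hostile basis (values ~150^10, Gram matrices with condition
numbers ~1e13).  A `MaxentWorkspace` therefore carries an internally
orthonormalized representation of the same polynomial span: counts are
affinely mapped to z ∈ [−1, 1] per species, monomials in z are centered
and whitened by a Cholesky factor of their Gram matrix under the uniform
distribution on Ω.  The public interface (λ, μ, A, A′) stays in the raw
monomial basis; the transform is an exact triangular linear map.  With it,
−J has condition numbers of order 10–1e4 instead of 1e13.

Three further choices matter in practice:

* **Centered covariances.**  −J is accumulated as E[(g−Eg)(g−Eg)ᵀ], not as
  E[ggᵀ] − μμᵀ; for sharply concentrated distributions the two-pass form
  cancels catastrophically, and the small eigenvalues it destroys are
  exactly what the multiplier dynamics divide by.
* **Spectral solves.**  The linear solves with −J use a symmetric
  eigendecomposition.  Newton steps use a hard pseudo-inverse cutoff
  (eigenvalues below 1e−13 of the largest are exact degeneracies of the
  basis on the effective support; those directions get the minimal-norm
  step).  The ODE right-hand side instead uses a smooth Tikhonov filter
  w/(w² + (c·w_max)²) with c = `SolverConfig.j_cutoff` (default 1e−9):
  near-degenerate directions influence the distribution by O(c) but,
  inverted verbatim, produce arbitrarily fast spurious modes, and a hard
  threshold makes the vector field discontinuous whenever an eigenvalue
  drifts across it (the step controller then thrashes).
* **Generator-action tables.**  dμ/dt inside the solver is computed as
  Σ_r Σ_X a_r(X)[g_i(X+ν_r) − g_i(X)] P(X) from a precomputed table in the
  orthonormal basis, where every intermediate is of order unity.  The
  (A, A′, μ_c) matrix route is retained as an exact polynomial-identity
  cross-check (`method="matrix"`), but mapping its raw high-order moment
  values (~1e20) into the orthonormal coordinates cancels digits, so the
  direct route is the default.

The integrator is the standard RK5(4)7M tableau with per-component mixed
error control (`rel_tol` 1e−8, `abs_tol` 1e−10, safety 0.9, step-ratio
bounds [0.2, 5]); output times are hit by shortening steps, and a failed
−J factorization inside a trial step counts as a step rejection.  λ_0 is
never integrated; the identity dλ_0/dt = −Σ μ_j dλ_j/dt is exposed as a
consistency diagnostic only.

The initial-value fit uses damped Newton (backtracking halving to 1e−4)
with residuals measured in the orthonormalized moment coordinates, where
the default tolerance 1e−9 means "matched to 1e−9 of a basis-function
standard deviation" uniformly across moment orders.  Plain Newton from
the uniform start stalls for rich targets; `fit_lambda_ladder` fits order
2 first and zero-pads each solution as the next order's starting point,
which kept every benchmark fit inside its Newton basin.  A point mass is
a boundary point of the family (infinite multipliers), so "empty"
initial states are represented by strongly concentrated members
(mean ≲ 1e−6 molecules), which changes linear-network transients below
1e−7 relative.

## The SSA baseline

The Gillespie direct method is implemented exactly (exponential waiting
times, propensity-proportional reaction choice) in a numba kernel
(~1e7 events/s).  Trajectories run on the untruncated lattice; only
histogramming clips to Ω, with an overflow counter measuring what the
truncation misses.  Every trajectory uses its own RNG substream derived
from the master seed by a splitmix64 counter hash, so results are
identical regardless of batching.  Even- and odd-numbered trajectories
are additionally histogrammed separately (see below).

## Benchmark experiments

Four networks are built in, with the published rate constants and
initial first/second factorial moments: the bistable Schlögl model
(1 species, closure order 10, box [0,150], window 40 s), Wilhelm's
bistable system (2 species, order 6, [0,90]², 10 s), the oscillatory
Brusselator (2 species, order 4, [0,90]×[0,100], 30 s) and the
Goutsias-type viral infection model (3 species, order 2,
[0,55]×[0,70]×[0,115], 5 s, `rel_tol` 1e−6 — second-order moments need
far less integration accuracy and the three-species box is large).  Run
boxes are trimmed relative to the generous fixture defaults so that the
boundary mass stays far below 1e−10 (checked at run time) without
wasting solver effort on empty states.

The initial condition of each benchmark is "a short burn away from
steady state": a point mass evolved for a fixed time.  `run_benchmark`
computes that burn *exactly* (matrix-exponential action of the truncated
generator) rather than sampling it: for the multistable systems the
closure's basin-weight error varies several-fold across equally valid
sampled burn-in realizations (first-order Wilhelm errors 0.2–1.9% over
three realizations), and a deterministic initial makes the reported
number a property of the method rather than of a burn-in seed.  The
sampled burn-in (`make_initial_condition`) remains available.  Start
states and burn times were chosen once so the burn moments land near the
published initial conditions (Schlögl {X}=38.0, {X²}=2.14e3 against
38.01/2.10e3; the others within ~5–15% per moment).

Comparisons against an SSA ensemble started from the same initial table
report, per output time and then averaged:

* **Probability error:** KL(SSA ‖ LME) in nats × 100.  The maxent table
  is strictly positive, so this direction is always finite.  For
  multi-species systems the tabulated column is the component-averaged
  *marginal* KL — the distribution comparisons published for these
  systems are per-component marginals, and the joint 2-D plug-in KL at
  reduced trajectory counts is dominated by histogram bias; the joint
  value (raw and debiased) is kept in the report metadata.
* **Moment errors:** 100·‖Δ‖₂/‖ref‖₂ over all factorial moments of the
  same order (1 and 2), against the SSA estimates computed from
  untruncated states.

Finite ensembles bias both metrics upward, so the reported values are
debiased estimates of what an infinite ensemble would give: the plug-in
KL is Richardson-extrapolated from the even/odd half-ensembles
(2·KL_n − mean KL_{n/2}), and the moment errors subtract the known
standard-error variance in quadrature.  Raw values and the asymptotic
sampling floor (k−1)/(2n) are reported alongside.

### What the benchmarks show — and do not show

With these estimators the deterministic error columns are, at the
default ensemble sizes:

| system | KL% | 1st-order % | 2nd-order % |
|---|---|---|---|
| Schlögl (k=10) | 0.05 | 0.46 | 0.54 |
| Wilhelm (k=6) | 0.19 | 1.3 | 1.8 |
| Brusselator (k=4) | ~90 | 6.6 | 16 |
| viral (k=2) | 0.46 | 0.07 | 0.11 |

Two structural limits of the closure, established with the independent
CME oracles, are worth knowing:

* The closure has a genuine stationary bias: the order-10 Schlögl LME
  fixed point (verified by an independent root-find of the fixed-point
  equations) sits 0.46% off the true stationary mean; the order-4
  Brusselator fixed point is qualitatively wrong (KL 2.6 nats against
  the truth, whose best order-4 moment projection is already 0.13 nats
  away), so once the damped oscillation dies out the Brusselator error
  columns are dominated by that plateau.
* Enlarging the truncation box adds *real* degrees of freedom to the
  family — the polynomial tail beyond the occupied region — which relax
  toward the soft-tailed (higher-entropy) member of the current moments.
  Third-moment trajectories of the order-10 Schlögl run therefore shift
  by 1e−3…1e−2 relative when the upper bound grows from 150 to 300, even
  though the exact CME solutions agree to 3e−10.  Box insensitivity holds
  at figure resolution, not to high precision.

The viral-model moment errors are at or below the sampling floor of the
scaled ensembles used here; they bound, rather than resolve, the true
closure error.

## Reproducing the results

`scripts/acceptance.py --seed S --out results.json` reruns the Schlögl,
Wilhelm and Brusselator benchmarks from scratch at ensemble sizes
1e5/2e5/1e5 (about 10–15 minutes on one CPU) and writes the averaged
error columns.  The seed drives the comparison ensembles; the initial
conditions and LME solutions are deterministic, so repeated runs differ
only by the ensemble noise (±0.03 percentage points or so).

## Known limitations

* Explicit time stepping: strongly stiff closures (large boxes, high
  orders) are handled by the spectral filter, not by an implicit method.
* Moment-problem feasibility is not certified; infeasible targets are
  reported as non-convergence of the Newton fit.
* Factorial-moment standard errors neglect covariances between monomial
  estimators (upper-triangular conversion applied to variances).
* The closure order is fixed by the caller; there is no automatic
  selection, and initialization difficulty grows with order (the ladder
  helps but does not guarantee convergence for arbitrary targets).
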