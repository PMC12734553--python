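# Methods

## Model and assumptions

We model an ensemble of `N` identical carriers, each with an external
compartment of `mE` binding sites and an internal compartment of `mI`
sites; the `M` cargo items occupy at most one site each.  Transfer is
strictly intra-carrier, with fixed first-order rate constants `KEI`
(external → internal) and `KIE` (internal → external).  This neglects
inter-carrier (collision-driven) exchange, cooperativity between transfer
events, and any compositional heterogeneity of the carriers — each transfer
is an independent single-molecule event across a fixed barrier, the
picture appropriate for passive flip-flop of amphipathic molecules between
bilayer leaflets.

Because carriers do not exchange cargo, the subpopulation `S_v` of carriers
with total load `v = i + n` is frozen for every `v`; the dynamics only
redistributes cargo *within* each subpopulation.  All three solution layers
in the package respect this exactly or to integration tolerance:

1. **Master equation** (`flipkin.master`).  The linear jump process on the
   `(mE+1) × (mI+1)` occupancy grid with combinatorial factors
   `gEI(i,n) = i (1 − n/mI)` and `gIE(n,i) = n (1 − i/mE)`.  The stationary
   state within each `v`-class is the product of two binomials with
   site-occupation probabilities `(p, q)` solving detailed balance
   `mE KEI p (1−q) = mI KIE (1−p) q` together with cargo conservation
   `p mE + q mI = M/N`.
2. **Continuum propagator** (`flipkin.fokker_planck`).  In the Gaussian
   regime at low occupation (`mE, mI` large, `p, q ≪ 1`, per-carrier loads
   finite) the density obeys a drift–diffusion equation that, in
   `u = x − z`, `v = x + z`, is an Ornstein–Uhlenbeck process in `u` alone,
   solved exactly by a Gaussian kernel with mean
   `u′ e^{−t/τ} + v r (1 − e^{−t/τ})` and variance
   `σ(t) = σ∞(1 − e^{−2t/τ})`.
3. **Gillespie oracle** (`flipkin.ssa`).  The exact direct-method jump
   process, simulated per carrier.

## Numerical choices

**Detailed-balance occupancies.**  Eliminating `q` (linear in `q` at fixed
`p`) turns detailed balance into a quadratic in `p`; exactly one root lies
in `(0,1)` for `0 < M < N(mE+mI)` (the quadratic changes sign between the
endpoints), and interiority of `q` follows from the balance relation
itself.  A three-step Newton polish brings both residuals to ~1e−15
absolute; the default acceptance tolerance for algebraic residuals is
1e−12 (configurable).  Degenerate double roots raise rather than guess.

**Equilibrium normalizer.**  The stationary state multiplies the product
binomial by a per-class factor `g(v)` fixed so each anti-diagonal sums to
its conserved `S_v`; this is the unique stationary state compatible with
the frozen subpopulations.  `g` is computed in log space (binomial log-pmfs
plus log-sum-exp), so classes dozens of standard deviations from the
binomial bulk are handled without underflow.

**Integration and truncation.**  The master equation is integrated with an
adaptive explicit Runge–Kutta scheme (DOP853, rtol 1e−8, atol 1e−12·N
defaults) on a sparse generator.  The equations are only mildly stiff
(spectral radius ~ `K · max load`), so the explicit scheme outruns implicit
ones at these sizes.  Grids above ~250k states are automatically truncated
to a window covering the initial and equilibrium bulk to `mean ± k·sd` with
`k ≥ 10` and a Gaussian tail bound below ε = 1e−12; jumps leaving the
window are dropped and the resulting carrier-count leak is monitored
against the bound.  This makes the 2501² reference grid cost the same as a
~150² one.  Windowed and full-grid runs agree to 1e−9·N (tested).

**Propagator evaluation.**  All initial conditions used in practice are
finite Gaussian mixtures in `(u, v)` (a delta is a zero-covariance
component), and the kernel acts on a mixture as the exact affine map
`mean → A·mean`, `cov → A·cov·Aᵀ + diag(σ(t), 0)` — no quadrature, no grid.
`t = 0` returns the initial object unchanged (the kernel is a delta);
densities of singular components raise a degenerate-delta error instead of
evaluating a 0-variance Gaussian, while marginals and moments remain
available symbolically.  Gridded initial data use per-`v`-slice trapezoid
quadrature against the same kernel on a caller-supplied grid (≥ ~400 points
spanning mean ± 8 sd recommended; the bundled tests resolve the closed form
to 1e−5 relative at 541 points).  Densities follow the convention that the
`(u,v)`-chart field integrates to `2N` (Jacobian `dx dz = du dv / 2`), so
`f(v) = ∫ ỹ du` obeys `(1/2)∫ f dv = N`.

**Stochastic oracle.**  Each carrier runs its own two-reaction direct-method
SSA from a counter-derived splitmix64 substream keyed by (master seed,
carrier index): results are bit-identical for identical `(seed, ensemble
size, parameters)` regardless of execution order, and per-carrier total
cargo is conserved in integer arithmetic.  Gaussian initial conditions are
discretized by rounding to the nearest integer and clipping to `[0, m]` —
an approximation used only for oracle comparisons.  Moment estimates carry
delete-one jackknife standard errors.

## What the generator emulates — and what passing tests show

The built-in initial conditions (delta, variance-equals-mean Gaussian,
two-Gaussian mixtures, product binomial) are the idealized ensembles of the
worked examples: carriers i.i.d., loads Poisson-like, rates homogeneous.
Real liposome preparations add polydispersity in size (hence in `mE`, `mI`
and rates), correlated loading, and inter-carrier exchange — none of which
is represented here.  Passing tests therefore certify the internal
consistency and numerical fidelity of the three solution layers for the
stated model, not the model's adequacy for any particular formulation.

## Accuracy of the continuum approximation (a caution)

The drift of the continuum equation is the large-`m` limit of the exact
drift, but its diffusion coefficient is a *constant*, `σ∞/2τ`, fixed by
requiring the correct equilibrium.  The exact jump noise is state-dependent
(∝ `KEI x + KIE z`), and the difference shows in transients.  The cleanest
statement: in the strict low-occupation limit each `v`-class consists of
`v` independent two-state molecules, so the class distribution is exactly
`Binomial(v, π(t))` with `π(t)` the single-molecule occupation probability
— and the identity `4π(1−π) + (2π−1)² = 1` then makes the ensemble
u-variance *constant in time*, `var_u ≡ M/N`, for the
variance-equals-mean Gaussian start.  The continuum solution instead
predicts the dip to `(8/9)·M/N` at `t = τ ln 2`.  Both statements are
true of their respective equations; the package computes each exactly, and
the Gillespie oracle sides with the master equation (the bundled test
`test_variance_tracks_master_equation_not_constant_diffusion` pins this
down).

Consequently the cross-section agreement between the integrated master
equation and the continuum closed form is excellent but not asymptotically
perfect: the peak-normalized sup-norm falls like `1/m` through 0.44, 0.19,
0.09, 0.044 at `m = 250, 500, 1000, 2500`, then saturates near a 4–6%
floor set by the constant-diffusion approximation (0.051 at `m = 5000`,
0.056 at `m = 10000`); near `m ≈ 2500` the binomial variance deflation of
the discrete start happens to cancel most of the jump-noise overshoot.
The reference comparisons therefore use `m ≤ 2500` and assert monotone
improvement over `m = 250…2500` rather than a vanishing limit.

## Parameters that matter

| parameter | meaning | default / typical |
| --- | --- | --- |
| `KEI`, `KIE` | flip-flop rate constants, 1/time | set by the user; examples use `1/(3τ̂)`, `2/(3τ̂)` |
| `τ = 1/(KEI+KIE)` | moment relaxation time | derived; times are most naturally given in units of `τ` |
| `mE`, `mI` | sites per compartment | `inf` for continuum work; 2500 for the reference grid |
| `M/N` | cargo per carrier | 100 in the worked examples |
| `rtol`, `atol` | integrator tolerances | 1e−8, 1e−12·N |
| `ε` | truncation mass bound | 1e−12 |

## Problem sizes used by the bundled checks

The test suite integrates grids up to `mE = mI = 2500` (truncated to a
~150² active window), runs the Gillespie oracle with 10⁵ carriers on the
`mE = 8, mI = 5` grid and 2·10⁴ carriers at `m = 500–2000`, and evaluates
propagator/closed-form identities on 200² point sets; the whole suite and
the acceptance script each complete in well under a minute on one core.

## Known limitations

* No inter-carrier transfer, multiple carrier species, or time-dependent
  rate constants.
* The first-order (drift-only) continuum equation is a derivation step
  only; no finite-difference PDE solver is provided — the Green's function
  *is* the continuum solution method, valid in the low-occupation Gaussian
  regime.
* Rate-constant estimation from experimental release data is out of scope.
* Continuous initial conditions are discretized by rounding for the
  stochastic oracle; for strongly skewed or near-boundary loads this
  rounding bias can exceed the Monte-Carlo error.
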