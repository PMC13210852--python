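# Methods

## Model

`enzfilm` simulates enzymatic degradation of a thin semicrystalline polymer
film immersed in a well-mixed enzyme bath, with the crystalline and amorphous
phases treated as distinct reactive states. Six species are tracked through
the film half-thickness `x ∈ [0, L]` (the film is attacked symmetrically from
both faces, so only half the thickness is modelled): free enzyme `E`
(normalised by the bath concentration), crystalline polymer `C` and amorphous
polymer `A` (volume fractions normalised so `C0 + A0 = 1`), the bound
complexes `EC` and `EA`, and the cumulative soluble product `P`.

The mass-action network is

```
E + C  <-> EC        (k1 / k_m1)
E + A  <-> EA        (k3 / k_m3)
EC -> E + A          (k_conv, amorphisation of bound crystalline material)
EC -> E + P          (k_deg_C, crystalline enzymolysis)
EA -> E + P          (k_deg_A, amorphous enzymolysis)
```

All rates are first order with units 1/h (the bracketed concentrations are
dimensionless). The network conserves polymer pointwise,
`d(C+A+EC+EA+P)/dt = 0`, and enzyme, `d(E+EC+EA)/dt = 0` — both hold
algebraically and are asserted in the tests to `10·atol` along whole
trajectories.

Only the free enzyme moves: polymer phases are immobile, and soluble products
are removed instantly by the well-mixed bath. Enzyme transport is Fickian
with a porosity-dependent effective diffusivity

```
phi = 1 - (C + A),       De(phi) = De0 * (1 + alpha_e * phi)
```

with `De0` in mm²/h and `alpha_e = 1` by default. A sensitivity check over
`alpha_e ∈ [0.5, 5]` (in the test suite) moves the weight-loss and
crystallinity curves by less than one percentage point, so the single-
parameter linear form costs little. Note on units: baseline diffusivities
are occasionally quoted in mm/h in the degradation literature, but the
diffusion timescale `L²/De0` and Fick's law are dimensionally consistent only
with mm²/h, which is what this package uses throughout.

Boundary conditions: `E = 1` at the exposed surface (Dirichlet, bath value)
and zero flux at the mid-plane. The initial state is pristine polymer with no
enzyme inside the film; the surface node is set to the bath value at
integration start, and the start-up discontinuity is absorbed by the stiff
integrator's first step.

## Numerics

Method of lines on a uniform grid: second-order central differences with
arithmetic-mean interface diffusivities, the Dirichlet node pinned, and a
half-control-volume correction at the no-flux boundary. The reference grid is
N = 25 nodes for L = 0.25 mm (`dx ≈ 0.0104` mm); other thicknesses scale N to
keep `dx` at or below this value so thick films are never under-resolved.
Grid convergence (N = 25/50/100) changes weight loss by far less than half a
percentage point.

Two BDF-family stiff integrator backends are provided behind the same
interface and agree to ~1e-5 on the case study:

* `method: BDF` — scipy `solve_ivp` BDF, the default, run at rtol 1e-6,
  atol 1e-9, max step 0.5 h;
* `method: LSODA` — `odeint` with a banded Jacobian (the interleaved state
  layout has bandwidth ml=6/mu=8); LSODA switches to BDF in the stiff regime
  and is ~10x faster per solve, so the sampling-heavy drivers (MCMC, Sobol,
  replicate fitting) use it on a coarse 7-node grid.

The right-hand side is a compiled (numba) kernel; an independent plain-numpy
operator (`assemble_rhs`) is kept as the readable reference and the two are
asserted equal on random states. Further independent checks: a fixed-step
explicit Euler integration at 20% of the diffusive stability limit reproduces
a small instance to 1e-4, and in the `De0 → ∞` limit the polymer subsystem
matches the matrix exponential of the linear `E ≡ 1` system to 1e-4.

Degenerate inputs: states are validated for finiteness; concentrations may
undershoot zero by at most 1e-6 (solver tolerance slack) before the run is
rejected; porosity is clipped to [0, 1] only inside the diffusivity, never in
the state itself. Integration failures raise `SimulationError` carrying the
time reached; during calibration they map to a large finite penalty (1e12)
so the optimiser can still rank failed probes, and during MCMC to `-inf`
(the move is rejected).

## Observables

* Bulk crystallinity `χc = ∫C dx / ∫(C+A) dx` (trapezoidal quadrature; only
  uncomplexed polymer counts, since washing removes enzyme, complexes and
  products before a DSC measurement). Local crystallinity `χ(x) = C/(C+A)`;
  fully degraded nodes are reported as NaN, never as zero.
* Weight loss. No standard formula exists for which fraction of enzyme-bound
  polymer a washed film retains, so the convention is explicit:
  the default counts cumulative product, `WL = 100·∫P dx / L`, making WL
  monotone and the residual film mass inclusive of complexed polymer; the
  alternative `polymer` convention counts only `C + A` (consistent with the
  crystallinity washing convention) and is a one-argument switch.
* Regime metrics: `tau_diff = L²/De0` and the Damköhler numbers
  `Da = k_deg · L²/De0` for both pathways. With the calibrated parameters,
  `tau_diff ≈ 9.6 h` at L = 4 mm (8 mm full film) and `Da_A ≈ 0.048`; the
  regime classifier labels a film transport-influenced when `Da_A > 0.04`, a
  configurable heuristic placed just below the 8-mm case, which the thickness
  sweep identifies as the onset of transport influence. (Note `Da_A` at that
  point is ~0.05, not ~1: the onset shows up well before the classical
  `Da ≈ 1` balance because the catalytic and diffusive timescales act on
  different observables.)

## Synthetic data

The generator emulates joint weight-loss/crystallinity degradation datasets:
observations at {0, 4, 8, 16, 20, 24, 40, 64} h for both observables,
independent Gaussian measurement noise with per-point standard deviations
(default 2% for both series, matching the residual scale of thin-film
PCL–lipase experiments), truncated to the physical [0, 100]% range by
resampling. Everything is seeded and the seed is recorded in the dataset
provenance.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: temporal correlation of measurement errors, systematic
DSC baseline effects, recrystallisation (real crystallinity series can
plateau transiently), batch-to-batch material variability, and the fact that
real replicate counts vary per time point. One structural consequence is
measurable: for observables near 0% the truncated noise is biased upward by
up to ~+1.6% while the inference model keeps the plain Gaussian likelihood,
and this mismatch visibly shifts the posterior of weakly identified
parameters (see below).

## Calibration

The joint objective is the raw sum of σ-weighted squared residuals over both
series (placing them on one dimensionless scale). The eight-parameter search
runs in log10 space over the feasible box (rates in [1e-6, 50] 1/h, De0 in
[1e-12, 50] mm²/h): a seeded Latin-hypercube probe ranks candidate starts,
then bound-constrained trust-region least squares polishes the best few. Two
numerical choices matter:

* the finite-difference Jacobian step is 0.01 in log10 space — the default
  square-root-of-machine-epsilon step sits below the ODE solver's noise
  floor and yields spurious gradients;
* per-observable R² is computed on raw (unweighted) values.

Identifiability: the model has a practical compensation ridge between `k3`
and `k_deg_A` — once `k_deg_A ≫ k_m3`, the product formation rate approaches
`k3·E·A` and the data no longer separate the two. On noise-free case-study
data the ridge attains a weighted loss of ~0.7 (rms residual ~0.4%), so
under 2% noise a fully global fit lands on the ridge in roughly half the
replicates. The replicate recovery experiment therefore follows the
informed-start protocol — each replicate is refit locally from the case-study
point estimate — under which the median recovered `k_deg_A` across replicates
stays within ~20% of the generating value, while individual replicates can
still wander by 2x or more along the soft direction.

## Bayesian inference

Independent log-uniform priors over the feasible box; joint Gaussian
likelihood over both series, so `log L = const − loss/2` exactly (asserted
numerically). Sampling uses differential-evolution ensemble MCMC with
snooker updates (probability 0.1) on the log10 scale, via emcee's
`DEMove`/`DESnookerMove`. The default budget is 40 chains × 500 iterations
with thinning 5 — 4000 retained draws, no burn-in removal by default (an
optional `burn_in` is provided). Chains start from the least-squares estimate
with seeded log-space Gaussian jitter (`sigma_init`, default 0.05; the
coverage experiments use 0.5 so the initial population is overdispersed).

Caveats measured on this model: with short chains the DE ensemble does not
fully traverse the near-flat directions of the posterior (acceptance
fractions run at 0.05–0.15), so credible intervals for the weakly identified
parameters (`k1`, `k_m1`, `k_conv`, `k_deg_C`, `De0`) should be read as
lower bounds on the true posterior width; and the generator-likelihood
truncation mismatch above shifts the posterior of `k3` and `k_deg_C` enough
that their 95% intervals do not reliably cover the generating values in
replicate experiments, while `k_deg_A` covers in essentially all replicates.
Posterior predictive bands propagate retained draws (optionally a seeded
subsample) through the forward model; the central curve is the trajectory at
the posterior-mean parameter vector, and failed draws are excluded with the
count reported.

## Sobol sensitivity

Saltelli paired-matrix estimation on scrambled Sobol' points (`n(d+2)` model
runs for `n` base samples), first-order indices by the Saltelli-2010
estimator and total-order by Jansen's, bootstrap confidence half-widths,
all seeded. The estimators are verified against closed forms (additive
linear function, Ishigami) in the tests. The analysis ranges default to
[0.5×, 2×] the calibrated values sampled log-uniformly — analysis ranges are
a reporting choice, so results carry the range used; the full calibration
box is available as a preset. Time-dependent indices of the mass-loss output
are computed at the case-study observation times; t = 0 is excluded (zero
output variance; such points are flagged, not silently zeroed). At the
case-study thickness the amorphous catalytic rate dominates both index
families at every time, the amorphous binding rate shows the clearest
interaction excess (total order above first order), and the total-order
index of `De0` grows with film thickness while remaining negligible at and
below the experimental 0.5 mm.

## Problem sizes used by the shipped experiments

The test suite and the acceptance script run the sampling-heavy stages on a
7-node grid with the LSODA backend (forward solve ~4 ms): the full 40×500
sampler budget on one synthetic dataset; Sobol at base sample 256 (2560
forward runs per thickness); the thickness sweep at the per-L grid rule; and
10 replicate recovery/coverage experiments with a 20-chain × 300-iteration
sampler per replicate. These sizes were chosen so the entire suite completes
on a single CPU in well under half an hour while leaving every qualitative
conclusion unchanged at larger budgets (doubling the Sobol base sample moves
the dominant indices by < 0.05; the grid-convergence and backend-agreement
tests bound the discretisation error).

## Known limitations

One-dimensional geometry only; no moving erosion front, no product
inhibition, no recrystallisation; crystallinity is a model-state ratio, not
a DSC signal model. The weight-loss convention for complexed polymer is a
modelling choice (both variants provided). Thick-film behaviour is a
prediction: the calibration data are thin-film and carry almost no
information on `De0`, which is why its posterior is broad.
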