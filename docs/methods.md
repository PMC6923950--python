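# Methods

This note documents the models, the numerical choices, and what the
synthetic-data pipeline does and does not establish.

## Microenvironment model

Five ODEs describe one locally homogeneous volume: masses in the glucose,
ethanol, and quiescent states and the two nutrient pools (see README for
the equations).  Assumptions baked into the structure:

* Growth on glucose is bilinear (`mu1 m_g g`), with no Monod saturation;
  the switching term `beta1 m_g/(g + K)` turns on as glucose is depleted.
* Quiescence is absorbing: there is no death state, no lysis, and no
  regrowth from quiescent cells.
* Ethanol is produced only during glucose growth and consumed only by
  ethanol-state growth; yields `gamma1..gamma3` are constant.
* A petite (respiratory-deficient) strain shares all parameters with wild
  type except `mu2 = 0`.

Initial conditions fix `g(0) = 1` (glucose level normalized to the
initial supply) and put all initial biomass in the glucose state —
cultures start in fresh glucose-rich medium — so the free parameters are
the logs of `{m_g(0), mu1, beta1, K, mu2, gamma1, gamma2, gamma3}` plus
`log beta2` and/or `log beta3` where the switching topology allows them
(10 parameters for H1, 9 for H2/H3).  Log-space coordinates make the
standard-normal priors act as soft positivity bounds: a rate present in
the model cannot shrink to zero for free.

### Integration

The reference route (`simulate_microenv`) uses LSODA at
`rtol 1e-8 / atol 1e-10`; switching near `g ≈ 0` makes the system
moderately stiff.  Calibration needs ~1e5–1e6 trajectory solves per run,
so the likelihood path uses an in-package Cash–Karp RK45 with adaptive
step control (`rtol 1e-6 / atol 1e-9`), compiled with numba.  The two
integrators agree to ~1e-8 on the calibrated trajectories (tested).  The
compiled solver fails fast — step budget 10 000, state bound 1e7 — and a
failed solve scores a log-likelihood of −1e10 rather than raising, which
keeps samplers alive in pathological corners of the prior.  Integrator
undershoots below zero smaller than 1e-9 of the initial content are
clamped; anything larger aborts as a genuine error.

## Likelihood and priors

The likelihood multiplies per-timepoint Gaussians for the replicate-mean
total mass (variance = the replicate sample variance, floored at 1e-8)
with two Gaussians for the steady-state composition fractions at
`t_N = 80 h` (both with sd 0.02).  Priors are independent standard
normals on every log-parameter; the hypothesis prior is uniform.

## Population MCMC and evidence

Power posteriors `L^beta * prior` are sampled jointly over the ladder
`beta_i = ((i−1)/(N_beta−1))^5` (30 rungs at full scale).  One sweep is a
random-walk Metropolis update per rung followed by `N_beta − 1` exchange
attempts between uniformly chosen adjacent rungs.  Proposals are
multivariate normal; during burn-in the proposal *shape* follows the
trailing-window sample covariance (window 750, scaled 2.38²/d + 1e-8·I)
while the overall *scale* is tuned by a Robbins–Monro recursion toward
25% acceptance, and both are frozen afterwards.  The scale recursion is
load-bearing: exchange moves inject cross-mode jumps into the trailing
window, and a proposal built from that inflated covariance alone can
freeze a rung at 0% acceptance.

Chains start from per-rung optima of the power posterior, found by a
cascade that optimizes the coldest informative rung first and warm-starts
each rung below with the optimum above; rungs with `beta < 1e-3` are
prior-dominated and start from the cascaded point directly.  Because the
posterior surface has cliff-like drops where trajectories degrade,
each optimization runs a Nelder–Mead stage followed by an L-BFGS-B
polish, and the multistart set always includes a data-informed starting
point read off the growth curve (initial OD, early exponential slope,
plateau mass).  This heuristic start lands in the dominant mode
essentially always in testing; random prior starts alone frequently do
not.

The log marginal likelihood is the trapezoidal quadrature of the
per-rung posterior mean log-likelihood over beta.  Two limitations are
inherent to this estimator here and documented deliberately:

* The integrand at the bottom of the ladder is the prior expectation of
  the log-likelihood, which is astronomically negative and heavy-tailed
  (a prior draw rarely resembles the data).  The power-5 ladder
  concentrates rungs there precisely to control this, but a few nats of
  noise and discretization bias remain in any absolute evidence value.
* Hypothesis comparison is much better behaved than absolute evidence:
  the bottom-ladder contributions are dominated by the shared model
  structure.  `select_hypothesis` additionally reuses the same sampler
  seeds for every hypothesis (common random numbers), so much of that
  noise cancels in the evidence differences.

Convergence across independent runs is summarized by the classic
Gelman–Rubin PSRF (between/within variance form, threshold 1.1), not the
rank-normalized split variant.  The MAP estimate is the best sampled
point refined by one local polish and is never worse than the best
sample.

## Spatial framework

The lattice holds per-cube amounts (cube volume is the unit, so amounts
and concentrations coincide).  Defaults follow the physical setup: cube
edge 0.1 mm, mass-movement threshold `th = 1`, mass-movement rate
20 /h, agar glucose initialized to 1 inside a disc 0.2 mm thick (2 cube
layers), one seeded cube at the lattice centre with `m_g = th` and local
glucose 1.  The default lattice is a reduced 21×21×(2+10) box with a
2 mm disc; the full experimental geometry (1 cm disc, 101×101 footprint)
is a config change.

Transport rules:

* Cell mass moves only when the donor's thresholded total exceeds the
  neighbour's, carries the donor's state fractions, and never enters the
  agar.  Fluxes are antisymmetric per cube pair, so total cell mass is
  conserved exactly (tested to 1e-12 relative per step).
* Glucose diffuses over the union of the agar and cell-bearing cubes;
  ethanol only over cell-bearing cubes, always at the colony rate.  The
  per-edge rate rule is implemented literally: colony rate strictly above
  the first cell-mass layer and on vertical edges leading up out of it;
  agar rate otherwise — including lateral edges within the first colony
  layer, an ambiguity of the layer rule that is resolved literally here.
* Domain boundaries are zero-flux (a sealed dish); missing neighbours
  contribute nothing.

Stepping is explicit Euler at `dt = 0.0025 h`.  The production loop runs
in a compiled kernel that is bit-for-bit identical to the vectorized
reference implementation (tested).  Per-axis flux sums are grouped as
`(x + y) + z`, which makes a centred colony exactly invariant under
quarter-turn rotations — a strong structural regression test.  The
footprint observable is the count of lattice columns holding any
above-agar cell mass times the cube face area.

## Spatial calibration

The two nutrient transfer rates are fitted by minimizing
`xi = log Σ (A_sim − A_meas)²` (floored at 1e-300) with GP Bayesian
optimization: 20 Latin-hypercube points over the physical box
[5, 75] × [0.005, 1], then fit-predict-propose loops with the
squared-exponential kernel, hyperparameters from a single optimization
started at lengthscales 1, signal variance 1, noise sd 0.1 (log-space,
bounded, jitter 1e-10), and expected improvement maximized by multistart
local search from 50 LHS points; the loop stops below an EI of 1e-46 or
at the iteration cap.  Cost evaluations that raise are recorded as a
large sentinel and the loop continues.

Identifiability depends on the observation scale: the footprint area is
quantized in units of one column, so on very small lattices (≲15×15,
short horizons) ±25% changes in `lambda_agar` can leave the discrete
footprint series bit-identical and no optimizer can recover the rate.
On the default 21×21 lattice over 48 h both rates perturb the series,
but the cost basin around the generating rates spans only a few percent
of the physical search box, and a single-lengthscale squared-exponential
surrogate over the linear box does not localize it within the standard
evaluation budget.  Point recovery of the transfer rates should
therefore only be expected at the full experimental scale (larger
colony, 7.5-day horizon, smoother area response); at test scale the
meaningful guarantee — and the one the suite asserts — is
self-consistency: the calibrated model reproduces the measured footprint
series to within a few percent of the final colony area.

## Synthetic data

The generator reproduces the study design: 6 replicate growth curves on
a 15-min grid to 88 h, composition observations at 80 h with sd 0.02,
and footprint areas every 20 min for up to 7.5 days.  Growth noise is
additive homoscedastic Gaussian per replicate (sd 0.02 OD, ~1% of final
mass — typical plate-reader replicate scatter); heteroscedasticity enters
the likelihood only through the per-timepoint sample variances.
Composition noise is truncated to the unit simplex by rejection;
footprint noise is truncated at zero.

The frozen ground truth is an H2 parameterization
(`m_g0 = 0.1, mu1 = 1.0, beta1 = 0.07591, K = 3.03593, mu2 = 0.06881,
beta3 = 0.02418, gamma1 = 1.5, gamma2 = 1.5, gamma3 = 1.0`) chosen so the
noiseless 80-h composition equals the published wild-type steady state
(29% ethanol state, 62% quiescent) exactly, with a diauxic shift near
6–10 h and a saturating curve.  Note `beta3` and `beta1` sit in the slow
tail of the prior; this is what an 88-h experiment demands of rates in
1/h and mirrors the soft-lower-bound role of the prior.

What passing tests show — and don't.  The synthetic data match the
model family exactly (no model misspecification), noise is exactly
Gaussian, and the OD-to-mass map is the identity.  Recovery results
therefore validate the inference machinery, not the biological model;
real growth curves add preprocessing, drift, and misspecification that
these tests do not probe.

## Problem sizes in the test suite

Full-scale settings (30 rungs, 1e5 burn-in sweeps, thin 1000, 2500 kept,
4 runs; 20+9 BO evaluations on the 101×101 lattice) are available via
configuration.  The routine suite uses sizes chosen for quick iteration:
hypothesis selection runs 30 rungs with 1200 burn-in sweeps, 250 kept at
thin 3, and two pooled runs per hypothesis; MAP fits use 6–8 starts;
colony runs use the 21×21 or 11×11 lattices with horizons of 8–48 h.
The evidence-oracle check uses the conjugate normal–normal toy at 10
rungs and 2×10⁴ samples per rung.
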