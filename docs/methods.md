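# Methods

`cocult` models the population dynamics of co-cultured wild-type (W) and
p53-null (P) mouse embryonic stem cells during differentiation, where the
p53-null line behaves as a super-competitor that eliminates its wild-type
neighbours. The package implements two rival mechanistic descriptions of the
growth curves, a population-scaled Gaussian likelihood, DREAM-style MCMC
inference with posterior hypothesis testing and model comparison, synthetic
data generation matching the assay design, and counterfactual simulations of
the BCL2 (doxycycline-inducible) rescue.

## Models

**Direct competition (Lotka–Volterra).** Cell counts per well evolve as

    dW/dt = W (rho_W − k_WW W − k_WP P)
    dP/dt = P (rho_P − k_PP P − k_PW W)

with intrinsic net growth rates `rho_i > 0` (per day) and four competition
strengths `k_{affected,effector} > 0` (per cell per day). Per-capita growth
declines linearly with each neighbour count, so crowded wells shrink; a
species alone follows logistic growth with carrying capacity `rho_i / k_ii`.
The asymmetry of interest is heterotypic suppression of the wild type:
super-competition appears as `k_WP > k_WW` together with `rho_P > rho_W`.

**Resource competition.** The alternative mechanism is competition for a
shared nutrient `R`:

    dW/dt = W (alpha_W − delta_W · [R < r_W])
    dP/dt = P (alpha_P − delta_P · [R < r_P])
    dR/dt = −(gamma_W W + gamma_P P) · [R > 0]

Each species grows at its maximum net rate `alpha_i` until the resource falls
below its characteristic concentration `r_i`, when a starvation apoptotic
rate `delta_i` switches on (`alpha_i − delta_i` may be negative). The
indicator brackets are sharp (Heaviside) switches evaluated with strict
inequalities: a resource level exactly at `r_i` still counts as available,
and a fully depleted resource is not consumed further. The switch sits on
the death term only; because the crossing set has measure zero under fixed
Euler stepping, the boundary convention has no dynamical consequence. The
right-hand side is isolated in one function so a saturating variant
(`R/(R+r_i)`) could be swapped in; the threshold form is the default.

Units: populations are raw cells per well (a plating of 0.4×10⁵ is stored as
40000), time in days, rates per day. Resource units are arbitrary; see
*Identifiability* below.

## Solver

Both systems are integrated with a fixed-step explicit forward Euler scheme,
the reference solver for this model family here. The grid is constructed to
contain every observation time exactly (`dt` must divide the sampling
interval), so no interpolation convention is needed. Components driven below
zero by a step are clamped to zero (counts are non-negative); clamp events
are logged at debug level. Interventions switch parameters at the start of
the first step whose time is ≥ the treatment time (left-continuous), so the
state is continuous at the switch.

The default `dt = 1e-3` day was chosen against the closed-form logistic
solution (the homotypic limit): at the assay's plating scales and rates
(~1/day) the relative error at day 4 is below 1e-3, and halving `dt` halves
the error (first-order convergence), which the tests verify over the ladder
{0.02, 0.01, 0.005}. A numba-jitted kernel evaluates batches of wells and
parameter vectors; it replicates the numpy reference kernel operation for
operation and a test asserts bit-identical results, with a transparent numpy
fallback when numba is absent.

## Likelihood

Observed counts are modelled as Gaussian around the deterministic model
trajectory with variance equal to the *model* population size — the √N
counting-noise assumption:

    log L(θ) = Σ [ −(x_exp − x_model)² / (2σ²) − ½ log(2πσ²) ],
    σ² = max(x_model, 1)

summed over conditions, replicates, observation days and both species. The
variance floor of 1 cell² prevents a degenerate likelihood at extinction;
both the floor and the model-vs-data width choice are exposed as
configuration. The normalisation term is kept because σ depends on the model
prediction: dropping it would bias cross-model comparison. Non-finite
trajectories yield −∞ (rejected by the sampler) rather than an exception.

Fitting uses the same `dt` as the forward simulation it is compared against.
This matters: at populations of 10⁵–10⁶ the √N noise is 0.1–0.3% relative,
smaller than the Euler bias at a coarser step, so fitting a `dt = 0.01`
solver to `dt = 1e-3` data visibly biases the parameter estimates. The
recovery experiment therefore generates and fits at `dt = 1e-3`; the
scaled-down model-selection experiment generates and fits at `dt = 0.02`.

## Priors and identifiability

Priors are independent uniforms on log10 scale — the natural "equally
compatible with competing hypotheses" choice for rates known only to an
order of magnitude. Defaults: `rho ∈ [1e-2, 1e1]` per day and
`k ∈ [1e-8, 1e-2]` per cell·day (bracketing carrying capacities 10²–10⁹
cells); `alpha, delta ∈ [1e-2, 1e1]`, `gamma ∈ [1e-9, 1e-3]`,
`r ∈ [1e-3, 1e3]`.

The resource model is exactly invariant under jointly rescaling
`(gamma_W, gamma_P, r_W, r_P, R0)`: the resource unit is unobservable. A
9-parameter posterior therefore contains a perfectly flat ridge on which
independent chains cannot ever satisfy a convergence diagnostic. The package
pins the unit by convention, `R0 = 1`, and infers the 8 identifiable rates;
supplying a prior that covers `R0` re-enables sampling it for users who want
the ridge explicitly.

## Sampler

The posterior is sampled with a differential-evolution Metropolis with
archive (DE-MC(Z)), the same algorithm family as the multiple-try
differential-evolution adaptive Metropolis used in this literature. Five
chains (default) propose `z* = z + γ (z_r1 − z_r2) + ε`, with `z_r1, z_r2`
drawn from the shared archive of past states, subspace crossover masks (CR ∈
{1/3, 2/3, 1}), `γ = 2.38/√(2 d')` jittered by U(0.5, 1.5) with `d'` the
number of updated dimensions, and 10% full-dimension `γ = 1` mode-hopping
moves. Moves are made on the prior's log10 scale, where the posterior is the
likelihood restricted to a box. During burn-in (first 50% of each chain,
discarded), the DREAM family's standard outlier-chain correction is applied:
chains whose recent mean log-likelihood is an inter-quartile-range outlier,
or sits more than 10 log-likelihood units below the best chain (posterior
odds < e⁻¹⁰, i.e. negligible mass), are moved to the best chain's state.
After burn-in chains evolve untouched. Every entry point takes an explicit
seed and is reproducible bit for bit.

Convergence is assessed with the classic (non-split) Gelman–Rubin potential
scale reduction per parameter, computed on the sampling scale, with the
conventional threshold R̂ < 1.2 across chains.

## Posterior analyses

* **Hypothesis tests** report the fraction of posterior draws satisfying an
  inequality such as `rho_P > rho_W`, plus the posterior distribution of the
  bounded relative difference `(p2 − p1)/(p2 + p1)` oriented so positive
  values agree with the inequality. No multiplicity correction is applied;
  raw posterior fractions are reported.
* **Prediction bands** select draws with likelihood above 90% of the sampled
  maximum (log-likelihood within log 0.9 ≈ −0.105 of the max), simulate
  each, and return the pointwise min/max envelope with the
  maximum-likelihood trajectory. For sharply peaked posteriors this retained
  set shrinks toward the single best draw — the band then degenerates to
  (nearly) the ML trajectory and is *not* a credible band: a parameter value
  one posterior standard deviation away typically sits several
  log-likelihood units below the maximum, far outside the 0.105 window. The
  band is a likelihood-plateau visualisation, informative exactly when the
  likelihood surface is flat; with fewer than two retained draws the
  function warns and returns the ML trajectory alone.
* **Model comparison** fits both models to the identical dataset with the
  identical likelihood and compares the full per-draw log-likelihood
  distributions and their maxima; the higher maximum wins. No information
  criterion is computed (the models have different parameter counts; the
  observed margins, 10³–10⁶ log-likelihood units, make penalty terms
  irrelevant). If either fit fails the R̂ gate the comparison is refused;
  an optional bounded retry refits an unconverged model with doubled chain
  length and a fresh derived seed, which cannot bias the winner.
* **Experiment design** scores candidate platings by posterior-predictive
  disagreement: the summed variance across posterior draws of predicted
  counts over the candidate's observation days. High-scoring conditions are
  those the current posterior cannot predict, hence most informative to run
  next. Ties break by condition id.

## Synthetic data

Raw counts from these assays are not bundled, so all experiments run on
synthetic data with the assumed statistical structure: deterministic model
trajectories observed daily over 4 days in 3 replicate wells (1 in the
scaled-down model-selection experiment), with independent Gaussian noise of
standard deviation √N, rounded to whole cells and floored at zero. Day-0
records report the plated counts exactly, as a seeding census would.
Species not plated in a condition are not recorded. The generator's variance
calibration (empirical variance ≈ model value within 10% at 10⁴ replicates)
and the negligibility of the zero-truncation bias above ~100 cells are
asserted in tests.

Plating designs: the core triplet (0.8×10⁵ separate cultures of each line,
0.4+0.4×10⁵ co-culture); a 24-condition grid crossing total densities
{0.16, 0.8, 2, 10}×10⁵ with W:P mixes {1:0, 0:1, 1:1, 2:1, 1:3, 1:10} — the
grid's membership is this package's stand-in for an unenumerated design, and
downstream results depend only on its information content; a ratio series
(1:1 to 1:10); and a rescue series (doxycycline from days 0, 2, 3 plus
untreated).

What the generator does *not* emulate: replicate-level batch effects,
counting-instrument error beyond √N, plating-number variation (day-0 counts
are exact), multiplicative noise at large N (an optional extension knob,
off by default), media changes, or any spatial structure. Passing recovery
tests therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to real-data misspecification.

## Reference experiments and problem sizes

* **Parameter recovery** (the core validation): truth `rho_W = 0.9`,
  `rho_P = 1.1` per day, `k_WW = k_PP = k_PW = 0.9/2×10⁵` (carrying capacity
  2×10⁵ cells) and `k_WP = 3 k_WW`; 24-condition grid × 3 replicates;
  5 chains × 12000 iterations at `dt = 1e-3`. All six 95% credible intervals
  cover the truth, the posterior fractions for `rho_P > rho_W` and
  `k_WP > k_WW` exceed 0.99, and the median relative difference between
  `k_PP` and `k_PW` stays within ±0.1 — the asymmetric-super-competitor
  signature with no spurious asymmetry.
* **Model selection**: datasets from each truth (direct: recovery truth;
  resource: `alpha = 0.9/1.1`, `delta = 2`, `gamma = 5e-7`, `r_W = 0.3`,
  `r_P = 0.05`, `R0 = 1`, chosen so the nutrient runs out inside the 4-day
  window and produces the characteristic growth-then-collapse curves) on the
  core platings, 1 replicate, `dt = 0.02`; 10 dataset seeds per direction;
  direct fits use 15000 iterations, resource fits 120000 on direct-model
  data (the rugged misfit posterior) and 40000 on resource-model data, each
  with up to two convergence retries. The generating model wins by thousands (direct data)
  to millions (resource data) of log-likelihood units.
* **Rescue**: at the recovery truth, treating from day 0 with both
  asymmetries removed makes the W and P trajectories identical (bitwise, for
  equal platings); the final wild-type count is monotone non-increasing in
  the treatment day over {0, 1, 2, 3}; and the full rescue strictly beats
  both single-asymmetry counterfactuals, with the untreated well the
  minimum. "Rescue success" is quantified as the final-day fold changes
  W(4)/W(0) and P(4)/P(0) in the same well — a metric of this package.

## Numerical choices and degenerate inputs

Tolerances: solver–oracle agreement 1e-3 relative; likelihood–oracle
agreement 1e-10 relative. Ties in condition ranking break by id. A
point-collapsed prior returns the prior (proposal jitter scales with each
dimension's prior extent, so degenerate boxes remain samplable). Empty
datasets, unknown species tokens, duplicate records, negative counts,
non-divisible `dt`, and out-of-range intervention days are rejected with
named errors; numerical overflow during integration raises an error naming
the offending time, while inside the likelihood it returns −∞.

## Known limitations

The two-species, well-mixed ODE description ignores spatial structure and
neighbourhood composition, which the underlying biology implicates; no
stochastic birth–death version is provided. The likelihood treats rounded
counts as continuous Gaussians. The Heaviside resource model makes the
likelihood discontinuous in parameters, which produces rugged misfit
posteriors (hence the convergence retries). Prediction bands follow the
>90%-of-maximum-likelihood convention and should not be read as credible
intervals (see above). Inferred parameter values are comparable across runs
of this package but are not calibrated against any external dataset.
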