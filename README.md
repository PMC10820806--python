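# cocult

Population dynamics of cell competition in co-culture: Lotka–Volterra
modelling and Bayesian inference for wild-type vs p53-null embryonic stem
cell growth curves.

## The problem

When mouse embryonic stem cells exit pluripotency, cells lacking the tumour
suppressor p53 behave as *super-competitors*: grown alone they do only
slightly better than wild-type cells, but in co-culture they drive the
elimination of their wild-type neighbours. Growth curves alone confound two
very different explanations — a direct, neighbour-dependent killing
interaction versus passive competition for a shared nutrient. `cocult` is a
library for teasing these apart quantitatively: it fits mechanistic ODE
models to replicate growth-curve data, tests hypotheses about the fitted
rates, compares the competing mechanisms, and simulates rescue
interventions.

## The models

Direct competition (two-species Lotka–Volterra), counts per well:

    dW/dt = W (ρ_W − k_WW W − k_WP P)
    dP/dt = P (ρ_P − k_PP P − k_PW W)

with intrinsic net growth rates ρ_i (per day) and competition strengths
`k_{affected,effector}` (per cell·day). Super-competition is the asymmetry
`k_WP > k_WW` with `ρ_P > ρ_W`.

Resource competition, the rival mechanism: a shared nutrient R is depleted
at per-cell rates γ_i, and a species starves (apoptotic rate δ_i switches
on) once R falls below its characteristic concentration r_i.

Inference uses the population-scaled Gaussian likelihood (observation s.d. =
√N, the counting-noise law), uniform log10 priors, and a DREAM-style
differential-evolution MCMC with 5 chains and the Gelman–Rubin R̂ < 1.2
convergence gate. Full details and design rationale: `docs/methods.md`.

## Worked example

```python
import cocult as cc

truth = cc.recovery_truth()                      # known generating rates
conds = cc.default_conditions("paper_core")      # 0.8e5 alone x2 + 0.4+0.4e5 co
data  = cc.generate(cc.GeneratorSpec(truth=truth, conditions=conds,
                                     replicates=3, seed=1))

fit = cc.sample_posterior("direct", data, conds,
                          n_chains=5, n_iter=8000, seed=2, dt=0.01)
print(cc.gelman_rubin(fit).converged)
for q in ("rho_P > rho_W", "k_WP > k_WW", "k_PP > k_PW"):
    h = cc.hypothesis_probability(fit, q)
    print(q, h.fraction, round(h.median_rel_diff(), 3))
```

prints (seed 1, as above):

```
True
rho_P > rho_W 1.0 0.107
k_WP > k_WW 1.0 0.503
k_PP > k_PW 0.505 0.0
```

Reading: the posterior is certain the mutant grows intrinsically faster and
suppresses the wild type more strongly than the wild type suppresses itself
(median relative differences (p2−p1)/(p2+p1) of +0.11 and +0.50 — the
generating truth has ρ ratio 1.1/0.9 and k_WP = 3 k_WW, i.e. true relative
differences 0.1 and 0.5), while the two suppressions *of* the mutant are
indistinguishable (fraction ≈ 0.5, relative difference ≈ 0) — exactly the
asymmetric super-competitor signature, with no spurious asymmetry.

The `examples/` scripts walk through each capability: growth-curve
simulation, fitting and hypothesis testing, model comparison, rescue
counterfactuals, and experiment design. A thin CLI mirrors the pipeline
(`cocult simulate | fit | compare | hypotheses | band | rescue |
rank-conditions`).

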