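"""Discriminate direct competition from resource competition.

Growth curves are simulated from the direct Lotka-Volterra model and both
candidate mechanisms are fitted to the same data with the identical
population-scaled Gaussian likelihood.  The direct model should win by a
wide margin of maximum log-likelihood: shared-nutrient depletion produces
kinked exponential-growth-then-collapse curves that cannot mimic smooth
logistic-like saturation.
"""

import cocult as cc

conditions = cc.default_conditions("paper_core")
dataset = cc.generate(
    cc.GeneratorSpec(
        truth=cc.recovery_truth(), conditions=conditions, replicates=1,
        seed=2, dt=0.02,
    )
)

comparison = cc.compare_models(
    dataset,
    conditions,
    seed=15,
    n_iter={"direct": 15000, "resource": 120000},
    dt=0.02,
    max_retries=2,
)

print(f"max log-likelihood, direct model:   {comparison.max_direct:12.1f}")
print(f"max log-likelihood, resource model: {comparison.max_resource:12.1f}")
print(f"difference (direct - resource):     {comparison.delta_max:12.1f}")
print(f"winner: {comparison.winner}")

print("\nA positive difference of thousands of log-likelihood units means the")
print("resource model is overwhelmingly rejected on these data; both fits")
print("passed the Gelman-Rubin R-hat < 1.2 gate, so the comparison is fair.")
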