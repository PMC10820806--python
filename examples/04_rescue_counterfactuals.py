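"""BCL2-rescue simulations: when must treatment start, and what must change?

Doxycycline-induced BCL2 makes the wild type resistant to elimination, which
the model represents as instantaneously restoring the wild-type parameters to
the p53-null ones (rho_W <- rho_P and k_WP <- k_WW).  Two questions:

1. How does the final wild-type count depend on the treatment day?
2. Is removing only the growth asymmetry, or only the competition asymmetry,
   enough to rescue?  (The counterfactual decomposition.)
"""

import cocult as cc

truth = cc.recovery_truth()
co = cc.Condition(id="co", W0=4e4, P0=4e4)

print("treatment day vs final wild-type count (full rescue):")
for day in (0.0, 1.0, 2.0, 3.0):
    tr = cc.simulate_rescue(truth, co, dox_day=day, mode="full", dt=1e-3)
    print(f"  dox from day {day:.0f}:  W(4 d) = {tr.W[-1]:>9.0f} cells")
untreated = cc.simulate_rescue(truth, co, dox_day=0.0, mode="untreated", dt=1e-3)
print(f"  untreated:      W(4 d) = {untreated.W[-1]:>9.0f} cells")

print("\ncounterfactual decomposition (treatment from day 0):")
table = cc.rescue_decomposition(truth, co, dox_day=0.0, dt=1e-3)
print(table.to_string(index=False,
                      float_format=lambda v: f"{v:,.1f}"))

print("\nEarlier treatment rescues more wild-type cells, and neither")
print("single-asymmetry counterfactual reaches the full rescue: both the")
print("intrinsic-growth and the competition asymmetry must be removed.")
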