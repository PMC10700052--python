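"""Balanced-selection designs: f_G = 1 drifts away from q0, f_E = 1 does not.

Runs 2n generations (n=7) of exactly balanced selection from frequency 0.5
at the reduced 50,000-replicate preset and reports whether the mean final
frequency returns to 0.5.
"""

import effsel as es

for scenario, label in [
    ("block_fg1", "f_G=1 block (5/6 then 6/5)"),
    ("alternating_fg1", "f_G=1 alternating"),
    ("linear_fg1", "f_G=1 block, linear update"),
    ("block_fe1", "f_E=1 (Δs −0.045 then +0.045)"),
]:
    res = es.run_fg1_fe1_experiment(scenario, n_values=[7], reps=50_000, seed=0)
    row = res.table.iloc[0]
    print(f"{label:34s} mean q_14 = {row['mean_final_freq']:.5f} "
          f"(p = {row['p_value']:.3g}, discarded {row['n_discarded']})")
print()
print("only the f_G=1 designs under the real (nonlinear) update drift below")
print("0.5; the f_E=1 schedule and the linearized control stay on target.")
print("(the alternating bias is small; its significance needs the full")
print("500,000-replicate scale.)")
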