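"""Simulate the three size-control rules and measure their slope signatures.

Each rule leaves a distinct fingerprint in the regression of division
volume on birth volume: a sizer forgets birth size (slope 0), an adder
adds a fixed volume (slope 1), and a timer doubles whatever it was born
with (slope 2 at steady state).  Noise blurs but does not erase the
fingerprint.
"""

import math

import numpy as np

import cyanocycle as cc

for rule in ("sizer", "adder", "timer"):
    trig = {"sizer": 2.0, "adder": 1.0, "timer": math.log(2) / 0.055}[rule]
    spec = cc.ModelSpec(rule, trig, trigger_cv=0.1, asym_sd=0.033,
                        growth_rate_mean=0.055, growth_rate_cv=0.1, seed=1)
    mean, sd = cc.simulated_slope_distribution(
        spec, "Vd_vs_Vb", n_replicates=50, cells_per_replicate=278)
    print(f"{rule:>6s}: ideal slope {cc.ideal_model_slope(rule):+.0f}, "
          f"simulated {mean:+.2f} ± {sd:.2f}  "
          f"(50 replicates of 278 cycles, modest noise)")

print()
print("Each line compares the analytic noise-free slope with the slope")
print("measured from stochastic lineage simulations: the rules remain")
print("separable at realistic noise levels and sample sizes.")
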