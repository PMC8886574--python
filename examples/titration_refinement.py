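"""Recover stability constants from a simulated spectrophotometric titration.

Simulates a 60-point multiwavelength titration of the Fe(III)/6a system
across the full measured p[H] window (-0.4 to 12) with 0.002 AU noise,
then refines the three complex constants by variable projection starting
0.5 log units away from the truth.
"""

import numpy as np

from equichel import (SyntheticSpec, format_with_uncertainty, gen_titration,
                      load_model, refine_constants)

system = load_model("fe_6a_water")
truth = {"FeL": 10.38, "FeL2": 18.1, "FeL3": 23.85}
colored = ["L", "LH", "LH2", "FeL", "FeL2", "FeL3"]

spec = SyntheticSpec(seed=42, design="full")
dataset, _ = gen_titration(spec, system, n_points=60)
print(f"simulated {dataset.n_points}-point titration, "
      f"{dataset.wavelengths.size} wavelengths, noise 0.002 AU")

start = {name: value + 0.5 for name, value in truth.items()}
result = refine_constants(dataset, system, list(truth),
                          initial_log_beta=start, absorbers=colored)

print("\nspecies   true    start   refined")
for name, value in truth.items():
    fitted, sd = result.refined_log_beta[name]
    print(f"{name:8s} {value:6.2f}  {start[name]:6.2f}   "
          f"{format_with_uncertainty(fitted, sd)}")
print(f"\nsigma_fit = {result.sigma_fit:.4f} AU (injected noise 0.0020 AU)")
print("Each constant returns to within a few 0.01 log units of the truth;")
print("the parenthesised digit is one standard deviation on the last place.")
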