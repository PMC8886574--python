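"""Speciation of the Fe(III)/6a system: who holds the iron at pH 7.4?

Loads the packaged aqueous model for ligand 6a (1-hydroxy-5,6-dimethyl-
pyrazin-2(1H)-one), solves the mass balances at physiological pH, and
prints the species distribution and side-reaction coefficients.
"""

import math

import numpy as np

from equichel import (alpha_coefficient, load_model,
                      solve_free_concentrations, species_distribution)

system = load_model("fe_6a_water")
totals = {"Fe": 1e-9, "L": 1e-4}

state = solve_free_concentrations(system, totals, pH=7.4)
print(f"{system.label}: totals Fe = {totals['Fe']:.1e} M, L = {totals['L']:.1e} M, pH 7.4")
print(f"free [Fe3+] = {state.free['Fe']:.3e} M, free [L-] = {state.free['L']:.3e} M")
print("\niron-containing species (fraction of total Fe):")
for sp in system.species:
    if sp.n_metal:
        frac = sp.n_metal * state.species_conc[sp.name] / totals["Fe"]
        if frac > 1e-4:
            print(f"  {sp.name:10s} {frac:7.2%}")

# hydrolysis competition in one number: the side-reaction coefficient
a_fe = alpha_coefficient(system, "Fe", 7.4)
a_l = alpha_coefficient(system, "L", 7.4)
print(f"\nlog alpha_Fe(OH) at pH 7.4 = {math.log10(a_fe):.2f} "
      "(hydroxide competition the ligand must beat)")
print(f"alpha_L(H) at pH 7.4 = {a_l:.4f} (ligand almost fully deprotonated)")

# ligand-only distribution: the protonation crossing sits at the pKa
df = species_distribution(system, {"Fe": 0.0, "L": 1.54e-4},
                          np.arange(2.0, 12.0 + 1e-9, 0.05))
i = (df["L"] - df["LH"]).abs().idxmin()
print(f"\nL/LH crossing at pH {df['pH'][i]:.2f} (pKa of the N-hydroxyl group)")
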