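# Methods

`equichel` computes the solution-equilibrium and assay quantities used
to profile bidentate O,O-donor iron(III) chelators of the
hydroxypyridinone/hydroxypyrazinone family: speciation at fixed pH,
species-distribution curves, sequestration diagrams with pL0.5,
refinement of protonation and stability constants from multiwavelength
titration spectra, and the reductions for DPPH, TEAC and shake-flask
assays.

## Equilibrium model

A `ChemicalSystem` is defined over the component basis (M, L, H): one
metal, one ligand, the proton. Every species M_mL_lH_h carries a
cumulative formation constant on the concentration scale,

    beta_mlh = [M_m L_l H_h] / ([M]^m [L]^l [H]^h).

Conventions and assumptions:

* **pH is −log10[H+] on the concentration scale.** Glass electrodes in
  this kind of work are calibrated as hydrogen-concentration probes, so
  no activity correction is applied to the proton. The proton is
  treated as buffered/measured: it is fixed at 10^−pH, never
  mass-balanced.
* **Hydroxo species carry negative proton stoichiometry** (Fe(OH)²⁺ is
  (1, 0, −1)), so the solvent pKw (13.77 in water, 14.42 in MeOH/H₂O
  80/20 w/w) is metadata only and never enters the solver.
* **Constants are used as reported at I = 0.1 M, 25 °C.** No
  Davies/SIT activity model, no van 't Hoff temperature adjustment.
* **No solid phases.** Fe(OH)₃ precipitation is not modelled. At the
  trace-metal level used for sequestration work (total Fe(III) =
  10⁻⁹ M) the aqueous hydrolysis model alone reproduces the reported
  aqueous pL0.5 values; titration fitting is meant for
  pre-precipitation data, which is also how such data are collected.
* Polynuclear hydroxides (Fe₂(OH)₂, Fe₃(OH)₄) are kept in the full
  solver — their contribution is concentration-dependent — but the
  `alpha_coefficient` convenience function is mononuclear-only by
  construction and documented as such.
* Constants only estimated in the source data (printed with "~") are
  used at face value and flagged `approximate`; at pH 7.4 they are
  numerically irrelevant.

Six ready-made systems are packaged as JSON under `equichel/data/`:
the aqueous Fe(III) models for ligands 6a and 11a, the mixed-solvent
models for 10a, 6c and 6d (6d with protonated complexes FeLH, FeL₂H₂,
FeL₃H₃, since its phenol stays protonated over the measured window),
the water-only protonation model for 10a, and both hydroxide sets.

## Speciation solver

`solve_free_concentrations` iterates Newton steps on (ln[M], ln[L])
with the analytic Jacobian of the two mass balances. Log-space
iteration keeps concentrations positive over the ~30 orders of
magnitude that trace-metal hydrolysis problems span. Numerical
choices:

* step clipping at ±2 log units per iteration, with backtracking on
  the max relative residual;
* convergence at max relative mass-balance residual ≤ 1e−12,
  iteration cap 200;
* a stall detector (five consecutive non-improving damped steps)
  catches the rank-degenerate Jacobian that arises when a single
  polydentate complex dominates both balances, and hands over to a
  nested-bisection fallback: outer bracketing on ln[M] with an inner
  bracket on ln[L], monotone because all metal/ligand stoichiometries
  are non-negative;
* reported concentrations are floored at 1e−30 M to avoid log(0);
  the fallback bracket reaches 40 decades below that floor because
  strong binding can push a trace component's free concentration far
  under its total;
* components with zero analytical total are excluded from the
  iteration and reported at the floor.

The converged state is unique for these mass-action systems, so the
answer is independent of the starting point; the test suite checks
agreement to 1e−8 across randomized initialisations, and agreement
with an independently written nested-bracketing oracle to 6
significant figures.

## Sequestration diagrams and pL0.5

χ_M is the mole fraction of total metal bound in species containing at
least one ligand (weighted by n_M, which matters only if polynuclear
mixed species are added). pL = −log10 c_L uses the **total** ligand
concentration — free in all protonation states plus metal-bound. That
convention makes the toy 1:1 system with log β = 20 and c_M = 10⁻⁹ M
come out at pL0.5 = −log10(5.00×10⁻¹⁰ + 10⁻²⁰) ≈ 9.30: at the midpoint
the bound ligand dominates the total.

The primary pL0.5 estimate is root bracketing of χ_M − 0.5 over pL ∈
[0, 14] (resolved to better than 1e−4 pL); the Boltzmann-type sigmoid

    chi(pL) = 1 / (1 + 10^(slope * (pL − pL0.5)))

is fitted by least squares as a cross-check, since the literature
convention extracts pL0.5 from exactly such a sigmoid. The default
conditions are the standard comparison point: pH 7.4, total Fe(III)
10⁻⁹ M, grid pL 0→14.

Reproduction of the reported values: the aqueous systems land on the
printed numbers (6a 4.357 vs 4.36; 11a 3.132 vs 3.13), as does 10a in
mixed solvent (3.973 vs 3.95). For 6c (5.987 vs 5.98) and 6d (7.474 vs
7.34) the bare model deviates by up to ~0.15; the source of the 6d
offset is not resolvable from the printed constants alone (it may
involve additional solvent-specific species or the fit-based
extraction used there), so the tests hold these two to ±0.25 and the
others to ±0.05. Whether polynuclear hydroxides were retained at
trace metal in the original calculations is unstated; they are
included here, where they are negligible at 10⁻⁹ M Fe.

## Titration simulation and constant refinement

The forward model is Beer–Lambert superposition over the absorbing
species (free metal, free ligand, every complex):
A(i, λ) = path · Σ_k ε(k, λ) · c(i, k), with per-point analytical
totals already corrected for titrant dilution by the caller (no
burette model is included).

`refine_constants` re-implements the global multiwavelength refinement
workflow: **variable projection** eliminates the molar absorptivities
exactly at each trial of the log β vector (per-wavelength linear least
squares, nonnegative by default via NNLS), and the outer damped
least-squares iteration (trust-region, central-difference derivatives,
relative step 1e−5) only sees the small nonlinear problem. Joint
optimisation over ε and β would be orders of magnitude larger and
worse conditioned. Standard deviations come from the Gauss–Newton
covariance at the optimum and are formatted in the last-digit
convention, e.g. `4.58(4)`. Nonnegative ε can be disabled for
difference-spectrum dialects; whether the original fits constrained ε
or co-refined the acidic batch and direct titrations jointly is
unstated, so both switches are exposed. The rank of an absorbance
matrix (number of absorbing species) is estimated from its singular
values: values above 10× the median of the trailing half are counted,
backstopped by a relative floor of 1e−10 of the leading value so
noiseless matrices behave; the factor is an overridable heuristic.

**Identifiability.** Two species whose concentration profiles are
collinear across a design cannot be refined separately; the fit warns
when any pairwise profile correlation exceeds 0.999 or the normalised
concentration matrix is ill-conditioned. This is not hypothetical: on
a direct titration restricted to pH 2–12, the FeL profile of the
6a-type system correlates at 0.9975 with LH₂ and FeL never exceeds
~6% of total iron, leaving log β(FeL) effectively undetermined (its
profile-likelihood spread is ~0.3 log units) — which is precisely why
such systems are measured down to p[H] ≈ −0.4 with a batch series.
The recovery simulations therefore use a single 60-point design
spanning p[H] −0.4 to 12, the union of the two windows such studies
measure; on it all three complex constants return to within ±0.01 of
truth at 0.002 AU noise, and the ligand pKa to ±0.02.

## Synthetic data

The generators produce the statistical structure the analyses assume,
deterministically per seed:

* **Titrations**: Gaussian-band species spectra (ε_max 10³–10⁴
  M⁻¹cm⁻¹, widths 20–60 nm) on a 250–800 nm grid (2 nm step); every
  metal–ligand complex carries a band inside the 450–650 nm window —
  the LMCT signature that signals Fe(III) complexation — while the
  aquo ion and pure hydroxo species are treated as non-absorbing.
  Additive Gaussian absorbance noise (default 0.002 AU) models
  instrument-dominated error. Default totals: ligand 2.5×10⁻⁴ M with
  0.3 equivalents of Fe(III) for complexation designs, matching
  common practice for 1:3 systems. Designs: direct pH 2–12 (step
  0.15), batch p[H] −0.4–2 (step 0.2), or the full union window.
* **Assay curves**: multiplicative log-normal noise on concentrations
  (pipetting-dominated error). The DPPH generator draws a saturating
  hyperbola through 50% at the true EC50 over a 0.01–0.1 mg/mL series;
  the shake-flask generator splits a total concentration according to
  10^logD.

What the generators do **not** emulate — and hence what passing
recovery tests do not establish about real data: electrode drift and
calibration error, baseline/turbidity wander, precipitation onset at
high pH, spectral band asymmetry, and correlated (non-iid) noise.
Real titrations also have uncertainty in the analytical totals, which
the refinement treats as exact.

## Assay reductions

* DPPH scavenging is exactly (A_c − A_t)/A_c × 100; pro-oxidant
  (negative) readings are returned as measured and flagged, never
  clamped.
* EC50 is read by bracketing linear interpolation between measured
  points (an exact 50% measurement is returned as-is); no 4-parameter
  logistic is imposed because screening tables report single
  steady-state crossings. The curve must be monotone after 3-point
  median smoothing. Mass→molar conversion divides by the molar mass
  (mg/mL ≡ g/L), with display rounding to 2 significant figures and
  the raw value retained for chaining.
* TEAC is the ratio of inhibition-vs-concentration slopes
  (compound/Trolox) at a common time point, by ordinary least squares
  **with** an intercept — the plots are linear but not forced through
  the origin.
* log D = log10(C_organic/C_aqueous), both phases required positive.

## Problem sizes and scope

Default numerical sizes were chosen so every routine answers in
seconds on one core: sequestration grids of 701–1401 points, bisection
to 1e−6 pL, recovery simulations of 60 titration points × 276
wavelengths × 10 seeds. Out of scope by design: activity-coefficient
models, precipitation/solubility equilibria, kinetics of radical
scavenging, multi-metal competition, automated stoichiometry-model
selection, and co-refinement of multiple datasets.
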