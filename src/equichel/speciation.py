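"""Mass-balance speciation at fixed pH.

Given analytical totals for metal and ligand and a measured pH, the free
concentrations [M] and [L] solve the two mass balances

    T_M = [M] + sum_s m_s beta_s [M]^m_s [L]^l_s [H]^h_s
    T_L = [L] + sum_s l_s beta_s [M]^m_s [L]^l_s [H]^h_s

with [H] = 10^-pH held fixed (the proton is buffered/measured, not mass
balanced).  The solver iterates Newton steps on (ln[M], ln[L]) with an
analytic Jacobian; log-space iteration keeps concentrations positive
across the ~30 orders of magnitude trace-metal hydrolysis problems span.
A nested-bisection continuation is used as fallback if Newton stalls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .system import ChemicalSystem, Species

__all__ = [
    "SpeciationState",
    "ConvergenceError",
    "solve_free_concentrations",
    "species_distribution",
    "alpha_coefficient",
    "CONC_FLOOR",
]

#: concentrations are floored here to avoid log(0); never reported as 0
CONC_FLOOR = 1e-30

_LN10 = math.log(10.0)


class ConvergenceError(RuntimeError):
    """Speciation solver failed; carries the last mass-balance residuals."""

    def __init__(self, message: str, residuals: Mapping[str, float] | None = None):
        super().__init__(message)
        self.residuals = dict(residuals or {})


@dataclass(frozen=True)
class SpeciationState:
    """Solved equilibrium state at one (totals, pH) condition."""

    system: ChemicalSystem
    pH: float
    totals: dict[str, float]
    free: dict[str, float]
    species_conc: dict[str, float]
    residuals: dict[str, float]

    def bound(self, component: str, predicate=None) -> float:
        """Total concentration of `component` carried by complex species.

        `predicate(species) -> bool` restricts which species count.
        """
        sys_ = self.system
        idx = {sys_.metal: 0, sys_.ligand: 1, sys_.proton: 2}
        if component not in idx:
            raise KeyError(f"unknown component {component!r}")
        i = idx[component]
        tot = 0.0
        for sp in sys_.species:
            if predicate is not None and not predicate(sp):
                continue
            n = sp.stoich[i]
            if n:
                tot += n * self.species_conc[sp.name]
        return tot


def _stoich_arrays(system: ChemicalSystem):
    n = len(system.species)
    nm = np.array([sp.n_metal for sp in system.species], dtype=float)
    nl = np.array([sp.n_ligand for sp in system.species], dtype=float)
    nh = np.array([sp.n_proton for sp in system.species], dtype=float)
    lb = np.array([sp.log_beta for sp in system.species], dtype=float)
    return nm.reshape(n), nl, nh, lb


def _species_log_conc(lnM, lnL, pH, nm, nl, nh, lb):
    # ln c_s = ln10*logbeta + m ln[M] + l ln[L] + h ln(10^-pH)
    return _LN10 * lb + nm * lnM + nl * lnL + nh * (-_LN10 * pH)


def solve_free_concentrations(
    system: ChemicalSystem,
    totals: Mapping[str, float],
    pH: float,
    *,
    initial_free: Mapping[str, float] | None = None,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> SpeciationState:
    """Solve the M/L mass balances at fixed pH.

    Parameters
    ----------
    totals
        Analytical totals keyed by component name (missing keys mean 0).
    pH
        -log10 of the free proton concentration (concentration scale).
    initial_free
        Optional starting free concentrations (used by the start-point
        independence checks); the converged answer does not depend on it.
    """
    if not math.isfinite(pH):
        raise ValueError("pH must be finite")
    tM = float(totals.get(system.metal, 0.0))
    tL = float(totals.get(system.ligand, 0.0))
    if tM < 0 or tL < 0:
        raise ValueError("analytical totals must be non-negative")

    nm, nl, nh, lb = _stoich_arrays(system)

    # active components take part in the Newton iteration
    active = [t > 0 for t in (tM, tL)]
    T = np.array([tM, tL])
    lnfree = np.array([
        math.log(tM) if active[0] else math.log(CONC_FLOOR),
        math.log(tL) if active[1] else math.log(CONC_FLOOR),
    ])
    if initial_free is not None:
        if system.metal in initial_free and active[0]:
            lnfree[0] = math.log(max(float(initial_free[system.metal]), CONC_FLOOR))
        if system.ligand in initial_free and active[1]:
            lnfree[1] = math.log(max(float(initial_free[system.ligand]), CONC_FLOOR))

    def residuals_at(lnf):
        lc = _species_log_conc(lnf[0], lnf[1], pH, nm, nl, nh, lb)
        c = np.exp(np.minimum(lc, 700.0))  # underflow to 0 is harmless
        calc = np.array([
            math.exp(lnf[0]) + float(nm @ c),
            math.exp(lnf[1]) + float(nl @ c),
        ])
        r = np.zeros(2)
        for i in range(2):
            if active[i]:
                r[i] = (calc[i] - T[i]) / T[i]
        return r, c

    r, c = residuals_at(lnfree)
    converged = float(np.max(np.abs(r))) <= tol
    it = 0
    stalls = 0
    while not converged and it < max_iter and stalls < 5:
        it += 1
        # analytic Jacobian of the scaled residuals wrt (ln[M], ln[L])
        J = np.zeros((2, 2))
        for i, (ni, act) in enumerate(zip((nm, nl), active)):
            if not act:
                J[i, i] = 1.0
                continue
            for j, njv in enumerate((nm, nl)):
                val = float((ni * njv) @ c)
                if i == j:
                    val += math.exp(lnfree[i])
                J[i, j] = val / T[i]
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -2.0 * _LN10, 2.0 * _LN10)
        for i in range(2):
            if not active[i]:
                step[i] = 0.0
        # backtracking on the residual norm; a step that cannot improve
        # even when heavily damped counts as a stall (near-singular J)
        norm0 = float(np.max(np.abs(r)))
        lam = 1.0
        for _ in range(40):
            trial = lnfree + lam * step
            r_new, c_new = residuals_at(trial)
            if float(np.max(np.abs(r_new))) < norm0 or lam < 1e-6:
                break
            lam *= 0.5
        stalls = stalls + 1 if float(np.max(np.abs(r_new))) >= norm0 else 0
        lnfree = lnfree + lam * step
        r, c = r_new, c_new
        converged = float(np.max(np.abs(r))) <= tol

    if not converged:
        lnfree = _nested_bisection(system, tM, tL, pH, nm, nl, nh, lb, active, lnfree)
        r, c = residuals_at(lnfree)
        if float(np.max(np.abs(r))) > 1e-10:
            raise ConvergenceError(
                f"speciation failed to converge at pH {pH:g} "
                f"(totals {system.metal}={tM:g}, {system.ligand}={tL:g})",
                {system.metal: float(r[0]), system.ligand: float(r[1])},
            )

    free = {
        system.metal: max(math.exp(lnfree[0]), CONC_FLOOR) if active[0] else CONC_FLOOR,
        system.ligand: max(math.exp(lnfree[1]), CONC_FLOOR) if active[1] else CONC_FLOOR,
        system.proton: 10.0 ** (-pH),
    }
    species_conc = {
        sp.name: max(float(ci), CONC_FLOOR)
        for sp, ci in zip(system.species, c)
    }
    residuals = {system.metal: float(r[0]), system.ligand: float(r[1])}
    return SpeciationState(system, float(pH), {system.metal: tM, system.ligand: tL},
                           free, species_conc, residuals)


def _nested_bisection(system, tM, tL, pH, nm, nl, nh, lb, active, lnfree):
    """Fallback: bisection on ln[M] with an inner bisection on ln[L].

    Both mass-balance functions are monotone in their own free
    concentration (all metal/ligand stoichiometries are non-negative),
    so nested bracketing always converges, if slowly.  The bracket
    reaches far below the reporting floor: strong binding can push a
    trace component's free concentration tens of decades under its
    total.
    """
    lo = math.log(CONC_FLOOR) - 40.0 * _LN10

    def calc_T(lnM, lnL):
        lc = _species_log_conc(lnM, lnL, pH, nm, nl, nh, lb)
        c = np.exp(np.minimum(lc, 700.0))  # underflow to 0 is harmless
        return math.exp(lnM) + float(nm @ c), math.exp(lnL) + float(nl @ c)

    def solve_L(lnM):
        if not active[1]:
            return math.log(CONC_FLOOR)
        hi = math.log(tL)
        f = lambda lnL: calc_T(lnM, lnL)[1] - tL
        if f(lo) >= 0:
            return lo
        return brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=300)

    if not active[0]:
        return np.array([math.log(CONC_FLOOR), solve_L(math.log(CONC_FLOOR))])

    hi = math.log(tM)
    g = lambda lnM: calc_T(lnM, solve_L(lnM))[0] - tM
    if g(lo) >= 0:
        lnM = lo
    else:
        lnM = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=300)
    return np.array([lnM, solve_L(lnM)])


def species_distribution(
    system: ChemicalSystem,
    totals: Mapping[str, float],
    pH_grid: Sequence[float],
    reference: str | None = None,
) -> "pandas.DataFrame":
    """Fractional abundances versus pH with respect to one component.

    Returns a DataFrame with a ``pH`` column, one column for the free
    reference component, and one per species containing it; at every pH
    the fractions sum to 1.
    """
    import pandas as pd

    grid = np.asarray(list(pH_grid), dtype=float)
    if grid.size and np.any(np.diff(grid) <= 0):
        raise ValueError("pH_grid must be strictly increasing")
    ref = reference or (system.ligand if totals.get(system.metal, 0.0) == 0
                        else system.metal)
    if ref not in (system.metal, system.ligand):
        raise KeyError(f"reference component must be {system.metal!r} or {system.ligand!r}")
    total_ref = float(totals.get(ref, 0.0))
    if total_ref <= 0:
        raise ValueError(f"reference component {ref!r} must have a positive total")

    idx = 0 if ref == system.metal else 1
    members = [sp for sp in system.species if sp.stoich[idx] > 0]
    rows = []
    for ph in grid:
        try:
            st = solve_free_concentrations(system, totals, ph)
        except ConvergenceError as exc:
            raise ConvergenceError(f"at pH {ph:g}: {exc}", exc.residuals) from exc
        row = {"pH": ph, ref: st.free[ref] / total_ref}
        for sp in members:
            row[sp.name] = sp.stoich[idx] * st.species_conc[sp.name] / total_ref
        rows.append(row)
    return pd.DataFrame(rows)


def alpha_coefficient(system: ChemicalSystem, component: str, pH: float) -> float:
    """Side-reaction coefficient alpha_X from mononuclear species only.

    alpha_X = ([X] + sum over X Y_h species) / [X]
            = 1 + sum 10^(log beta - n_H * pH),

    summed over species with exactly one X and none of the other
    exchanging component.  Polynuclear species are deliberately
    excluded; use the full solver where they matter.
    """
    if component == system.metal:
        sel = lambda sp: sp.n_metal == 1 and sp.n_ligand == 0
    elif component == system.ligand:
        sel = lambda sp: sp.n_ligand == 1 and sp.n_metal == 0
    else:
        raise KeyError(f"unknown component {component!r}")
    alpha = 1.0
    for sp in system.species:
        if sel(sp):
            alpha += 10.0 ** (sp.log_beta - sp.n_proton * pH)
    return alpha
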