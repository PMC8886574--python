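"""Sequestration diagrams and pL0.5.

chi_M is the mole fraction of total metal bound in metal-ligand
complexes, and pL = -log10 c_L with c_L the *total* ligand
concentration (free in all protonation states plus metal-bound).
pL0.5 is the pL at which chi_M = 0.5 for trace metal at fixed pH; it is
the field's conditional, like-for-like measure of sequestering power
(higher pL0.5 = the ligand does the same job at higher dilution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from .speciation import ConvergenceError, solve_free_concentrations
from .system import ChemicalSystem

__all__ = [
    "SequestrationCurve",
    "BoltzmannFit",
    "chi_complexed",
    "sequestration_diagram",
    "pl05_bisection",
    "fit_boltzmann",
    "DEFAULT_C_M",
    "DEFAULT_PH",
]

#: trace-metal condition used throughout: total Fe(III) 1e-9 M at pH 7.4
DEFAULT_C_M = 1e-9
DEFAULT_PH = 7.4


@dataclass(frozen=True)
class SequestrationCurve:
    pL: np.ndarray
    chi: np.ndarray
    c_M: float
    pH: float
    system_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "pL", np.asarray(self.pL, dtype=float))
        object.__setattr__(self, "chi", np.asarray(self.chi, dtype=float))
        if self.pL.shape != self.chi.shape:
            raise ValueError("pL and chi must have the same shape")


@dataclass(frozen=True)
class BoltzmannFit:
    """Sigmoid fit chi(pL) = 1 / (1 + 10^(slope*(pL - pL05)))."""

    pL05: float
    slope: float
    rss: float
    n_points: int


def chi_complexed(system: ChemicalSystem, c_M: float, c_L: float, pH: float) -> float:
    """Mole fraction of total metal bound in species containing ligand."""
    if c_M <= 0:
        raise ValueError("c_M must be positive")
    if c_L < 0:
        raise ValueError("c_L must be non-negative")
    if c_L == 0.0:
        return 0.0
    state = solve_free_concentrations(
        system, {system.metal: c_M, system.ligand: c_L}, pH
    )
    bound = state.bound(system.metal, predicate=lambda sp: sp.n_ligand >= 1)
    return min(max(bound / c_M, 0.0), 1.0)


def sequestration_diagram(
    system: ChemicalSystem,
    c_M: float = DEFAULT_C_M,
    pH: float = DEFAULT_PH,
    pL_min: float = 0.0,
    pL_max: float = 14.0,
    n_points: int = 1401,
) -> SequestrationCurve:
    """chi_M versus pL on a uniform grid at fixed pH and trace metal."""
    if not pL_min < pL_max:
        raise ValueError("pL_min must be < pL_max")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.linspace(pL_min, pL_max, n_points)
    chi = np.empty_like(grid)
    failures = []
    for i, pl in enumerate(grid):
        try:
            chi[i] = chi_complexed(system, c_M, 10.0 ** (-pl), pH)
        except ConvergenceError:
            chi[i] = np.nan
            failures.append(pl)
    if len(failures) > 0.01 * n_points:
        raise ConvergenceError(
            f"sequestration diagram rejected: {len(failures)}/{n_points} grid "
            f"points failed (first at pL={failures[0]:g})"
        )
    if failures:
        chi = np.asarray(
            np.interp(grid, grid[~np.isnan(chi)], chi[~np.isnan(chi)])
        )
    return SequestrationCurve(grid, chi, c_M, pH, system.label)


def pl05_bisection(
    system: ChemicalSystem,
    c_M: float = DEFAULT_C_M,
    pH: float = DEFAULT_PH,
    pL_bracket: tuple[float, float] = (0.0, 14.0),
    xtol: float = 1e-6,
) -> float:
    """pL at which chi_M crosses 0.5, by root bracketing.

    This is the primary pL0.5 estimate (the Boltzmann fit is the
    cross-check); it resolves the crossing to well below 1e-4 pL.
    """
    lo, hi = pL_bracket
    f = lambda pl: chi_complexed(system, c_M, 10.0 ** (-pl), pH) - 0.5
    f_lo, f_hi = f(lo), f(hi)
    if f_lo < 0 or f_hi > 0:
        raise ValueError(
            "ligand cannot sequester 50% at any concentration "
            f"<= {10.0 ** (-lo):g} M at pH {pH:g}"
        )
    return float(brentq(f, lo, hi, xtol=xtol))


def fit_boltzmann(curve: SequestrationCurve) -> BoltzmannFit:
    """Least-squares sigmoid fit of a sequestration curve.

    Requires the curve to actually traverse the transition (chi from
    >= 0.95 down to <= 0.05 over the grid).
    """
    chi = curve.chi
    if not (np.max(chi) >= 0.95 and np.min(chi) <= 0.05):
        raise ValueError(
            "curve must span chi >= 0.95 down to <= 0.05 to fit the sigmoid"
        )
    if float(np.max(chi) - np.min(chi)) < 0.5:
        raise ValueError("degenerate (flat) curve")

    def model(pl, pl05, slope):
        return 1.0 / (1.0 + 10.0 ** (slope * (pl - pl05)))

    i0 = int(np.argmin(np.abs(chi - 0.5)))
    p0 = (float(curve.pL[i0]), 1.0)
    popt, _ = curve_fit(model, curve.pL, chi, p0=p0, maxfev=10000)
    pl05, slope = float(popt[0]), float(popt[1])
    rss = float(np.sum((model(curve.pL, *popt) - chi) ** 2))
    if slope <= 0:
        raise ValueError("fitted slope is non-positive; curve is not sigmoidal")
    return BoltzmannFit(pl05, slope, rss, int(curve.pL.size))
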