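"""Multiwavelength titration datasets and stability-constant refinement.

The forward model is Beer-Lambert superposition: at titration point i
and wavelength j,

    A_ij = path * sum_k eps_kj * c_ik,

where c_ik are the equilibrium concentrations of the absorbing species
(free metal, free ligand and every complex) from the speciation solver.
Refinement uses variable projection: at each trial of the nonlinear
parameters (the free log beta values) the linear parameters (molar
absorptivities) are eliminated exactly by per-wavelength linear least
squares, optionally nonnegative; the outer damped least-squares
iteration then only sees the small nonlinear problem.  This is the
structure of the established multiwavelength refinement programs for
protonation/stability constants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from .speciation import ConvergenceError, solve_free_concentrations
from .system import ChemicalSystem

__all__ = [
    "TitrationDataset",
    "RefinementResult",
    "IdentifiabilityWarning",
    "absorber_names",
    "concentration_matrix",
    "beer_lambert_forward",
    "estimate_rank",
    "fit_epsilons",
    "refine_constants",
    "format_with_uncertainty",
]


class IdentifiabilityWarning(UserWarning):
    """Two species' concentration profiles are nearly collinear."""


@dataclass
class TitrationDataset:
    """Absorbance matrix with per-point analytical totals.

    Totals are dilution-corrected by the caller; the dataset carries no
    burette model.
    """

    pH: np.ndarray
    total_metal: np.ndarray
    total_ligand: np.ndarray
    wavelengths: np.ndarray
    absorbance: np.ndarray
    path_length_cm: float = 1.0
    label: str = ""

    def __post_init__(self):
        self.pH = np.asarray(self.pH, dtype=float)
        self.total_metal = np.asarray(self.total_metal, dtype=float)
        self.total_ligand = np.asarray(self.total_ligand, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        n = self.pH.size
        if n < 2:
            raise ValueError("a titration needs at least 2 points")
        if self.total_metal.shape != (n,) or self.total_ligand.shape != (n,):
            raise ValueError("totals must match the number of titration points")
        if self.absorbance.shape != (n, self.wavelengths.size):
            raise ValueError("absorbance matrix must be points x wavelengths")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.path_length_cm <= 0:
            raise ValueError("path length must be positive")

    @property
    def n_points(self) -> int:
        return int(self.pH.size)

    # CSV dialect: header row `pH,total_M,total_L,A_<wavelength>...`
    def to_csv(self, path) -> None:
        cols = {"pH": self.pH, "total_M": self.total_metal,
                "total_L": self.total_ligand}
        for j, wl in enumerate(self.wavelengths):
            cols[f"A_{wl:g}"] = self.absorbance[:, j]
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, path_length_cm: float = 1.0,
                 label: str = "") -> "TitrationDataset":
        df = pd.read_csv(path)
        acols = [c for c in df.columns if c.startswith("A_")]
        wl = np.array([float(c[2:]) for c in acols])
        order = np.argsort(wl)
        return cls(
            pH=df["pH"].to_numpy(),
            total_metal=df["total_M"].to_numpy(),
            total_ligand=df["total_L"].to_numpy(),
            wavelengths=wl[order],
            absorbance=df[acols].to_numpy()[:, order],
            path_length_cm=path_length_cm,
            label=label,
        )


@dataclass
class RefinementResult:
    refined_log_beta: dict[str, tuple[float, float]]  # name -> (value, sd)
    epsilon: np.ndarray  # absorbers x wavelengths
    absorbers: list[str]
    sigma_fit: float  # RMS residual, AU
    converged: bool
    n_iterations: int

    def summary(self) -> str:
        lines = [
            f"{name}: log beta = {format_with_uncertainty(val, sd)}"
            for name, (val, sd) in self.refined_log_beta.items()
        ]
        lines.append(f"sigma_fit = {self.sigma_fit:.4g} AU "
                     f"({'converged' if self.converged else 'NOT converged'}, "
                     f"{self.n_iterations} iterations)")
        return "\n".join(lines)


def absorber_names(system: ChemicalSystem) -> list[str]:
    """Column order of the absorbing-species basis: free M, free L, species."""
    return [system.metal, system.ligand] + [sp.name for sp in system.species]


def concentration_matrix(system: ChemicalSystem,
                         dataset: TitrationDataset) -> np.ndarray:
    """Equilibrium concentrations (points x absorbers) across the titration."""
    names = absorber_names(system)
    C = np.empty((dataset.n_points, len(names)))
    for i in range(dataset.n_points):
        st = solve_free_concentrations(
            system,
            {system.metal: dataset.total_metal[i],
             system.ligand: dataset.total_ligand[i]},
            dataset.pH[i],
        )
        C[i, 0] = st.free[system.metal]
        C[i, 1] = st.free[system.ligand]
        for k, sp in enumerate(system.species):
            C[i, 2 + k] = st.species_conc[sp.name]
    return C


def beer_lambert_forward(state_conc: np.ndarray, epsilon: np.ndarray,
                         path_length_cm: float = 1.0) -> np.ndarray:
    """A = path * C @ eps, with C points x species and eps species x wl."""
    if path_length_cm <= 0:
        raise ValueError("path length must be positive")
    C = np.atleast_2d(np.asarray(state_conc, dtype=float))
    E = np.atleast_2d(np.asarray(epsilon, dtype=float))
    if C.shape[1] != E.shape[0]:
        raise ValueError("concentration and epsilon dimensions disagree")
    return path_length_cm * (C @ E)


def estimate_rank(dataset: TitrationDataset, threshold_factor: float = 10.0) -> int:
    """Number of absorbing species by singular-value inspection.

    Counts singular values exceeding ``threshold_factor`` times the
    median of the trailing half of the spectrum (a noise-floor
    heuristic; override the factor for unusual designs).
    """
    s = np.linalg.svd(dataset.absorbance, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    # noise floor from the trailing half, backstopped by a relative
    # floor so noiseless (numerically zero-tailed) data behave
    noise_floor = threshold_factor * float(np.median(s[s.size // 2:]))
    return int(np.sum(s > max(noise_floor, s[0] * 1e-10)))


def _absorber_columns(system: ChemicalSystem,
                      absorbers: Sequence[str] | None) -> list[int] | None:
    if absorbers is None:
        return None
    names = absorber_names(system)
    cols = []
    for a in absorbers:
        if a not in names:
            raise KeyError(f"unknown absorber {a!r}")
        cols.append(names.index(a))
    if not cols:
        raise ValueError("at least one absorber is required")
    return cols


def fit_epsilons(
    dataset: TitrationDataset,
    system: ChemicalSystem,
    nonnegative: bool = True,
    conc: np.ndarray | None = None,
    absorbers: Sequence[str] | None = None,
) -> tuple[np.ndarray, float]:
    """Molar absorptivities by per-wavelength linear least squares.

    Returns ``(epsilon, residual)`` with epsilon of shape
    (absorbers x wavelengths) and residual the Frobenius norm of the
    misfit.  ``absorbers`` restricts which species are treated as
    coloured (default: all, including free metal and ligand); species
    known to be colourless are conventionally excluded to keep the
    linear step well determined.  Warns (but still fits) when the
    concentration matrix is ill-conditioned, i.e. species profiles are
    nearly collinear.
    """
    C = concentration_matrix(system, dataset) if conc is None else conc
    cols = _absorber_columns(system, absorbers)
    if cols is not None:
        C = C[:, cols]
    X = dataset.path_length_cm * C
    # collinearity check on norm-scaled, non-degenerate profiles (a
    # species that never forms is harmless to the linear fit)
    norms = np.linalg.norm(X, axis=0)
    live = norms > np.max(norms) * 1e-12 if norms.size else norms > 0
    if int(live.sum()) >= 2:
        cond = np.linalg.cond(X[:, live] / norms[live])
        if cond > 1e8:
            warnings.warn(
                f"concentration profiles nearly collinear (condition number "
                f"{cond:.3g}); molar absorptivities are poorly determined",
                IdentifiabilityWarning,
                stacklevel=2,
            )
    n_wl = dataset.wavelengths.size
    E = np.empty((X.shape[1], n_wl))
    if nonnegative:
        for j in range(n_wl):
            E[:, j], _ = nnls(X, dataset.absorbance[:, j])
    else:
        E, *_ = np.linalg.lstsq(X, dataset.absorbance, rcond=None)
    resid = float(np.linalg.norm(X @ E - dataset.absorbance))
    return E, resid


def _profile_correlation_check(C: np.ndarray, names: Sequence[str]) -> None:
    sd = C.std(axis=0)
    keep = sd > 0
    if keep.sum() < 2:
        return
    R = np.corrcoef(C[:, keep].T)
    kept = [n for n, k in zip(names, keep) if k]
    n = len(kept)
    for a in range(n):
        for b in range(a + 1, n):
            if abs(R[a, b]) > 0.999:
                warnings.warn(
                    f"concentration profiles of {kept[a]!r} and {kept[b]!r} "
                    f"are collinear (|r| = {abs(R[a, b]):.6f}); their "
                    "constants are not separately identifiable from this design",
                    IdentifiabilityWarning,
                    stacklevel=3,
                )


def refine_constants(
    dataset: TitrationDataset,
    system: ChemicalSystem,
    free_species: Sequence[str],
    initial_log_beta: Mapping[str, float] | None = None,
    nonnegative: bool = True,
    absorbers: Sequence[str] | None = None,
    max_iter: int = 100,
    ftol: float = 1e-8,
) -> RefinementResult:
    """Refine selected log beta values against a titration dataset.

    Variable projection: the residual at trial log beta values is the
    Beer-Lambert misfit after the exact inner epsilon fit; the outer
    minimisation runs damped least squares with central-difference
    derivatives on the log beta vector.  Standard deviations come from
    the Jacobian at the optimum.  ``absorbers`` names the coloured
    species (see :func:`fit_epsilons`).
    """
    free_species = list(free_species)
    if not free_species:
        raise ValueError("at least one species must be refined")
    for name in free_species:
        system.get(name)  # raises KeyError on unknown names
    start = np.array([
        float(initial_log_beta[name]) if initial_log_beta and name in initial_log_beta
        else system.get(name).log_beta
        for name in free_species
    ])
    if not np.all(np.isfinite(start)):
        raise ValueError("initial log beta values must be finite")

    names = absorber_names(system)
    cols = _absorber_columns(system, absorbers)
    fit_names = names if cols is None else [names[c] for c in cols]
    n_data = dataset.absorbance.size

    def residual_vector(x):
        trial = system.with_log_beta(dict(zip(free_species, x)))
        try:
            C = concentration_matrix(trial, dataset)
        except ConvergenceError:
            # reject the trial point: large residual sends the damped
            # step back toward the previous iterate
            return np.full(n_data, 1e3)
        if cols is not None:
            C = C[:, cols]
        E, _ = fit_epsilons(dataset, trial, nonnegative=nonnegative, conc=C)
        model = dataset.path_length_cm * C @ E
        return (model - dataset.absorbance).ravel()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IdentifiabilityWarning)
        sol = least_squares(
            residual_vector,
            start,
            jac="3-point",
            diff_step=1e-5,
            method="trf",
            ftol=ftol,
            xtol=1e-10,
            gtol=1e-12,
            max_nfev=max_iter * (2 * len(free_species) + 1),
        )

    final = system.with_log_beta(dict(zip(free_species, sol.x)))
    C = concentration_matrix(final, dataset)
    if cols is not None:
        C = C[:, cols]
    _profile_correlation_check(C, fit_names)
    E, _ = fit_epsilons(dataset, final, nonnegative=nonnegative, conc=C)
    sigma_fit = math.sqrt(2.0 * sol.cost / n_data)

    # 1-sigma uncertainties from the Gauss-Newton covariance at the optimum
    dof = max(n_data - len(free_species), 1)
    s2 = 2.0 * sol.cost / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
        sds = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        sds = np.full(len(free_species), np.nan)

    return RefinementResult(
        refined_log_beta={n: (float(v), float(s))
                          for n, v, s in zip(free_species, sol.x, sds)},
        epsilon=E,
        absorbers=fit_names,
        sigma_fit=sigma_fit,
        converged=bool(sol.status > 0),
        n_iterations=int(sol.nfev),
    )


def format_with_uncertainty(value: float, sd: float) -> str:
    """Format as value with 1 sigma on the last digit, e.g. ``4.58(4)``."""
    if not math.isfinite(sd) or sd <= 0:
        return f"{value:g}"
    exp = math.floor(math.log10(sd))
    digit = round(sd / 10.0 ** exp)
    if digit == 10:  # 0.096 -> 0.1
        digit, exp = 1, exp + 1
    decimals = max(-exp, 0)
    return f"{value:.{decimals}f}({digit:d})"
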