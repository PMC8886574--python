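"""Seeded synthetic data with the structure the analyses assume.

Titrations are generated by Beer-Lambert superposition of smooth
Gaussian-band species spectra over the equilibrium speciation, with
additive Gaussian absorbance noise (instrument-dominated error).
Metal-ligand complexes always carry a charge-transfer-like band in the
450-650 nm window, the visible signature of Fe(III) complexation by
O,O-donor chelators.  Assay concentrations get multiplicative
log-normal noise (pipetting-dominated error).  Every generator is a
pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assays import AssayCurve, dpph_scavenging
from .speciation import ConvergenceError, solve_free_concentrations
from .system import ChemicalSystem
from .titration import TitrationDataset, absorber_names, beer_lambert_forward

__all__ = [
    "SyntheticSpec",
    "TitrationTruth",
    "gen_epsilon_spectra",
    "gen_titration",
    "gen_dpph",
    "gen_shake_flask",
]


def _default_wavelengths() -> np.ndarray:
    return np.arange(250.0, 800.0 + 1e-9, 2.0)


@dataclass
class SyntheticSpec:
    """Design and noise parameters for the generators.

    Defaults mirror the titration protocols the analyses target: direct
    titration pH 2-12 in 0.15 steps (or strongly acidic batch series
    p[H] -0.4 to 2 in 0.2 steps), total ligand 2.5e-4 M with 0.3 equiv
    of metal for complexation designs, absorbance noise 0.002 AU, and
    band heights in the 1e3-1e4 /M/cm range typical of pi-pi* and
    charge-transfer transitions.
    """

    seed: int = 0
    noise_sd_absorbance: float = 0.002
    wavelengths: np.ndarray = field(default_factory=_default_wavelengths)
    design: str = "direct"  # "direct" (pH 2-12), "batch" (p[H] -0.4-2),
    # or "full" (p[H] -0.4-12, the union of the two measured windows)
    total_ligand: float = 2.5e-4
    metal_to_ligand_ratio: float = 0.3
    eps_max_range: tuple[float, float] = (1e3, 1e4)
    band_width_range: tuple[float, float] = (20.0, 60.0)
    lmct_window: tuple[float, float] = (450.0, 650.0)
    assay_conc_noise: float = 0.01

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.noise_sd_absorbance < 0:
            raise ValueError("noise sd must be >= 0")
        if self.design not in ("direct", "batch", "full"):
            raise ValueError("design must be 'direct', 'batch' or 'full'")

    def ph_grid(self) -> np.ndarray:
        if self.design == "direct":
            return np.arange(2.0, 12.0 + 1e-9, 0.15)
        if self.design == "batch":
            return np.arange(-0.4, 2.0 + 1e-9, 0.2)
        return np.arange(-0.4, 12.0 + 1e-9, 0.2)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TitrationTruth:
    """Ground truth paired with a generated titration."""

    log_beta: dict[str, float]
    epsilon: np.ndarray
    absorbers: list[str]
    concentrations: np.ndarray  # points x absorbers
    clean_absorbance: np.ndarray


def _gaussian_band(wl: np.ndarray, center: float, width: float,
                   height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((wl - center) / width) ** 2)


def gen_epsilon_spectra(
    spec: SyntheticSpec,
    system: ChemicalSystem,
    bands: Mapping[str, Sequence[tuple[float, float, float]]] | None = None,
) -> np.ndarray:
    """Molar absorptivity spectra (absorbers x wavelengths).

    Rows follow :func:`equichel.titration.absorber_names`.  With
    ``bands`` given explicitly, each entry is a list of
    (center_nm, width_nm, eps_max) Gaussian bands; otherwise bands are
    drawn from the spec's ranges: UV bands for ligand-containing
    absorbers, plus a guaranteed band inside the charge-transfer window
    for every metal-ligand complex.  The free metal aquo ion and pure
    hydroxo species are treated as non-absorbing.
    """
    rng = spec.rng()
    wl = spec.wavelengths
    names = absorber_names(system)
    E = np.zeros((len(names), wl.size))

    def draw_band(lo, hi):
        center = rng.uniform(lo, hi)
        width = rng.uniform(*spec.band_width_range)
        height = rng.uniform(*spec.eps_max_range)
        return center, width, height

    for row, name in enumerate(names):
        if bands is not None:
            for center, width, height in bands.get(name, ()):
                E[row] += _gaussian_band(wl, center, width, height)
            continue
        if name == system.metal:
            continue  # aquo ion: no significant band in this window
        if name == system.ligand:
            E[row] += _gaussian_band(wl, *draw_band(260.0, 380.0))
            continue
        sp = system.get(name)
        if sp.n_ligand == 0:
            continue  # hydroxo species: treated as non-absorbing
        E[row] += _gaussian_band(wl, *draw_band(260.0, 380.0))
        if sp.n_metal > 0:
            E[row] += _gaussian_band(wl, *draw_band(*spec.lmct_window))
    return E


def gen_titration(
    spec: SyntheticSpec,
    system: ChemicalSystem,
    epsilon: np.ndarray | None = None,
    n_points: int | None = None,
) -> tuple[TitrationDataset, TitrationTruth]:
    """Simulate a multiwavelength titration of the given system.

    Totals follow the spec (ligand 2.5e-4 M; 0.3 equiv metal when the
    system contains complexes, none otherwise).  Points where the
    speciation solver fails are dropped.  Returns the noisy dataset and
    the ground truth for recovery tests.
    """
    rng = spec.rng()
    if epsilon is None:
        epsilon = gen_epsilon_spectra(spec, system)
    names = absorber_names(system)
    if epsilon.shape != (len(names), spec.wavelengths.size):
        raise ValueError("epsilon shape must be absorbers x wavelengths")

    grid = spec.ph_grid()
    if n_points is not None:
        grid = np.linspace(grid[0], grid[-1], n_points)
    tL = spec.total_ligand
    tM = spec.metal_to_ligand_ratio * tL if system.complexes() else 0.0

    rows, kept_ph = [], []
    for ph in grid:
        try:
            st = solve_free_concentrations(
                system, {system.metal: tM, system.ligand: tL}, ph)
        except ConvergenceError:
            continue
        rows.append([st.free[system.metal], st.free[system.ligand]]
                    + [st.species_conc[sp.name] for sp in system.species])
        kept_ph.append(ph)
    C = np.array(rows)
    clean = beer_lambert_forward(C, epsilon, 1.0)
    noisy = clean + rng.normal(0.0, spec.noise_sd_absorbance, clean.shape)

    dataset = TitrationDataset(
        pH=np.array(kept_ph),
        total_metal=np.full(len(kept_ph), tM),
        total_ligand=np.full(len(kept_ph), tL),
        wavelengths=spec.wavelengths,
        absorbance=noisy,
        path_length_cm=1.0,
        label=f"synthetic {spec.design} titration of {system.label or 'system'}",
    )
    truth = TitrationTruth(
        log_beta={sp.name: sp.log_beta for sp in system.species},
        epsilon=epsilon,
        absorbers=names,
        concentrations=C,
        clean_absorbance=clean,
    )
    return dataset, truth


def gen_dpph(
    true_ec50: float,
    spec: SyntheticSpec,
    concentrations: np.ndarray | None = None,
    control_absorbance: float = 1.0,
) -> AssayCurve:
    """Simulate a DPPH dose-response series with a known EC50 (mg/mL).

    The clean response is the saturating hyperbola
    100 * c / (c + EC50), which passes through 50% at the true EC50;
    log-normal noise perturbs the realised concentrations.  The default
    series is 0.01-0.1 mg/mL in 10 steps, matching common protocols.
    """
    rng = spec.rng()
    if concentrations is None:
        concentrations = np.linspace(0.01, 0.1, 10)
    concentrations = np.asarray(concentrations, dtype=float)
    if not (concentrations[0] <= true_ec50 <= concentrations[-1]):
        raise ValueError("true EC50 must lie within the concentration range")
    actual = concentrations * np.exp(
        rng.normal(0.0, spec.assay_conc_noise, concentrations.size))
    responses = 100.0 * actual / (actual + true_ec50)
    A_t = control_absorbance * (1.0 - responses / 100.0)
    responses = np.array([dpph_scavenging(control_absorbance, a) for a in A_t])
    return AssayCurve(
        concentrations=concentrations,
        responses=responses,
        unit="mg/mL",
        control_absorbance=control_absorbance,
        sample_absorbances=A_t,
    )


def gen_shake_flask(true_log_d: float,
                    spec: SyntheticSpec,
                    total_conc: float = 1e-4) -> tuple[float, float]:
    """Simulate one shake-flask partition: (C_organic, C_aqueous).

    The phases split according to 10^log D and each measured
    concentration carries multiplicative log-normal noise with sd
    ``assay_conc_noise``; the ratio is invariant to common dilution.
    """
    rng = spec.rng()
    ratio = 10.0 ** true_log_d
    aq = total_conc / (1.0 + ratio)
    org = total_conc - aq
    noise = np.exp(rng.normal(0.0, spec.assay_conc_noise, 2))
    return float(org * noise[0]), float(aq * noise[1])
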