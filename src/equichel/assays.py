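"""Antioxidant and partition assay reductions.

Covers the three bench assays used to profile chelator candidates:

* DPPH radical scavenging: % scavenging = (A_c - A_t)/A_c * 100, with
  EC50 read off the dose-response curve by bracketing interpolation.
* TEAC: the compound's ABTS inhibition-vs-concentration slope
  normalised to the Trolox slope at the same time point.
* Shake-flask distribution coefficient: log D = log10(C_org / C_aq).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AssayCurve",
    "AssayResult",
    "dpph_scavenging",
    "ec50_from_curve",
    "mgml_to_molar",
    "round_sig",
    "teac_value",
    "log_d",
]


@dataclass
class AssayCurve:
    """Concentration-response records for one assay run.

    Negative responses (pro-oxidant readings or noise at low dose) are
    kept as measured and flagged via :attr:`has_negative_responses`.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    unit: str = "mg/mL"
    time_point_min: float | None = None
    control_absorbance: float | None = None
    sample_absorbances: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")

    @property
    def has_negative_responses(self) -> bool:
        return bool(np.any(self.responses < 0))


@dataclass
class AssayResult:
    """Reduced assay quantities for one compound."""

    ec50_mass: float | None = None  # mg/mL
    molar_mass: float | None = None  # g/mol
    teac: float | None = None  # Trolox equivalents
    log_d: float | None = None

    @property
    def ec50_molar(self) -> float | None:
        if self.ec50_mass is None or self.molar_mass is None:
            return None
        return self.ec50_mass / self.molar_mass


def dpph_scavenging(A_c: float, A_t: float) -> float:
    """Percent DPPH scavenging, (A_c - A_t)/A_c * 100.

    A_t above the control gives a negative value; it is returned as-is
    (callers flag it through :class:`AssayCurve`).
    """
    if A_c <= 0:
        raise ValueError("control absorbance must be positive")
    return (A_c - A_t) / A_c * 100.0


def ec50_from_curve(curve: AssayCurve) -> float:
    """Concentration at 50% response by bracketing linear interpolation.

    An exactly measured 50% point is returned directly.  The curve must
    be monotone after 3-point median smoothing; no sigmoid model is
    imposed.
    """
    c, r = curve.concentrations, curve.responses
    if float(np.max(r)) < 50.0:
        raise ValueError(
            f"EC50 not reached: maximum response {np.max(r):.3g}% < 50%"
        )
    if c.size >= 3:
        smooth = np.copy(r)
        smooth[1:-1] = [np.median(r[i - 1:i + 2]) for i in range(1, r.size - 1)]
        if np.any(np.diff(smooth) < 0):
            raise ValueError("non-monotone response curve; cannot interpolate EC50")
    hits = np.nonzero(r == 50.0)[0]
    if hits.size:
        return float(c[hits[0]])
    i = int(np.argmax(r >= 50.0))
    if i == 0:
        # already above 50% at the lowest dose: extrapolate from origin
        return float(c[0] * 50.0 / r[0])
    frac = (50.0 - r[i - 1]) / (r[i] - r[i - 1])
    return float(c[i - 1] + frac * (c[i] - c[i - 1]))


def mgml_to_molar(ec50_mass: float, molar_mass: float,
                  sig_figs: int | None = 2) -> float:
    """Convert an EC50 in mg/mL to mol/L (mg/mL = g/L).

    ``sig_figs`` applies display rounding (2 matches the usual table
    convention); pass ``None`` for the raw value.
    """
    if ec50_mass <= 0 or molar_mass <= 0:
        raise ValueError("mass concentration and molar mass must be positive")
    value = ec50_mass / molar_mass
    return value if sig_figs is None else round_sig(value, sig_figs)


def round_sig(value: float, sig_figs: int) -> float:
    if value == 0:
        return 0.0
    return round(value, -int(math.floor(math.log10(abs(value)))) + sig_figs - 1)


def teac_value(ligand_curve: AssayCurve, trolox_curve: AssayCurve) -> float:
    """Trolox-equivalent antioxidant capacity at one time point.

    TEAC = slope(ligand inhibition vs concentration) / slope(Trolox),
    both slopes from ordinary least squares with an intercept.
    """
    if ligand_curve.time_point_min != trolox_curve.time_point_min:
        raise ValueError("curves must be taken at the same time point")
    if ligand_curve.concentrations.size < 3 or trolox_curve.concentrations.size < 3:
        raise ValueError("at least 3 concentrations per curve are required")

    def slope(curve: AssayCurve) -> float:
        m, _ = np.polyfit(curve.concentrations, curve.responses, 1)
        return float(m)

    s_trolox = slope(trolox_curve)
    if s_trolox <= 0:
        raise ValueError("Trolox slope must be positive")
    return slope(ligand_curve) / s_trolox


def log_d(conc_organic: float, conc_aqueous: float) -> float:
    """Distribution coefficient log10(C_organic / C_aqueous)."""
    if conc_organic <= 0 or conc_aqueous <= 0:
        raise ValueError("phase concentrations must be positive")
    return math.log10(conc_organic / conc_aqueous)
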