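"""Equilibrium models for metal/ligand/proton systems.

A :class:`ChemicalSystem` collects the components (metal M, ligand L,
proton H) and the complex species M_mL_lH_h with their cumulative
formation constants on the concentration scale,

    beta_mlh = [M_m L_l H_h] / ([M]^m [L]^l [H]^h).

Hydroxo species are encoded with negative proton stoichiometry, e.g.
Fe(OH)2+ is (1, 0, -1), so the solvent pKw never enters the speciation
algebra directly; it is carried as metadata only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Species",
    "ChemicalSystem",
    "logK_to_logbeta",
    "logbeta_to_logK",
    "load_model",
    "builtin_models",
]


@dataclass(frozen=True)
class Species:
    """One complex M_mL_lH_h with its cumulative log beta.

    ``n_proton`` may be negative (hydroxo species); ``approximate`` flags
    constants that were only estimated (printed as "~" in data tables).
    """

    name: str
    n_metal: int
    n_ligand: int
    n_proton: int
    log_beta: float
    approximate: bool = False

    def __post_init__(self) -> None:
        if self.n_metal < 0 or self.n_ligand < 0:
            raise ValueError(
                f"species {self.name!r}: metal/ligand stoichiometry must be >= 0"
            )
        if self.n_metal == 0 and self.n_ligand == 0 and self.n_proton == 0:
            raise ValueError(f"species {self.name!r}: empty stoichiometry")
        if not math.isfinite(self.log_beta):
            raise ValueError(f"species {self.name!r}: log_beta must be finite")

    @property
    def stoich(self) -> tuple[int, int, int]:
        return (self.n_metal, self.n_ligand, self.n_proton)


@dataclass(frozen=True)
class ChemicalSystem:
    """A set of equilibria over the fixed component basis (M, L, H)."""

    species: tuple[Species, ...]
    components: tuple[str, str, str] = ("M", "L", "H")
    pKw: float = 13.77
    solvent_label: str = "H2O"
    temperature_C: float = 25.0
    ionic_strength_M: float = 0.1
    label: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.components) != 3:
            raise ValueError("exactly three components (M, L, H) are required")
        if self.pKw <= 0:
            raise ValueError("pKw must be positive")
        object.__setattr__(self, "species", tuple(self.species))
        seen: set[tuple[int, int, int]] = set()
        for sp in self.species:
            if sp.stoich in seen:
                raise ValueError(f"duplicate stoichiometry {sp.stoich} ({sp.name!r})")
            seen.add(sp.stoich)

    # -- component helpers -------------------------------------------------
    @property
    def metal(self) -> str:
        return self.components[0]

    @property
    def ligand(self) -> str:
        return self.components[1]

    @property
    def proton(self) -> str:
        return self.components[2]

    def metal_species(self) -> tuple[Species, ...]:
        return tuple(sp for sp in self.species if sp.n_metal > 0)

    def ligand_species(self) -> tuple[Species, ...]:
        return tuple(sp for sp in self.species if sp.n_ligand > 0)

    def complexes(self) -> tuple[Species, ...]:
        """Species containing both metal and ligand."""
        return tuple(sp for sp in self.species if sp.n_metal > 0 and sp.n_ligand > 0)

    def get(self, name: str) -> Species:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(f"no species named {name!r}")

    def with_log_beta(self, updates: Mapping[str, float]) -> "ChemicalSystem":
        """Return a copy with selected species' log beta values replaced."""
        missing = set(updates) - {sp.name for sp in self.species}
        if missing:
            raise KeyError(f"unknown species: {sorted(missing)}")
        new = tuple(
            Species(sp.name, sp.n_metal, sp.n_ligand, sp.n_proton,
                    updates.get(sp.name, sp.log_beta), sp.approximate)
            for sp in self.species
        )
        return ChemicalSystem(new, self.components, self.pKw, self.solvent_label,
                              self.temperature_C, self.ionic_strength_M,
                              self.label, self.source)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "components": list(self.components),
            "solvent": self.solvent_label,
            "pKw": self.pKw,
            "temperature_C": self.temperature_C,
            "ionic_strength_M": self.ionic_strength_M,
            "source": self.source,
            "species": [
                {
                    "name": sp.name,
                    "nM": sp.n_metal,
                    "nL": sp.n_ligand,
                    "nH": sp.n_proton,
                    "log_beta": sp.log_beta,
                    "approximate": sp.approximate,
                }
                for sp in self.species
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChemicalSystem":
        species = tuple(
            Species(s["name"], s["nM"], s["nL"], s["nH"], s["log_beta"],
                    bool(s.get("approximate", False)))
            for s in d["species"]
        )
        return cls(
            species=species,
            components=tuple(d.get("components", ("M", "L", "H"))),
            pKw=float(d.get("pKw", 13.77)),
            solvent_label=str(d.get("solvent", "H2O")),
            temperature_C=float(d.get("temperature_C", 25.0)),
            ionic_strength_M=float(d.get("ionic_strength_M", 0.1)),
            label=str(d.get("label", "")),
            source=str(d.get("source", "")),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ChemicalSystem":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def logK_to_logbeta(stepwise_logK: Sequence[float]) -> list[float]:
    """Cumulative log beta values from stepwise protonation constants.

    The input is ordered from the first protonation (L + H = LH)
    downward; cumulative value i is the running sum of the first i+1
    stepwise constants.
    """
    vals = list(stepwise_logK)
    if not vals:
        raise ValueError("at least one stepwise constant is required")
    out: list[float] = []
    acc = 0.0
    for k in vals:
        acc += float(k)
        out.append(acc)
    return out


def logbeta_to_logK(cumulative_logbeta: Sequence[float]) -> list[float]:
    """Inverse of :func:`logK_to_logbeta` (first differences)."""
    vals = list(cumulative_logbeta)
    if not vals:
        raise ValueError("at least one cumulative constant is required")
    return [vals[0]] + [b - a for a, b in zip(vals, vals[1:])]


_DATA_PACKAGE = "equichel.data"


def builtin_models() -> list[str]:
    """Names of the packaged equilibrium-model files."""
    names = []
    for entry in resources.files(_DATA_PACKAGE).iterdir():
        if entry.name.endswith(".json"):
            names.append(entry.name[: -len(".json")])
    return sorted(names)


def load_model(name: str) -> ChemicalSystem:
    """Load a packaged model by name (see :func:`builtin_models`)."""
    ref = resources.files(_DATA_PACKAGE) / f"{name}.json"
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"no packaged model {name!r}; available: {builtin_models()}"
        ) from None
    return ChemicalSystem.from_dict(json.loads(text))
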