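"""Molecular species used throughout the package.

Masses are *average* masses in Da: intact-protein native MS at the 33-57 kDa
scale resolves average, not monoisotopic, masses. Charging uses the average
proton mass and assumes positive-ion mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pmass

#: Average mass of a proton (Da); positive-ion charging only.
PROTON_MASS = 1.00728

LIPID_CLASSES = ("PE", "PG", "CDL", "lipid-II", "other")


def formula_mass(formula: str) -> float:
    """Average molecular mass (Da) of a chemical formula such as ``C39H76NO8P``."""
    return float(_pmass.calculate_mass(formula=formula, average=True))


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid identified by name, class and average mass.

    Exactly one of ``formula`` or ``average_mass`` must be given; a formula is
    resolved to its average mass at construction.
    """

    name: str
    lipid_class: str
    formula: str | None = None
    average_mass: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(
                f"lipid_class {self.lipid_class!r} not one of {LIPID_CLASSES}"
            )
        if self.formula is not None:
            mass = formula_mass(self.formula)
            if self.average_mass is not None and abs(self.average_mass - mass) > 0.5:
                raise ValueError(
                    f"{self.name}: declared mass {self.average_mass} disagrees "
                    f"with formula mass {mass:.2f}"
                )
            object.__setattr__(self, "average_mass", mass)
        if self.average_mass is None:
            raise ValueError(f"{self.name}: need a formula or an average mass")
        if self.average_mass <= 0:
            raise ValueError(f"{self.name}: mass must be positive")

    @property
    def mass(self) -> float:
        return self.average_mass  # type: ignore[return-value]


@dataclass(frozen=True)
class DetergentSpecies:
    """A detergent with its average monomer mass and CMC (% w/v)."""

    name: str
    average_mass: float
    cmc: float

    def __post_init__(self) -> None:
        if self.average_mass <= 0:
            raise ValueError(f"{self.name}: average_mass must be positive")
        if self.cmc < 0:
            raise ValueError(f"{self.name}: cmc must be non-negative")

    def percent_to_molar(self, percent_w_v: float) -> float:
        """Convert % w/v to mol/L: 1 % w/v = 10 g/L."""
        return 10.0 * percent_w_v / self.average_mass


@dataclass(frozen=True)
class ProteinSpecies:
    """An intact protein with its average mass and observable charge-state range."""

    name: str
    average_mass: float
    charge_states: tuple[int, int]

    def __post_init__(self) -> None:
        if self.average_mass <= 0:
            raise ValueError(f"{self.name}: average_mass must be positive")
        lo, hi = self.charge_states
        if lo < 1 or hi < lo:
            raise ValueError(
                f"{self.name}: charge range {self.charge_states} must be a "
                "non-empty range of charges >= 1"
            )

    @property
    def charges(self) -> range:
        lo, hi = self.charge_states
        return range(lo, hi + 1)


def mz_of(mass: float, z: int) -> float:
    """m/z of a species of the given neutral average mass carrying z protons."""
    return (mass + z * PROTON_MASS) / z
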