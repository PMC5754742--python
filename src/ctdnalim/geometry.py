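"""Tumor size allometry: diameter, volume, mass and cell count.

A solid tumor is idealized as a sphere of uniform density and cellularity.
Under those assumptions the four size measures are deterministic functions
of one another:

    volume (cm^3)  = (pi/6) * (diameter/10 mm)^3
    mass   (mg)    = volume * density            (default 1000 mg/cm^3)
    cells          = mass(g) * cells_per_gram    (default 1e8 cells/g)

Water-equivalent density (1 g/cm^3) makes a 1 cm^3 nodule weigh 1 g and a
10 cm^3 nodule weigh 10 g, which is the convention used throughout clinical
tumor-burden estimates.  The cellularity default of 1e8 cells/g is the low
end of the commonly quoted 1e8-1e9 range; solid carcinomas contain stroma
and extracellular matrix, so the low end tracks published cell counts for
gram-scale breast tumors.

Units are fixed by convention: diameters in mm, volumes in cm^3, masses in
mg.  All conversions accept scalars or numpy arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AllometryConstants",
    "TumorBurden",
    "diameter_to_volume",
    "volume_to_diameter",
    "volume_to_mass",
    "mass_to_volume",
    "mass_to_cells",
    "mass_to_diameter",
    "burden_from_diameter",
    "burden_from_mass",
]

_MM_PER_CM = 10.0
_MG_PER_G = 1000.0


@dataclass(frozen=True)
class AllometryConstants:
    """Physical constants tying tumor volume to mass and cell number.

    Parameters
    ----------
    density_mg_per_cm3 : float
        Tumor tissue density. Default 1000 mg/cm^3 (water-equivalent).
    cells_per_gram : float
        Cell count per gram of tumor tissue. Default 1e8.
    """

    density_mg_per_cm3: float = 1000.0
    cells_per_gram: float = 1e8

    def __post_init__(self) -> None:
        if self.density_mg_per_cm3 <= 0:
            raise ValueError("density must be strictly positive")
        if self.cells_per_gram <= 0:
            raise ValueError("cells_per_gram must be strictly positive")


DEFAULT_ALLOMETRY = AllometryConstants()


@dataclass(frozen=True)
class TumorBurden:
    """One tumor's mutually consistent size measures.

    Fields: ``diameter_mm``, ``volume_cm3``, ``mass_mg``, ``cells``.
    All four are zero together or positive together.
    """

    diameter_mm: float
    volume_cm3: float
    mass_mg: float
    cells: float

    def __post_init__(self) -> None:
        fields = (self.diameter_mm, self.volume_cm3, self.mass_mg, self.cells)
        if any(f < 0 for f in fields):
            raise ValueError("tumor burden fields must be nonnegative")
        if any(f == 0 for f in fields) and any(f > 0 for f in fields):
            raise ValueError("burden fields must be all zero or all positive")


def _check_nonnegative(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    return arr if arr.ndim else float(arr)


def diameter_to_volume(diameter_mm):
    """Volume in cm^3 of a sphere with the given diameter in mm."""
    d = _check_nonnegative(diameter_mm, "diameter")
    return (math.pi / 6.0) * (d / _MM_PER_CM) ** 3


def volume_to_diameter(volume_cm3):
    """Diameter in mm of a sphere with the given volume in cm^3."""
    v = _check_nonnegative(volume_cm3, "volume")
    return _MM_PER_CM * np.cbrt(6.0 * v / math.pi)


def volume_to_mass(volume_cm3, constants: AllometryConstants = DEFAULT_ALLOMETRY):
    """Mass in mg of a tumor of the given volume."""
    v = _check_nonnegative(volume_cm3, "volume")
    return v * constants.density_mg_per_cm3


def mass_to_volume(mass_mg, constants: AllometryConstants = DEFAULT_ALLOMETRY):
    """Volume in cm^3 of a tumor of the given mass."""
    m = _check_nonnegative(mass_mg, "mass")
    return m / constants.density_mg_per_cm3


def mass_to_cells(mass_mg, constants: AllometryConstants = DEFAULT_ALLOMETRY):
    """Cell count of a tumor of the given mass in mg."""
    m = _check_nonnegative(mass_mg, "mass")
    return (m / _MG_PER_G) * constants.cells_per_gram


def mass_to_diameter(mass_mg, constants: AllometryConstants = DEFAULT_ALLOMETRY):
    """Diameter in mm of a spherical tumor of the given mass in mg."""
    return volume_to_diameter(mass_to_volume(mass_mg, constants))


def burden_from_diameter(
    diameter_mm: float, constants: AllometryConstants = DEFAULT_ALLOMETRY
) -> TumorBurden:
    """Build the full consistent :class:`TumorBurden` record from a diameter."""
    v = diameter_to_volume(diameter_mm)
    m = volume_to_mass(v, constants)
    return TumorBurden(
        diameter_mm=float(diameter_mm),
        volume_cm3=float(v),
        mass_mg=float(m),
        cells=float(mass_to_cells(m, constants)),
    )


def burden_from_mass(
    mass_mg: float, constants: AllometryConstants = DEFAULT_ALLOMETRY
) -> TumorBurden:
    """Build the full consistent :class:`TumorBurden` record from a mass."""
    v = mass_to_volume(mass_mg, constants)
    return TumorBurden(
        diameter_mm=float(volume_to_diameter(v)),
        volume_cm3=float(v),
        mass_mg=float(mass_mg),
        cells=float(mass_to_cells(mass_mg, constants)),
    )
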