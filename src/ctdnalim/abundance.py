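"""Circulating tumor DNA abundance model.

Plasma carries cell-free DNA (cfDNA) from normal tissue turnover; in a
cancer patient a small fraction of those fragments derive from the tumor
(ctDNA) and carry its mutations.  This module converts a plasma cfDNA
concentration into haploid genome equivalents, scales the mutant fraction
linearly with tumor mass from a single published calibration point, and
multiplies the two to get the expected number of mutant genome copies in a
blood draw or in the whole circulation.

The linear mass scaling is anchored at a 10 g tumor shedding a mutant
fraction of 0.1% (1 mutant per 1,000 wild-type molecules), so a 1 g tumor
sheds 0.01%, a 1 mg tumor 1e-7, and so on.  Expected copy numbers are kept
as real-valued expectations; they are the Poisson rates consumed by the
detection model, never pre-rounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlasmaParams",
    "ShedAnchor",
    "genome_equivalents",
    "mutant_fraction",
    "expected_copies_per_draw",
    "copies_in_circulation",
]

_PG_PER_NG = 1000.0


@dataclass(frozen=True)
class PlasmaParams:
    """Physiological constants for the plasma compartment.

    Parameters
    ----------
    cfdna_ng_per_ml : float
        Total cfDNA concentration in plasma of individuals without cancer
        or with very small cancers. Default 5 ng/mL.
    plasma_ml_per_draw : float
        Plasma yield of one standard blood draw. Default 4 mL (from a
        10 mL whole-blood draw).
    blood_ml_per_draw : float
        Whole-blood volume of the draw; annotation only, not used in any
        formula. Default 10 mL.
    haploid_genome_pg : float
        Mass of one haploid human genome. Default 3.3 pg, which makes
        5 ng/mL x 4 mL come out at ~6,000 genome equivalents.
    total_plasma_ml : float
        Total circulating plasma volume of an adult. Default 3,000 mL.
    """

    cfdna_ng_per_ml: float = 5.0
    plasma_ml_per_draw: float = 4.0
    blood_ml_per_draw: float = 10.0
    haploid_genome_pg: float = 3.3
    total_plasma_ml: float = 3000.0

    def __post_init__(self) -> None:
        for name in (
            "cfdna_ng_per_ml",
            "plasma_ml_per_draw",
            "blood_ml_per_draw",
            "haploid_genome_pg",
            "total_plasma_ml",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.plasma_ml_per_draw > self.total_plasma_ml:
            raise ValueError("draw volume cannot exceed total plasma volume")


@dataclass(frozen=True)
class ShedAnchor:
    """Calibration pair fixing the linear mass -> mutant-fraction scaling.

    ``anchor_mass_mg`` is the tumor mass at which the plasma mutant
    fraction equals ``anchor_fraction``.  Defaults: 10 g and 0.1%.
    """

    anchor_mass_mg: float = 10_000.0
    anchor_fraction: float = 1e-3

    def __post_init__(self) -> None:
        if self.anchor_mass_mg <= 0:
            raise ValueError("anchor_mass_mg must be strictly positive")
        if not 0 < self.anchor_fraction <= 1:
            raise ValueError("anchor_fraction must be in (0, 1]")


DEFAULT_PLASMA = PlasmaParams()
DEFAULT_ANCHOR = ShedAnchor()


def _check_nonnegative(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    return arr if arr.ndim else float(arr)


def genome_equivalents(params: PlasmaParams = DEFAULT_PLASMA, plasma_ml=None):
    """Haploid genome equivalents of cfDNA in ``plasma_ml`` of plasma.

    cfDNA mass (concentration x volume) divided by the haploid genome
    mass; linear in the plasma volume.  Defaults to one draw's worth.
    Returns a real number, not an integer: this is the size of the
    fragment population from which mutant copies are sampled.
    """
    if plasma_ml is None:
        plasma_ml = params.plasma_ml_per_draw
    v = _check_nonnegative(plasma_ml, "plasma_ml")
    return params.cfdna_ng_per_ml * v * _PG_PER_NG / params.haploid_genome_pg


def mutant_fraction(tumor_mass_mg, anchor: ShedAnchor = DEFAULT_ANCHOR):
    """Plasma mutant-DNA fraction for a tumor of the given mass.

    Linear in mass through the anchor point, capped at 1 (a fraction
    cannot exceed unity).  A mass of zero gives fraction zero.
    """
    m = _check_nonnegative(tumor_mass_mg, "tumor_mass_mg")
    return np.minimum(anchor.anchor_fraction * m / anchor.anchor_mass_mg, 1.0)


def expected_copies_per_draw(
    tumor_mass_mg,
    params: PlasmaParams = DEFAULT_PLASMA,
    anchor: ShedAnchor = DEFAULT_ANCHOR,
    plasma_ml=None,
):
    """Expected mutant genome copies in one plasma draw.

    The product of the draw's genome equivalents and the tumor's mutant
    fraction.  Fractional values are meaningful: 0.3 means a 30% chance
    per draw of catching even one copy under Poisson sampling.
    """
    return genome_equivalents(params, plasma_ml) * mutant_fraction(tumor_mass_mg, anchor)


def copies_in_circulation(
    tumor_mass_mg,
    params: PlasmaParams = DEFAULT_PLASMA,
    anchor: ShedAnchor = DEFAULT_ANCHOR,
):
    """Expected mutant genome copies in the entire plasma compartment.

    Same product evaluated at ``total_plasma_ml`` instead of the draw
    volume.  The result depends directly on the assumed total plasma
    volume, so report it alongside any whole-circulation figure.
    """
    return expected_copies_per_draw(
        tumor_mass_mg, params, anchor, plasma_ml=params.total_plasma_ml
    )
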