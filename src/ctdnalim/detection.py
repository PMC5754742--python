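"""Sampling-error detection limits for rare ctDNA fragments.

A 4 mL plasma draw is a tiny aliquot of the circulation.  When the
expected number of mutant copies per draw drops below ~1, detection fails
not because the assay is poor but because the tube simply contains no
mutant molecule.  This module turns expected copy numbers into detection
probabilities and inverts the linear abundance model to give the minimum
tumor mass (and diameter) detectable at a given copy threshold.

Two detection modes are provided:

``poisson`` (default)
    Mutant fragments are rare and well mixed in plasma, so the copies in
    a draw are Poisson-distributed around the expectation; the detection
    probability is P(X >= k) for X ~ Poisson(lambda * efficiency).  The
    draw is small relative to total plasma, so the finite-population
    (hypergeometric) correction is negligible and is not offered.

``expectation_threshold``
    The deterministic reading "a draw is positive iff it is expected to
    contain at least k copies"; a step function of the expectation, useful
    for reproducing back-of-envelope minimum-size thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .abundance import (
    DEFAULT_ANCHOR,
    DEFAULT_PLASMA,
    PlasmaParams,
    ShedAnchor,
    expected_copies_per_draw,
    genome_equivalents,
)
from .geometry import (
    DEFAULT_ALLOMETRY,
    AllometryConstants,
    diameter_to_volume,
    mass_to_diameter,
    volume_to_mass,
)

__all__ = [
    "DetectionParams",
    "InfeasibleTargetError",
    "detection_probability",
    "min_detectable_mass",
    "min_detectable_diameter",
    "detection_curve",
]


class InfeasibleTargetError(ValueError):
    """Raised when no tumor mass can reach the requested copy target.

    Happens when the target exceeds the copy number at mutant fraction 1,
    i.e. even a tumor shedding pure mutant DNA could not supply it.
    """


@dataclass(frozen=True)
class DetectionParams:
    """Detection threshold and mode.

    ``min_copies`` is the number of mutant copies a draw must yield to be
    called positive (k >= 1, integer).  ``assay_efficiency`` thins the
    Poisson rate for imperfect molecule recovery/conversion; the default 1
    assumes perfect recovery.
    """

    min_copies: int = 1
    mode: str = "poisson"
    assay_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.min_copies < 1 or int(self.min_copies) != self.min_copies:
            raise ValueError("min_copies must be an integer >= 1")
        if not 0 < self.assay_efficiency <= 1:
            raise ValueError("assay_efficiency must be in (0, 1]")
        if self.mode not in ("poisson", "expectation_threshold"):
            raise ValueError("mode must be 'poisson' or 'expectation_threshold'")


DEFAULT_DETECTION = DetectionParams()


def detection_probability(expected_copies, det: DetectionParams = DEFAULT_DETECTION):
    """Probability that a draw yields at least ``det.min_copies`` copies.

    Accepts scalar or array expectations. In ``expectation_threshold``
    mode the result is the 0/1 indicator of the thinned expectation
    reaching the threshold.
    """
    lam = np.asarray(expected_copies, dtype=float)
    if np.any(lam < 0):
        raise ValueError("expected_copies must be nonnegative")
    lam_eff = lam * det.assay_efficiency
    if det.mode == "expectation_threshold":
        p = (lam_eff >= det.min_copies).astype(float)
    else:
        # P(X >= k) via the survival function at k-1
        p = stats.poisson.sf(det.min_copies - 1, lam_eff)
    return p if p.ndim else float(p)


def min_detectable_mass(
    target_copies: float = 1.0,
    params: PlasmaParams = DEFAULT_PLASMA,
    anchor: ShedAnchor = DEFAULT_ANCHOR,
    det: DetectionParams = DEFAULT_DETECTION,
    plasma_ml: float | None = None,
) -> float:
    """Smallest tumor mass (mg) whose draw is expected to contain the target.

    Exact inversion of the linear model: expected copies per draw equal
    genome_equivalents x anchor_fraction x mass / anchor_mass x efficiency,
    so the minimum mass is target / (that slope).  Raises
    :class:`InfeasibleTargetError` if the target is unreachable even at
    mutant fraction 1.
    """
    if target_copies <= 0:
        raise ValueError("target_copies must be strictly positive")
    ge = genome_equivalents(params, plasma_ml) * det.assay_efficiency
    if target_copies > ge:  # fraction would have to exceed 1
        raise InfeasibleTargetError(
            f"target of {target_copies} copies exceeds the {ge:.1f} genome "
            "equivalents available even at mutant fraction 1"
        )
    slope = ge * anchor.anchor_fraction / anchor.anchor_mass_mg
    return target_copies / slope


def min_detectable_diameter(
    target_copies: float = 1.0,
    params: PlasmaParams = DEFAULT_PLASMA,
    anchor: ShedAnchor = DEFAULT_ANCHOR,
    det: DetectionParams = DEFAULT_DETECTION,
    constants: AllometryConstants = DEFAULT_ALLOMETRY,
    plasma_ml: float | None = None,
) -> float:
    """Diameter (mm) of the smallest detectable spherical tumor."""
    m = min_detectable_mass(target_copies, params, anchor, det, plasma_ml)
    return float(mass_to_diameter(m, constants))


def detection_curve(
    diameters_mm: Sequence[float],
    params: PlasmaParams = DEFAULT_PLASMA,
    anchor: ShedAnchor = DEFAULT_ANCHOR,
    det: DetectionParams = DEFAULT_DETECTION,
    constants: AllometryConstants = DEFAULT_ALLOMETRY,
):
    """Expected copies and detection probability over a diameter sweep.

    Returns a list of ``(diameter_mm, expected_copies, detection_probability)``
    tuples in input order.
    """
    d = np.asarray(list(diameters_mm), dtype=float)
    if np.any(d < 0):
        raise ValueError("diameters must be nonnegative")
    masses = volume_to_mass(diameter_to_volume(d), constants)
    lam = np.atleast_1d(expected_copies_per_draw(masses, params, anchor))
    prob = np.atleast_1d(detection_probability(lam, det))
    return [
        (float(di), float(li), float(pi)) for di, li, pi in zip(d, lam, prob)
    ]
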