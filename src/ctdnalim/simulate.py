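"""Monte Carlo simulator for a ctDNA-screened cohort.

Each simulated individual carries a latent cancer status drawn at the
cohort prevalence.  Individuals with cancer get a tumor diameter from a
configurable size distribution; the tumor's expected mutant copies per
draw follow the deterministic allometry/abundance model, and the copies
actually captured in the tube are Poisson-sampled around that expectation.
A cancer screens positive only if all three independent layers succeed:

1. the draw contains at least ``min_copies`` mutant copies (sampling),
2. the tumor carries a panel-covered mutation (Bernoulli, coverage),
3. the assay calls it (Bernoulli, positivity).

Individuals without cancer screen positive with probability 1 -
specificity (a single Bernoulli; no mechanistic model of benign somatic
mutations is attempted).  The simulator composes the generative layers
directly and never calls the analytic screening formulas, so empirical
confusion matrices are an independent check of them.

Results come back as a pandas DataFrame with one row per individual plus
a summary :class:`~ctdnalim.screening.ConfusionCounts`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .abundance import (
    DEFAULT_ANCHOR,
    DEFAULT_PLASMA,
    PlasmaParams,
    ShedAnchor,
    expected_copies_per_draw,
)
from .detection import DEFAULT_DETECTION, DetectionParams
from .geometry import DEFAULT_ALLOMETRY, AllometryConstants, diameter_to_volume, volume_to_mass
from .screening import ConfusionCounts

__all__ = ["SizeDistribution", "CohortConfig", "simulate_cohort", "summarize"]

RECORD_COLUMNS = [
    "id",
    "has_cancer",
    "tumor_diameter_mm",
    "expected_copies",
    "sampled_copies",
    "covered_by_panel",
    "assay_positive",
    "screen_positive",
]


@dataclass(frozen=True)
class SizeDistribution:
    """Tumor diameter distribution (mm) for simulated cancers.

    Supported kinds: ``point`` (params: value), ``lognormal`` (params:
    mu, sigma of log-diameter), ``uniform`` (params: lo, hi).
    """

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.params
        if self.kind == "point":
            if "value" not in p or p["value"] < 0:
                raise ValueError("point distribution needs nonnegative 'value'")
        elif self.kind == "lognormal":
            if "mu" not in p or "sigma" not in p or p["sigma"] <= 0:
                raise ValueError("lognormal needs 'mu' and 'sigma' > 0")
        elif self.kind == "uniform":
            if "lo" not in p or "hi" not in p or not 0 <= p["lo"] < p["hi"]:
                raise ValueError("uniform needs 0 <= lo < hi")
        else:
            raise ValueError(f"unknown size distribution kind: {self.kind!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(size, float(self.params["value"]))
        if self.kind == "lognormal":
            return rng.lognormal(self.params["mu"], self.params["sigma"], size)
        return rng.uniform(self.params["lo"], self.params["hi"], size)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration for one simulated screening cohort.

    Defaults mirror the analytic screening scenario: 80% panel coverage,
    50% assay positivity among covered tumors, 1% false-positive rate in
    cancer-free individuals.  ``seed`` is mandatory: a single RNG stream
    makes runs bit-reproducible.
    """

    n: int
    prevalence: float
    size_distribution: SizeDistribution
    seed: int
    panel_coverage_prob: float = 0.80
    positivity_prob: float = 0.50
    false_positive_prob: float = 0.01

    def __post_init__(self) -> None:
        if self.n <= 0 or int(self.n) != self.n:
            raise ValueError("n must be a positive integer")
        for name in ("prevalence", "panel_coverage_prob", "positivity_prob", "false_positive_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def simulate_cohort(
    config: CohortConfig,
    plasma: PlasmaParams = DEFAULT_PLASMA,
    anchor: ShedAnchor = DEFAULT_ANCHOR,
    det: DetectionParams = DEFAULT_DETECTION,
    constants: AllometryConstants = DEFAULT_ALLOMETRY,
) -> tuple[pd.DataFrame, ConfusionCounts]:
    """Simulate one screened cohort.

    Returns ``(records, counts)``: a DataFrame with one row per
    individual (columns in :data:`RECORD_COLUMNS`) and the summary
    confusion counts.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    has_cancer = rng.random(n) < config.prevalence
    n_cancer = int(has_cancer.sum())

    diameters = np.zeros(n)
    diameters[has_cancer] = config.size_distribution.sample(rng, n_cancer)

    masses = volume_to_mass(diameter_to_volume(diameters), constants)
    lam = np.asarray(expected_copies_per_draw(masses, plasma, anchor), dtype=float)
    lam = np.atleast_1d(lam) * det.assay_efficiency

    sampled = np.zeros(n, dtype=np.int64)
    sampled[has_cancer] = rng.poisson(lam[has_cancer])

    covered = rng.random(n) < config.panel_coverage_prob
    assay_pos = rng.random(n) < config.positivity_prob
    fp_draw = rng.random(n) < config.false_positive_prob

    enough_copies = sampled >= det.min_copies
    positive = np.where(
        has_cancer,
        enough_copies & covered & assay_pos,
        fp_draw,
    )

    records = pd.DataFrame(
        {
            "id": np.arange(n),
            "has_cancer": has_cancer,
            "tumor_diameter_mm": diameters,
            "expected_copies": lam,
            "sampled_copies": sampled,
            "covered_by_panel": covered,
            "assay_positive": assay_pos,
            "screen_positive": positive,
        }
    )
    return records, summarize(records)


def summarize(records: pd.DataFrame, diameter_bins=None):
    """Confusion counts (and optional per-size sensitivities) from records.

    With ``diameter_bins`` (a sequence of bin edges in mm) the return is
    ``(counts, per_bin)`` where ``per_bin`` is a DataFrame of empirical
    sensitivity per diameter bin among cancers; otherwise just the counts.
    """
    if len(records) == 0:
        raise ValueError("record list is empty")
    cancer = records["has_cancer"].to_numpy(dtype=bool)
    positive = records["screen_positive"].to_numpy(dtype=bool)
    counts = ConfusionCounts(
        tp=int((cancer & positive).sum()),
        fn=int((cancer & ~positive).sum()),
        fp=int((~cancer & positive).sum()),
        tn=int((~cancer & ~positive).sum()),
    )
    if diameter_bins is None:
        return counts
    cancers = records.loc[records["has_cancer"]]
    binned = pd.cut(cancers["tumor_diameter_mm"], bins=diameter_bins)
    per_bin = (
        cancers.groupby(binned, observed=False)["screen_positive"]
        .agg(n="size", detected="sum")
        .assign(sensitivity=lambda d: d["detected"] / d["n"].where(d["n"] > 0))
        .reset_index(names="diameter_bin")
    )
    return counts, per_bin
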