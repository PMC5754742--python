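"""Screening operating characteristics: sensitivity, confusion counts, PPV.

Panel sequencing of plasma DNA has two multiplicative sensitivity layers
before sampling error even enters: the probability that the tumor carries
a mutation covered by the panel (max panel sensitivity, ~80% for current
driver panels) and the assay's overall positivity given coverage (~50%).
Their product bounds the overall screening sensitivity at ~40%.

At screening prevalences of ~1%, even 99% specificity floods the positives
with false calls.  This module builds the expected confusion matrix for a
screened cohort and computes PPV/NPV two ways: from exact Bayes rates and
from integer-rounded cohort counts (nearest integer, half-up), the
arithmetic typically shown in worked cohort examples.  Both are always
computed so the rounding step is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ScreeningParams",
    "ConfusionCounts",
    "combined_sensitivity",
    "expected_confusion",
    "ppv_from_rates",
    "npv_from_rates",
    "screen_sweep",
]


def _round_half_up(x: float) -> float:
    return math.floor(x + 0.5)


def _check_fraction(value: float, name: str) -> None:
    if not 0 <= value <= 1:
        raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class ScreeningParams:
    """Cohort and test parameters for one screening scenario.

    ``rounding`` selects how expected counts become cohort counts:
    ``"nearest_integer"`` (half-up) for worked integer examples, or
    ``"none"`` to keep exact expectations (counts then sum to n exactly).
    """

    cohort_n: int = 1000
    prevalence: float = 0.01
    max_panel_sensitivity: float = 0.80
    positivity: float = 0.50
    specificity: float = 0.99
    rounding: str = "nearest_integer"

    def __post_init__(self) -> None:
        if self.cohort_n <= 0 or int(self.cohort_n) != self.cohort_n:
            raise ValueError("cohort_n must be a positive integer")
        for name in ("prevalence", "max_panel_sensitivity", "positivity", "specificity"):
            _check_fraction(getattr(self, name), name)
        if self.rounding not in ("nearest_integer", "none"):
            raise ValueError("rounding must be 'nearest_integer' or 'none'")

    @property
    def sensitivity(self) -> float:
        return combined_sensitivity(self.max_panel_sensitivity, self.positivity)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/FP/TN counts with derived predictive values.

    ``ppv`` and ``npv`` are NaN when their denominator is zero (e.g. a
    zero-prevalence cohort has no true positives and, with a perfect
    test, no positives at all).
    """

    tp: float
    fn: float
    fp: float
    tn: float

    def __post_init__(self) -> None:
        if any(c < 0 for c in (self.tp, self.fn, self.fp, self.tn)):
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> float:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def ppv(self) -> float:
        pos = self.tp + self.fp
        return self.tp / pos if pos > 0 else float("nan")

    @property
    def npv(self) -> float:
        neg = self.tn + self.fn
        return self.tn / neg if neg > 0 else float("nan")


def combined_sensitivity(max_panel_sensitivity: float, positivity: float) -> float:
    """Overall sensitivity as panel coverage x assay positivity."""
    _check_fraction(max_panel_sensitivity, "max_panel_sensitivity")
    _check_fraction(positivity, "positivity")
    return max_panel_sensitivity * positivity


def expected_confusion(
    params: ScreeningParams, sensitivity: float | None = None
) -> ConfusionCounts:
    """Expected confusion matrix for the cohort.

    ``sensitivity`` defaults to the params' combined panel sensitivity.
    With ``rounding="nearest_integer"`` each count is rounded half-up
    before PPV/NPV (the counts may then not sum to n); with ``"none"``
    exact expectations are kept and tp+fn+fp+tn == n.
    """
    if sensitivity is None:
        sensitivity = params.sensitivity
    _check_fraction(sensitivity, "sensitivity")
    cancers = params.cohort_n * params.prevalence
    healthy = params.cohort_n * (1.0 - params.prevalence)
    tp = cancers * sensitivity
    fn = cancers * (1.0 - sensitivity)
    fp = healthy * (1.0 - params.specificity)
    tn = healthy * params.specificity
    if params.rounding == "nearest_integer":
        tp, fn, fp, tn = (_round_half_up(c) for c in (tp, fn, fp, tn))
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def ppv_from_rates(prevalence: float, sensitivity: float, specificity: float) -> float:
    """Exact Bayes positive predictive value.

    PPV = pi*Se / (pi*Se + (1-pi)*(1-Sp)); NaN when no positives occur
    (e.g. prevalence 0 with a perfectly specific test).
    """
    for name, v in (
        ("prevalence", prevalence),
        ("sensitivity", sensitivity),
        ("specificity", specificity),
    ):
        _check_fraction(v, name)
    num = prevalence * sensitivity
    den = num + (1.0 - prevalence) * (1.0 - specificity)
    return num / den if den > 0 else float("nan")


def npv_from_rates(prevalence: float, sensitivity: float, specificity: float) -> float:
    """Exact Bayes negative predictive value (NaN when no negatives occur)."""
    for name, v in (
        ("prevalence", prevalence),
        ("sensitivity", sensitivity),
        ("specificity", specificity),
    ):
        _check_fraction(v, name)
    num = (1.0 - prevalence) * specificity
    den = num + prevalence * (1.0 - sensitivity)
    return num / den if den > 0 else float("nan")


def screen_sweep(
    params: ScreeningParams,
    specificities: Sequence[float],
    prevalences: Sequence[float],
    sensitivity: float | None = None,
) -> pd.DataFrame:
    """Confusion counts and predictive values over a Sp x prevalence grid.

    Returns one row per grid point with both exact-Bayes and count-based
    (per ``params.rounding``) PPV/NPV.
    """
    specificities = list(specificities)
    prevalences = list(prevalences)
    if not specificities or not prevalences:
        raise ValueError("specificity and prevalence grids must be nonempty")
    if sensitivity is None:
        sensitivity = params.sensitivity
    rows = []
    for sp in specificities:
        for pi in prevalences:
            p = ScreeningParams(
                cohort_n=params.cohort_n,
                prevalence=pi,
                max_panel_sensitivity=params.max_panel_sensitivity,
                positivity=params.positivity,
                specificity=sp,
                rounding=params.rounding,
            )
            counts = expected_confusion(p, sensitivity)
            rows.append(
                {
                    "specificity": sp,
                    "prevalence": pi,
                    "sensitivity": sensitivity,
                    "tp": counts.tp,
                    "fn": counts.fn,
                    "fp": counts.fp,
                    "tn": counts.tn,
                    "ppv_counts": counts.ppv,
                    "npv_counts": counts.npv,
                    "ppv_exact": ppv_from_rates(pi, sensitivity, sp),
                    "npv_exact": npv_from_rates(pi, sensitivity, sp),
                }
            )
    return pd.DataFrame(rows)
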