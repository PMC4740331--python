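"""Per-year cancer hazard schedules for BRCA1/BRCA2 mutation carriers.

Carrier penetrance is represented as a per-year (discrete-time) hazard
``h(a)``: the probability that a carrier who is still cancer-free at her
``a``-th birthday develops the cancer during the year ``[a, a+1)``.  The
cumulative incidence then follows the usual life-table recursion

    F(0) = 0,    F(a+1) = F(a) + (1 - F(a)) * h(a)

equivalently ``F(a) = 1 - prod_{j<a} (1 - h(j))``.

Published carrier risks are usually quoted as cumulative incidences at a
handful of ages ("57% by age 70").  :func:`calibrate_hazard` turns such
cumulative-risk anchors into a piecewise-constant per-year hazard schedule:
within each band between consecutive anchors the hazard is the unique
constant solving

    (1 - F2) = (1 - F1) * (1 - h) ** (a2 - a1)

and the last band's hazard is held constant through the end of the schedule.
The default anchor sets carry the four widely cited cumulative risks at age
70: breast 57% (BRCA1) / 49% (BRCA2) and ovarian 40% (BRCA1) / 18% (BRCA2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

GENES = ("BRCA1", "BRCA2")
SITES = ("breast", "ovarian")

#: Schedules and curves are indexed by integer age 0..MAX_AGE.
MAX_AGE = 85

#: Hereditary risk before this age is treated as negligible by default.
DEFAULT_START_AGE = 25

#: General-population carrier frequencies (non-Ashkenazi): 0.058% / 0.068%.
DEFAULT_CARRIER_FREQS: dict[str, float] = {"BRCA1": 0.00058, "BRCA2": 0.00068}


@dataclass(frozen=True)
class RiskAnchor:
    """A published cumulative-risk point: ``cumulative_risk`` by ``age``."""

    age: int
    cumulative_risk: float

    def __post_init__(self) -> None:
        if not 1 <= self.age <= MAX_AGE:
            raise ValidationError(f"anchor age {self.age} outside [1, {MAX_AGE}]")
        if not 0.0 <= self.cumulative_risk < 1.0:
            raise ValidationError(
                f"anchor cumulative risk {self.cumulative_risk} outside [0, 1)"
            )


#: Cumulative carrier risks by age 70 used as default calibration anchors.
DEFAULT_ANCHORS: dict[tuple[str, str], tuple[RiskAnchor, ...]] = {
    ("BRCA1", "breast"): (RiskAnchor(70, 0.57),),
    ("BRCA2", "breast"): (RiskAnchor(70, 0.49),),
    ("BRCA1", "ovarian"): (RiskAnchor(70, 0.40),),
    ("BRCA2", "ovarian"): (RiskAnchor(70, 0.18),),
}


def _validate_anchor_set(anchors: Sequence[RiskAnchor]) -> None:
    if not anchors:
        raise ValidationError("anchor set is empty")
    ages = [a.age for a in anchors]
    risks = [a.cumulative_risk for a in anchors]
    if any(a2 <= a1 for a1, a2 in zip(ages, ages[1:])):
        raise ValidationError(f"anchor ages must be strictly increasing, got {ages}")
    if any(r2 < r1 for r1, r2 in zip(risks, risks[1:])):
        raise ValidationError(f"anchor risks must be non-decreasing, got {risks}")


@dataclass(frozen=True)
class HazardSchedule:
    """Per-year event probabilities for one (gene, site) pair, ages 0..85."""

    gene: str
    site: str
    hazard: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        h = np.asarray(self.hazard, dtype=float)
        if h.shape != (MAX_AGE + 1,):
            raise ValidationError(
                f"hazard array must have length {MAX_AGE + 1}, got {h.shape}"
            )
        if np.any(h < 0) or np.any(h >= 1):
            raise ValidationError("hazards must lie in [0, 1)")
        object.__setattr__(self, "hazard", h)

    def cumulative(self) -> "CumulativeCurve":
        return cumulative_from_hazard(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": np.arange(MAX_AGE + 1), "hazard": self.hazard})


@dataclass(frozen=True)
class CumulativeCurve:
    """Cumulative incidence ``F(a)`` for integer ages 0..85; F(0) = 0."""

    gene: str
    site: str
    F: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.shape != (MAX_AGE + 1,):
            raise ValidationError(
                f"cumulative array must have length {MAX_AGE + 1}, got {F.shape}"
            )
        if F[0] != 0.0:
            raise ValidationError("cumulative incidence must start at 0")
        if np.any(np.diff(F) < -1e-12) or np.any(F >= 1) or np.any(F < 0):
            raise ValidationError("cumulative incidence must be non-decreasing in [0, 1)")
        object.__setattr__(self, "F", F)

    def at(self, age: int | np.ndarray) -> float | np.ndarray:
        return self.F[age]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": np.arange(MAX_AGE + 1), "cumulative": self.F})


def calibrate_hazard(
    anchors: Iterable[RiskAnchor | tuple[int, float]],
    *,
    gene: str = "BRCA1",
    site: str = "breast",
    start_age: int = DEFAULT_START_AGE,
    end_age: int = MAX_AGE,
) -> HazardSchedule:
    """Fit a piecewise-constant per-year hazard through cumulative-risk anchors.

    The hazard is 0 below ``start_age``; between consecutive anchors
    ``(a1, F1), (a2, F2)`` it is the constant ``h`` solving
    ``(1-F2) = (1-F1) * (1-h)**(a2-a1)``; past the last anchor the final
    band's hazard is held constant through ``end_age``.
    """
    anchor_list = [
        a if isinstance(a, RiskAnchor) else RiskAnchor(int(a[0]), float(a[1]))
        for a in anchors
    ]
    _validate_anchor_set(anchor_list)
    if not 0 <= start_age < anchor_list[0].age:
        raise ValidationError(
            f"start_age {start_age} must precede the first anchor age {anchor_list[0].age}"
        )
    if anchor_list[-1].age > end_age or end_age > MAX_AGE:
        raise ValidationError("anchors must not extend past end_age <= 85")

    hazard = np.zeros(MAX_AGE + 1)
    prev_age, prev_F = start_age, 0.0
    band = 0.0
    for anchor in anchor_list:
        span = anchor.age - prev_age
        surv_ratio = (1.0 - anchor.cumulative_risk) / (1.0 - prev_F)
        if surv_ratio > 1.0:  # guarded by anchor validation, kept for safety
            raise ValidationError("cumulative risk decreased between anchors")
        band = 1.0 - surv_ratio ** (1.0 / span)
        hazard[prev_age : anchor.age] = band
        prev_age, prev_F = anchor.age, anchor.cumulative_risk
    hazard[prev_age : end_age + 1] = band
    return HazardSchedule(gene=gene, site=site, hazard=hazard)


def cumulative_from_hazard(schedule: HazardSchedule) -> CumulativeCurve:
    """Convert a hazard schedule to its cumulative incidence curve.

    Uses the product form ``F(a) = 1 - prod_{j<a} (1 - h(j))``, which is the
    closed-form solution of the recursion ``F(a+1) = F(a) + (1-F(a)) h(a)``.
    """
    surv = np.cumprod(1.0 - schedule.hazard[:MAX_AGE])
    F = np.concatenate(([0.0], 1.0 - surv))
    return CumulativeCurve(gene=schedule.gene, site=schedule.site, F=F)


def apply_hazard_ratio(
    schedule: HazardSchedule, ratio: float, from_age: int
) -> HazardSchedule:
    """Multiply the per-year hazard by ``ratio`` at and above ``from_age``."""
    if not 0.0 <= ratio <= 1.0:
        raise ValidationError(f"hazard ratio {ratio} outside [0, 1]")
    if not 0 <= from_age <= MAX_AGE:
        raise ValidationError(f"from_age {from_age} outside [0, {MAX_AGE}]")
    hazard = schedule.hazard.copy()
    hazard[from_age:] *= ratio
    return replace(schedule, hazard=hazard)


def default_schedules(
    *,
    anchors: Mapping[tuple[str, str], Sequence[RiskAnchor]] | None = None,
    start_age: int = DEFAULT_START_AGE,
) -> dict[tuple[str, str], HazardSchedule]:
    """Calibrated schedules for all four (gene, site) pairs."""
    anchor_map = dict(DEFAULT_ANCHORS if anchors is None else anchors)
    out = {}
    for gene in GENES:
        for site in SITES:
            key = (gene, site)
            if key not in anchor_map:
                raise ValidationError(f"missing anchor set for {key}")
            out[key] = calibrate_hazard(
                anchor_map[key], gene=gene, site=site, start_age=start_age
            )
    return out


def mixture_curve(
    curves: Mapping[str, CumulativeCurve],
    weights: Mapping[str, float] | None = None,
    *,
    site: str = "breast",
) -> CumulativeCurve:
    """Carrier-frequency-weighted mixture of per-gene cumulative curves.

    Weights default to the general-population carrier frequencies and are
    renormalised to sum to one.
    """
    w = dict(DEFAULT_CARRIER_FREQS if weights is None else weights)
    total = sum(w[g] for g in curves)
    if total <= 0:
        raise ValidationError("mixture weights must have positive sum")
    F = sum((w[g] / total) * curves[g].F for g in curves)
    return CumulativeCurve(gene="mixture", site=site, F=np.asarray(F))


def schedules_to_frame(
    schedules: Mapping[tuple[str, str], HazardSchedule]
) -> pd.DataFrame:
    """Long-format table (gene, site, age, hazard, cumulative) for CSV export."""
    rows = []
    for (gene, site), sched in schedules.items():
        curve = cumulative_from_hazard(sched)
        rows.append(
            pd.DataFrame(
                {
                    "gene": gene,
                    "site": site,
                    "age": np.arange(MAX_AGE + 1),
                    "hazard": sched.hazard,
                    "cumulative": curve.F,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
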