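"""Individual-level synthetic mammography populations and microsimulation.

This module plays three roles:

1. generate synthetic populations with the statistical structure the
   analysis assumes — ages from a parametric or explicit distribution,
   Bernoulli BRCA1/2 carrier status at population frequencies, Bernoulli
   progression through each screening-cascade step;
2. act as the stochastic (Monte-Carlo) oracle for the deterministic cohort
   model: cancer onset ages are drawn from the calibrated per-year hazard
   schedules and surgical protection is applied as Bernoulli thinning of
   events, the individual-level counterpart of the cohort model's
   proportional case scaling;
3. emit cascade fixture files (funnel + carrier outcomes) that the cascade
   module loads unchanged.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from the spec, so identical seeds give bit-identical populations.  Scenario
comparisons use common random numbers: onset, detection, uptake and
thinning uniforms are drawn once per woman and shared across arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cascade import CarrierOutcomes, CascadeFunnel, SurgeryTally, fixture_frame
from .cohort import (
    AT_RISK_MIN_AGE,
    AgeDistribution,
    InterventionScenario,
    MAX_ENTRY_AGE,
    MIN_ENTRY_AGE,
)
from .exceptions import ValidationError
from .penetrance import (
    DEFAULT_CARRIER_FREQS,
    GENES,
    MAX_AGE,
    HazardSchedule,
    cumulative_from_hazard,
    default_schedules,
)


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of a synthetic mammography population.

    The default age model is a truncated normal (mean 52, sd 12) on ages
    18-85; the default cascade step probabilities reflect an underserved
    safety-net population: 95.9% questionnaire participation, a ~5% RST flag
    rate, 51% referral acceptance, 50% appointment attendance among
    acceptors, and 76% testing uptake.  ``rst_sensitivity`` is the
    probability that a true carrier screens RST-positive (default 1.0); the
    non-carrier flag probability is chosen so the marginal positive rate
    matches ``rst_positive_rate``.
    """

    n_women: int = 200_000
    age_model: str = "truncnorm"  # "truncnorm" | "uniform" | "explicit"
    age_mean: float = 52.0
    age_sd: float = 12.0
    age_min: int = MIN_ENTRY_AGE
    age_max: int = MAX_ENTRY_AGE
    age_distribution: AgeDistribution | None = None
    carrier_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CARRIER_FREQS)
    )
    rst_sensitivity: float = 1.0
    rst_positive_rate: float = 0.05
    participation: float = 0.959
    referral_acceptance: float = 0.51
    attendance: float = 0.50
    testing_uptake: float = 0.76
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_women <= 0:
            raise ValidationError("n_women must be > 0")
        for name in (
            "rst_sensitivity",
            "rst_positive_rate",
            "participation",
            "referral_acceptance",
            "attendance",
            "testing_uptake",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for gene, f in self.carrier_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"carrier frequency {gene}={f} outside [0, 1]")
        if sum(self.carrier_freqs.values()) > 1.0:
            raise ValidationError("carrier frequencies sum beyond 1")
        if self.age_model not in ("truncnorm", "uniform", "explicit"):
            raise ValidationError(f"unknown age model {self.age_model!r}")
        if self.age_model == "explicit" and self.age_distribution is None:
            raise ValidationError("explicit age model needs an age_distribution")


def _sample_ages(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_women
    if spec.age_model == "explicit":
        counts = spec.age_distribution.counts
        p = counts / counts.sum()
        return rng.choice(np.arange(MAX_AGE + 1), size=n, p=p)
    if spec.age_model == "uniform":
        return rng.integers(spec.age_min, spec.age_max + 1, size=n)
    draws = rng.normal(spec.age_mean, spec.age_sd, size=n)
    # redraw out-of-range values (truncation by rejection, vectorised)
    bad = (draws < spec.age_min - 0.5) | (draws >= spec.age_max + 0.5)
    while bad.any():
        draws[bad] = rng.normal(spec.age_mean, spec.age_sd, size=int(bad.sum()))
        bad = (draws < spec.age_min - 0.5) | (draws >= spec.age_max + 0.5)
    return np.rint(draws).astype(int)


def generate_population(spec: PopulationSpec) -> pd.DataFrame:
    """One row per woman: age, gene, and Bernoulli cascade step outcomes.

    Columns: ``age`` (int), ``gene`` ("none"/"BRCA1"/"BRCA2"), and booleans
    ``informative``, ``rst_positive``, ``referral_accepted``, ``attended``,
    ``tested``, ``detected`` (tested carriers; assay sensitivity 1).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_women
    ages = _sample_ages(spec, rng)

    u = rng.random(n)
    freqs = [spec.carrier_freqs.get(g, 0.0) for g in GENES]
    edges = np.cumsum(freqs)
    gene = np.full(n, "none", dtype=object)
    lo = 0.0
    for g, hi in zip(GENES, edges):
        gene[(u >= lo) & (u < hi)] = g
        lo = hi
    carrier = gene != "none"

    f_tot = float(edges[-1]) if len(edges) else 0.0
    if f_tot < 1.0:
        q_noncarrier = (spec.rst_positive_rate - f_tot * spec.rst_sensitivity) / (
            1.0 - f_tot
        )
        q_noncarrier = min(max(q_noncarrier, 0.0), 1.0)
    else:
        q_noncarrier = 0.0

    informative = rng.random(n) < spec.participation
    p_flag = np.where(carrier, spec.rst_sensitivity, q_noncarrier)
    rst_positive = informative & (rng.random(n) < p_flag)
    referral_accepted = rst_positive & (rng.random(n) < spec.referral_acceptance)
    attended = referral_accepted & (rng.random(n) < spec.attendance)
    tested = attended & (rng.random(n) < spec.testing_uptake)
    detected = tested & carrier

    return pd.DataFrame(
        {
            "age": ages,
            "gene": gene,
            "informative": informative,
            "rst_positive": rst_positive,
            "referral_accepted": referral_accepted,
            "attended": attended,
            "tested": tested,
            "detected": detected,
        }
    )


def _onset_from_uniform(
    u: np.ndarray, gene: np.ndarray, curves_by_gene: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Inverse-transform onset ages from uniforms; NaN = never (or non-carrier).

    For cumulative curve F, onset age ``a`` is the smallest age with
    ``F(a+1) > u``; ``u >= F(85)`` means no onset by 85.
    """
    onset = np.full(u.shape, np.nan)
    for g, F in curves_by_gene.items():
        mask = gene == g
        if not mask.any():
            continue
        idx = np.searchsorted(F[1:], u[mask], side="right")
        ages = idx.astype(float)
        ages[idx >= MAX_AGE] = np.nan
        onset[mask] = ages
    return onset


def sample_onsets(
    population: pd.DataFrame,
    schedules: Mapping[tuple[str, str], HazardSchedule] | None = None,
    *,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach per-site cancer onset ages drawn from the hazard schedules.

    Sampling is exact inverse transform on the cumulative curve, equivalent
    in distribution to year-by-year Bernoulli draws at the per-year hazard.
    Returns a copy with float columns ``onset_breast`` / ``onset_ovarian``
    (NaN for non-carriers and women with no onset by age 85).
    """
    if schedules is None:
        schedules = default_schedules()
    if rng is None:
        rng = np.random.default_rng(seed)
    curves = {key: cumulative_from_hazard(s).F for key, s in schedules.items()}
    gene = population["gene"].to_numpy()
    out = population.copy()
    for site in ("breast", "ovarian"):
        u = rng.random(len(population))
        by_gene = {g: curves[(g, site)] for g in GENES}
        out[f"onset_{site}"] = _onset_from_uniform(u, gene, by_gene)
    return out


def _counted_cases(
    ages: np.ndarray,
    onset: np.ndarray,
    ratio: np.ndarray,
    u_thin: np.ndarray,
    horizon: int,
) -> np.ndarray:
    """Boolean counted-case indicator per woman for one site.

    A case counts when the onset falls inside the at-risk window
    (>= max(entry age, 35), <= 84), within the calendar horizon, and
    survives Bernoulli thinning at the woman's arm-specific risk ratio.
    Onsets before window entry are prevalent cases and never count.
    """
    window_entry = np.maximum(ages, AT_RISK_MIN_AGE)
    in_window = (
        ~np.isnan(onset)
        & (onset >= window_entry)
        & (onset <= MAX_AGE - 1)
        & (onset < ages + horizon)
    )
    return in_window & (u_thin < ratio)


@dataclass(frozen=True)
class MicrosimEstimate:
    reduction_pct: float
    se_pct: float
    cases_baseline: int
    cases_intervention: int


def microsim_reduction(
    spec: PopulationSpec,
    scenario: InterventionScenario,
    schedules: Mapping[tuple[str, str], HazardSchedule] | None = None,
    horizon: int | None = None,
) -> dict[str, MicrosimEstimate]:
    """Monte-Carlo reduction estimate versus no intervention, per site.

    The intervention and baseline runs share one population and one set of
    uniforms (common random numbers), so the comparison noise comes only
    from detection/uptake assignment and event thinning.  Conditional on the
    baseline cases X, each case survives into the intervention count with a
    known probability ``k_i`` (marginal over arm assignment and thinning),
    so the reported standard error is the exact binomial
    ``sqrt(sum k_i (1 - k_i)) / sum(X)`` of the survival ratio.
    """
    if schedules is None:
        schedules = default_schedules()
    H = scenario.horizon_years if horizon is None else horizon

    rng = np.random.default_rng(spec.seed)
    ages_all = _sample_ages(spec, rng)
    u_gene = rng.random(spec.n_women)
    freqs = [spec.carrier_freqs.get(g, 0.0) for g in GENES]
    edges = np.cumsum(freqs)
    gene_all = np.full(spec.n_women, "none", dtype=object)
    lo = 0.0
    for g, hi in zip(GENES, edges):
        gene_all[(u_gene >= lo) & (u_gene < hi)] = g
        lo = hi
    carrier = gene_all != "none"

    # Only carriers can have events; restrict all further draws to them.
    ages = ages_all[carrier]
    gene = gene_all[carrier]
    nc = ages.size
    u_detect = rng.random(nc)
    u_mast = rng.random(nc)
    u_ooph = rng.random(nc)
    u_onset = {site: rng.random(nc) for site in ("breast", "ovarian")}
    u_thin = {site: rng.random(nc) for site in ("breast", "ovarian")}

    curves = {key: cumulative_from_hazard(s).F for key, s in schedules.items()}
    onset = {
        site: _onset_from_uniform(
            u_onset[site], gene, {g: curves[(g, site)] for g in GENES}
        )
        for site in ("breast", "ovarian")
    }

    detected = u_detect < scenario.detection_rate
    mast = detected & (u_mast < scenario.mastectomy_uptake)
    ooph = detected & (u_ooph < scenario.oophorectomy_uptake)

    ratio_b = np.ones(nc)
    ooph_only = ooph & ~mast & (ages < scenario.breast_protection_age_cutoff)
    ratio_b[ooph_only] = scenario.eff_oophorectomy_breast_before50
    ratio_b[mast] = scenario.eff_mastectomy_breast
    ratio_v = np.ones(nc)
    ratio_v[ooph] = scenario.eff_oophorectomy_ovarian
    ratios = {"breast": ratio_b, "ovarian": ratio_v}

    # Marginal case-survival probability per carrier: detection, then the
    # arm mix (mastectomy dominates on breast; oophorectomy-before-50 rule).
    d, m, o = (
        scenario.detection_rate,
        scenario.mastectomy_uptake,
        scenario.oophorectomy_uptake,
    )
    r_age = np.where(
        ages < scenario.breast_protection_age_cutoff,
        scenario.eff_oophorectomy_breast_before50,
        1.0,
    )
    keep = {
        "breast": 1.0
        - d
        + d
        * (
            m * scenario.eff_mastectomy_breast
            + (1.0 - m) * o * r_age
            + (1.0 - m) * (1.0 - o)
        ),
        "ovarian": np.full(
            nc, 1.0 - d + d * (o * scenario.eff_oophorectomy_ovarian + (1.0 - o))
        ),
    }

    out = {}
    for site in ("breast", "ovarian"):
        ones = np.ones(nc)
        X = _counted_cases(ages, onset[site], ones, u_thin[site], H)
        Y = _counted_cases(ages, onset[site], ratios[site], u_thin[site], H)
        sx, sy = int(X.sum()), int(Y.sum())
        if sx == 0:
            out[site] = MicrosimEstimate(0.0, float("nan"), 0, sy)
            continue
        R = sy / sx
        k = keep[site][X]
        var_Y = float((k * (1.0 - k)).sum())
        out[site] = MicrosimEstimate(
            reduction_pct=100.0 * (1.0 - R),
            se_pct=100.0 * np.sqrt(var_Y) / sx,
            cases_baseline=sx,
            cases_intervention=sy,
        )
    return out


def emit_cascade_fixture(
    population: pd.DataFrame, label: str = "synthetic"
) -> tuple[CascadeFunnel, CarrierOutcomes]:
    """Summarise a generated population into cascade fixture objects.

    The funnel counts are monotone by construction.  If onset columns are
    present, detected carriers are classified as prior / concomitant /
    unaffected relative to their entry age; synthetic stages are unknown
    (stage at diagnosis is not modelled).
    """
    counts = {
        "screened": int(len(population)),
        "informative": int(population["informative"].sum()),
        "rst_positive": int(population["rst_positive"].sum()),
        "referral_accepted": int(population["referral_accepted"].sum()),
        "attended": int(population["attended"].sum()),
        "tested": int(population["tested"].sum()),
        "carriers_detected": int(population["detected"].sum()),
    }
    funnel = CascadeFunnel(population=label, counts=counts)

    affected: dict[str, float] = {}
    stages: dict[tuple[str, str], float] = {}
    surgery: dict[str, dict[str, SurgeryTally]] = {}
    if "onset_breast" in population.columns:
        det = population[population["detected"]]
        onset_min = det[["onset_breast", "onset_ovarian"]].min(axis=1)
        prior = onset_min < det["age"]
        concomitant = onset_min == det["age"]
        affected = {
            "prior": int(prior.sum()),
            "concomitant": int(concomitant.sum()),
            "unaffected": int((~(prior | concomitant)).sum()),
        }
        for site in ("breast", "ovarian"):
            n_aff = int((det[f"onset_{site}"] <= det["age"]).sum())
            if n_aff:
                stages[(site, "unknown")] = n_aff
    outcomes = CarrierOutcomes(
        population=label, affected=affected, stages=stages, surgery=surgery
    )
    return funnel, outcomes


def write_cascade_fixture(
    population: pd.DataFrame, path, label: str = "synthetic"
) -> pd.DataFrame:
    """Write a fixture CSV (cascade schema) for a generated population."""
    funnel, outcomes = emit_cascade_fixture(population, label)
    frame = fixture_frame(funnel, outcomes)
    frame.to_csv(path, index=False)
    return frame
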