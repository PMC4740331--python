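"""Deterministic age-structured cohort model of cancer prevention.

The model follows expected (real-valued) counts of BRCA1/2 mutation carriers
through yearly age steps.  Women enter at their current age; those aged
35-85 and cancer-free form the "at-risk" pool (prevalent cases are removed
at window entry using the cumulative penetrance at that age), women aged
18-34 age into the window during follow-up.  Each year every stratum loses
``at_risk * h(age)`` women to a cancer event or — in a surgical arm — to an
averted event, and the pool is reset before the next year.

Intervention arms (none / mastectomy / oophorectomy / both) are formed at
cohort entry from the mutation-detection rate and the surgery-uptake
fractions, with surgery at identification.  Surgical efficacy is applied as
proportional case scaling: the counted incident cancers in an arm are the
arm's risk ratio times the pool exits, so full uptake of a surgery with a
0.05 risk ratio yields exactly a 95% reduction in counted cancers.
Oophorectomy protects against breast cancer (ratio 0.50) only for women
whose surgery — i.e. cohort entry — happens before age 50.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ValidationError
from .penetrance import (
    GENES,
    MAX_AGE,
    SITES,
    CumulativeCurve,
    DEFAULT_CARRIER_FREQS,
    HazardSchedule,
    cumulative_from_hazard,
    default_schedules,
)

#: Intervention arms, in storage order.
ARMS = ("none", "mastectomy", "oophorectomy", "both")

#: Ages represented in a simulation population.
MIN_ENTRY_AGE, MAX_ENTRY_AGE = 18, 85
ENTRY_AGES = np.arange(MIN_ENTRY_AGE, MAX_ENTRY_AGE + 1)

#: The at-risk window: carriers aged 35-85 and cancer-free.
AT_RISK_MIN_AGE = 35


class AgeDistribution:
    """Counts of women per integer age 18-85 (real-valued counts allowed)."""

    def __init__(self, counts: Mapping[int, float] | np.ndarray):
        arr = np.zeros(MAX_AGE + 1)
        if isinstance(counts, Mapping):
            for age, n in counts.items():
                if not MIN_ENTRY_AGE <= int(age) <= MAX_ENTRY_AGE:
                    raise ValidationError(f"age {age} outside [18, 85]")
                arr[int(age)] = float(n)
        else:
            counts = np.asarray(counts, dtype=float)
            if counts.shape == (MAX_AGE + 1,):
                arr = counts.copy()
            elif counts.shape == (ENTRY_AGES.size,):
                arr[MIN_ENTRY_AGE:] = counts
            else:
                raise ValidationError(
                    "counts array must cover ages 0..85 or 18..85"
                )
        if np.any(arr < 0):
            raise ValidationError("age counts must be non-negative")
        if np.any(arr[:MIN_ENTRY_AGE] > 0):
            raise ValidationError("no women below age 18 allowed")
        if arr.sum() <= 0:
            raise ValidationError("age distribution must have positive total")
        self.counts = arr

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def single_age(cls, age: int, n: float) -> "AgeDistribution":
        return cls({age: n})

    @classmethod
    def from_ages(cls, ages: np.ndarray) -> "AgeDistribution":
        """Empirical distribution from an array of individual integer ages."""
        counts = np.bincount(np.asarray(ages, dtype=int), minlength=MAX_AGE + 1)
        return cls(counts[: MAX_AGE + 1].astype(float))

    @classmethod
    def truncated_normal(
        cls,
        n_women: float,
        mean: float = 52.0,
        sd: float = 12.0,
        low: int = MIN_ENTRY_AGE,
        high: int = MAX_ENTRY_AGE,
    ) -> "AgeDistribution":
        """Expected counts under a truncated-normal age model.

        Integer age ``a`` receives mass proportional to the normal probability
        of ``[a - 0.5, a + 0.5)`` truncated to ``[low - 0.5, high + 0.5)``.
        """
        edges = np.arange(low, high + 2) - 0.5
        cdf = stats.norm.cdf(edges, loc=mean, scale=sd)
        mass = np.diff(cdf)
        weights = mass / mass.sum()
        counts = np.zeros(MAX_AGE + 1)
        counts[low : high + 1] = n_women * weights
        return cls(counts)

    @classmethod
    def from_csv(cls, path) -> "AgeDistribution":
        df = pd.read_csv(path)
        if not {"age", "count"} <= set(df.columns):
            raise ValidationError("age-distribution CSV needs columns (age, count)")
        return cls(dict(zip(df["age"].astype(int), df["count"].astype(float))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": ENTRY_AGES, "count": self.counts[MIN_ENTRY_AGE:]})


@dataclass(frozen=True)
class InterventionScenario:
    """Detection, surgery uptake, efficacy and horizon for one scenario.

    ``detection_rate`` is the fraction of carriers identified; uptake
    fractions apply among identified carriers and are treated as independent
    (the both-surgeries arm fraction is their product).  Efficacies are risk
    ratios on counted cancers; oophorectomy's breast protection requires
    surgery before ``breast_protection_age_cutoff``.
    """

    name: str = "scenario"
    detection_rate: float = 0.0
    mastectomy_uptake: float = 0.0
    oophorectomy_uptake: float = 0.0
    eff_mastectomy_breast: float = 0.05
    eff_oophorectomy_ovarian: float = 0.05
    eff_oophorectomy_breast_before50: float = 0.50
    breast_protection_age_cutoff: int = 50
    horizon_years: int = 30

    def __post_init__(self) -> None:
        for name in (
            "detection_rate",
            "mastectomy_uptake",
            "oophorectomy_uptake",
            "eff_mastectomy_breast",
            "eff_oophorectomy_ovarian",
            "eff_oophorectomy_breast_before50",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.horizon_years < 1:
            raise ValidationError("horizon_years must be >= 1")

    def arm_fractions(self) -> dict[str, float]:
        """Fraction of all carriers in each intervention arm."""
        d, m, o = self.detection_rate, self.mastectomy_uptake, self.oophorectomy_uptake
        fracs = {
            "none": 1.0 - d + d * (1.0 - m) * (1.0 - o),
            "mastectomy": d * m * (1.0 - o),
            "oophorectomy": d * o * (1.0 - m),
            "both": d * m * o,
        }
        if not np.isclose(sum(fracs.values()), 1.0):
            raise ValidationError("arm fractions must sum to 1")
        return fracs

    def case_ratio_matrix(self) -> np.ndarray:
        """Counted-case risk ratios, shape (site, arm, entry_age).

        Breast: the mastectomy ratio in the mastectomy and both arms (the
        stronger mastectomy protection dominates; ratios are not compounded),
        the oophorectomy-before-50 ratio in the oophorectomy-only arm for
        entry ages below the cutoff.  Ovarian: the oophorectomy ratio in the
        oophorectomy and both arms.
        """
        ratio = np.ones((len(SITES), len(ARMS), ENTRY_AGES.size))
        b, v = SITES.index("breast"), SITES.index("ovarian")
        i_m, i_o, i_b = ARMS.index("mastectomy"), ARMS.index("oophorectomy"), ARMS.index("both")
        ratio[b, i_m, :] = self.eff_mastectomy_breast
        ratio[b, i_b, :] = self.eff_mastectomy_breast
        young = ENTRY_AGES < self.breast_protection_age_cutoff
        ratio[b, i_o, young] = self.eff_oophorectomy_breast_before50
        ratio[v, i_o, :] = self.eff_oophorectomy_ovarian
        ratio[v, i_b, :] = self.eff_oophorectomy_ovarian
        return ratio

    @classmethod
    def baseline(cls, horizon_years: int = 30) -> "InterventionScenario":
        return cls(name="no-intervention", horizon_years=horizon_years)


@dataclass
class CohortState:
    """At-risk bookkeeping, per (gene, site, arm, entry-age) stratum.

    ``pending`` holds carriers who entered younger than 35 and have not yet
    aged into the at-risk window; ``entry_pool`` accumulates each stratum's
    at-risk count at window entry; ``cum_exits`` the cumulative pool exits
    (cancer events, or averted events in a surgical arm).
    """

    at_risk: np.ndarray  # (gene, site, arm, entry_age)
    pending: np.ndarray  # (gene, arm, entry_age)
    entry_pool: np.ndarray  # like at_risk
    cum_exits: np.ndarray  # like at_risk
    curves: dict[tuple[str, str], CumulativeCurve] = field(repr=False, default_factory=dict)
    t: int = 0

    def conservation_gap(self) -> float:
        """Max |entry_pool - (at_risk + cum_exits)| over all strata."""
        return float(np.abs(self.entry_pool - (self.at_risk + self.cum_exits)).max())


def initialize_at_risk(
    dist: AgeDistribution,
    curves: Mapping[tuple[str, str], CumulativeCurve],
    carrier_freqs: Mapping[str, float] | None = None,
    arm_fractions: Mapping[str, float] | None = None,
) -> CohortState:
    """Build the entry cohort, subtracting prevalent cases at window entry.

    Carriers at age ``a`` number ``dist(a) * freq(gene)``; for entry ages in
    the at-risk window the site-specific at-risk count is
    ``carriers * (1 - F_site(a))``.  Younger carriers wait in ``pending``.
    """
    freqs = dict(DEFAULT_CARRIER_FREQS if carrier_freqs is None else carrier_freqs)
    fracs = dict(arm_fractions) if arm_fractions is not None else {"none": 1.0}
    for gene in GENES:
        for site in SITES:
            if (gene, site) not in curves:
                raise ConfigurationError(f"missing cumulative curve for {(gene, site)}")

    G, S, K, A = len(GENES), len(SITES), len(ARMS), ENTRY_AGES.size
    at_risk = np.zeros((G, S, K, A))
    pending = np.zeros((G, K, A))
    frac_vec = np.array([fracs.get(arm, 0.0) for arm in ARMS])
    in_window = ENTRY_AGES >= AT_RISK_MIN_AGE

    for gi, gene in enumerate(GENES):
        carriers = dist.counts[MIN_ENTRY_AGE:] * freqs.get(gene, 0.0)  # (A,)
        by_arm = carriers[None, :] * frac_vec[:, None]  # (K, A)
        pending[gi] = np.where(in_window[None, :], 0.0, by_arm)
        for si, site in enumerate(SITES):
            F = curves[(gene, site)].F[ENTRY_AGES]
            at_risk[gi, si] = np.where(in_window[None, :], by_arm * (1.0 - F[None, :]), 0.0)

    return CohortState(
        at_risk=at_risk,
        pending=pending,
        entry_pool=at_risk.copy(),
        cum_exits=np.zeros_like(at_risk),
        curves=dict(curves),
    )


def step_year(
    state: CohortState,
    schedules: Mapping[tuple[str, str], HazardSchedule],
    scenario: InterventionScenario,
) -> tuple[CohortState, np.ndarray]:
    """Advance the cohort one year; return (state, counted incidents).

    Pending strata whose current age reaches 35 are activated first (with
    prevalence at 35 subtracted).  For each active stratum the pool exits are
    ``at_risk * h(age)``; counted incident cancers are the exits times the
    arm's case risk ratio; the at-risk pool is then reset by subtracting the
    exits.  Strata at age 85+ no longer contribute.  Incidents are returned
    as an array of shape (site, arm).
    """
    cur_age = ENTRY_AGES + state.t

    # Activate strata ageing into the 35-85 window this year.
    act = np.where(cur_age == AT_RISK_MIN_AGE)[0]
    if act.size and state.pending[:, :, act].sum() > 0:
        for gi, gene in enumerate(GENES):
            pend = state.pending[gi][:, act]  # (K, n_act)
            for si, site in enumerate(SITES):
                F35 = state.curves[(gene, site)].F[AT_RISK_MIN_AGE]
                fresh = pend * (1.0 - F35)
                state.at_risk[gi, si][:, act] = fresh
                state.entry_pool[gi, si][:, act] += fresh
            state.pending[gi][:, act] = 0.0

    active = (cur_age >= AT_RISK_MIN_AGE) & (cur_age < MAX_AGE)
    age_idx = np.clip(cur_age, 0, MAX_AGE)
    ratio = scenario.case_ratio_matrix()  # (S, K, A)

    incidents = np.zeros((len(SITES), len(ARMS)))
    for gi, gene in enumerate(GENES):
        for si, site in enumerate(SITES):
            h = schedules[(gene, site)].hazard[age_idx] * active  # (A,)
            exits = state.at_risk[gi, si] * h[None, :]  # (K, A)
            counted = exits * ratio[si]
            state.at_risk[gi, si] -= exits
            state.cum_exits[gi, si] += exits
            incidents[si] += counted.sum(axis=1)
    state.t += 1
    return state, incidents


@dataclass(frozen=True)
class CohortTrajectory:
    """Per-year counted incident cancers by site and arm, plus entry pools."""

    scenario: InterventionScenario
    incidents: np.ndarray = field(repr=False)  # (horizon, site, arm)
    entry_pool: dict[str, float]  # site -> at-risk women entering the window

    @property
    def horizon(self) -> int:
        return self.incidents.shape[0]

    def per_year(self, site: str) -> np.ndarray:
        return self.incidents[:, SITES.index(site), :].sum(axis=1)

    def cumulative(self, site: str, horizon: int | None = None) -> float:
        h = self.horizon if horizon is None else horizon
        if not 0 < h <= self.horizon:
            raise ValidationError(f"horizon {h} outside (0, {self.horizon}]")
        return float(self.per_year(site)[:h].sum())

    def cumulative_series(self, site: str) -> np.ndarray:
        return np.cumsum(self.per_year(site))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for si, site in enumerate(SITES):
            for ki, arm in enumerate(ARMS):
                inc = self.incidents[:, si, ki]
                rows.append(
                    pd.DataFrame(
                        {
                            "year": np.arange(1, self.horizon + 1),
                            "site": site,
                            "arm": arm,
                            "incident": inc,
                            "cumulative": np.cumsum(inc),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def run_scenario(
    dist: AgeDistribution,
    scenario: InterventionScenario,
    schedules: Mapping[tuple[str, str], HazardSchedule],
    carrier_freqs: Mapping[str, float] | None = None,
) -> CohortTrajectory:
    """Run the yearly recursion for ``scenario.horizon_years`` years."""
    curves = {key: cumulative_from_hazard(s) for key, s in schedules.items()}
    state = initialize_at_risk(dist, curves, carrier_freqs, scenario.arm_fractions())
    incidents = np.zeros((scenario.horizon_years, len(SITES), len(ARMS)))
    for t in range(scenario.horizon_years):
        state, incidents[t] = step_year(state, schedules, scenario)
    entry = {
        site: float(state.entry_pool[:, SITES.index(site), :, :].sum())
        for site in SITES
    }
    return CohortTrajectory(scenario=scenario, incidents=incidents, entry_pool=entry)


def percent_reduction(
    baseline: CohortTrajectory,
    intervention: CohortTrajectory,
    site: str,
    horizon: int | None = None,
) -> float:
    """``100 * (1 - cum_intervention / cum_baseline)`` at the horizon."""
    if baseline.horizon != intervention.horizon and horizon is None:
        raise ValidationError(
            f"mismatched horizons: {baseline.horizon} vs {intervention.horizon}"
        )
    cb = baseline.cumulative(site, horizon)
    if cb == 0.0:
        return 0.0
    return 100.0 * (1.0 - intervention.cumulative(site, horizon) / cb)


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    p_value: float
    table: np.ndarray = field(repr=False)
    low_expected: bool = False


def compare_chisq(
    baseline: CohortTrajectory,
    intervention: CohortTrajectory,
    site: str,
    horizon: int | None = None,
) -> ChisqResult:
    """Pearson chi-square on {cancer, no cancer} x {baseline, intervention}.

    Cell counts are the rounded expected cumulative cases by the horizon and
    the rounded remainder of each arm's entry pool.  A cell with expectation
    below 1 sets ``low_expected`` (and yields NaN statistics when a margin is
    empty) rather than raising.
    """
    if baseline.horizon != intervention.horizon and horizon is None:
        raise ValidationError("mismatched horizons")
    rows = []
    for traj in (baseline, intervention):
        cases = round(traj.cumulative(site, horizon))
        n = round(traj.entry_pool[site])
        rows.append([cases, max(n - cases, 0)])
    table = np.array(rows, dtype=float)
    total = table.sum()
    if total == 0:
        return ChisqResult(float("nan"), float("nan"), table, low_expected=True)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    low = bool((expected < 1).any())
    if (expected == 0).any():
        return ChisqResult(float("nan"), float("nan"), table, low_expected=True)
    statistic = float(((table - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(statistic, df=1)) if statistic > 0 else 1.0
    return ChisqResult(statistic, p_value, table, low_expected=low)


class CohortModel:
    """Convenience wrapper tying an age distribution to calibrated schedules.

    Parameters
    ----------
    age_distribution:
        Simulation population (women per integer age 18-85).
    schedules:
        Per-(gene, site) hazard schedules; defaults to the anchor-calibrated
        BRCA1/2 breast and ovarian schedules.
    carrier_freqs:
        Per-gene population carrier frequencies (defaults 0.058% / 0.068%).
    """

    def __init__(
        self,
        age_distribution: AgeDistribution,
        schedules: Mapping[tuple[str, str], HazardSchedule] | None = None,
        carrier_freqs: Mapping[str, float] | None = None,
    ):
        self.age_distribution = age_distribution
        self.schedules = dict(schedules) if schedules is not None else default_schedules()
        self.carrier_freqs = dict(
            DEFAULT_CARRIER_FREQS if carrier_freqs is None else carrier_freqs
        )

    def run(self, scenario: InterventionScenario) -> CohortTrajectory:
        return run_scenario(
            self.age_distribution, scenario, self.schedules, self.carrier_freqs
        )

    def baseline(self, horizon_years: int = 30) -> CohortTrajectory:
        return self.run(InterventionScenario.baseline(horizon_years))

    def reduction_summary(
        self, scenario: InterventionScenario, baseline: CohortTrajectory | None = None
    ) -> dict:
        """Percent reductions and chi-square comparisons for both sites."""
        base = baseline if baseline is not None else self.baseline(scenario.horizon_years)
        traj = self.run(scenario)
        out: dict = {"scenario": scenario.name, "horizon_years": scenario.horizon_years}
        for site in SITES:
            chisq = compare_chisq(base, traj, site)
            out[site] = {
                "baseline_cases": base.cumulative(site),
                "intervention_cases": traj.cumulative(site),
                "percent_reduction": percent_reduction(base, traj, site),
                "chisq_statistic": chisq.statistic,
                "chisq_p_value": chisq.p_value,
                "chisq_low_expected": chisq.low_expected,
            }
        return out
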