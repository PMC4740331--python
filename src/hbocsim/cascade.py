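"""Screening-cascade (funnel) accounting for a mammography population.

A mammography screening programme for hereditary breast/ovarian cancer
(HBOC) proceeds through ordered steps with attrition at each one: women
screened at mammography -> family history provided (informative) -> flagged
high-risk by the referral screening tool (RST) -> referral accepted ->
genetic-counselling appointment attended -> BRCA1/2 test completed ->
mutation carrier detected.  This module loads integer step counts and
carrier-outcome tallies from fixture CSV files and re-derives every funnel
rate, the detection rate against the expected carrier count, prophylactic
surgery uptake and advanced-stage fractions — percentages are never stored,
only recomputed from counts.

Fixture CSV schema: ``population, record, stratum, count`` where ``record``
is one of ``funnel`` (stratum = step name or ``carriers_expected``),
``affected`` (prior / concomitant / unaffected, among newly identified
carriers), ``stage`` (stratum ``site:stage``, stage in 0/I/II/III/IV/
unknown), ``<surgery>_elected`` / ``<surgery>_eligible`` (stratum names the
carrier group), or ``metadata`` (carried through untouched).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import ValidationError

#: Funnel steps, in order; each count must not exceed the previous known one.
FUNNEL_ORDER = (
    "screened",
    "informative",
    "rst_positive",
    "referral_accepted",
    "attended",
    "tested",
    "carriers_detected",
)

ADVANCED_STAGES = frozenset({"III", "IV"})
KNOWN_STAGES = frozenset({"0", "I", "II", "III", "IV", "unknown"})
SURGERIES = ("mastectomy", "oophorectomy")


@dataclass(frozen=True)
class Rate:
    """A percentage kept as numerator/denominator; undefined when denom is 0."""

    numerator: float | None
    denominator: float | None

    @property
    def defined(self) -> bool:
        return (
            self.numerator is not None
            and self.denominator is not None
            and self.denominator > 0
        )

    @property
    def fraction(self) -> float | None:
        return self.numerator / self.denominator if self.defined else None

    def pct(self, ndigits: int = 1) -> float | None:
        if not self.defined:
            return None
        value = round(100.0 * self.fraction, ndigits)
        return int(value) if ndigits == 0 else value

    def to_dict(self) -> dict:
        return {
            "numerator": self.numerator,
            "denominator": self.denominator,
            "pct": self.pct(),
        }


@dataclass(frozen=True)
class CascadeFunnel:
    """Counts at each screening step; missing (unpublished) steps are None."""

    population: str
    counts: Mapping[str, float | None]
    carriers_expected: float | None = None

    def __post_init__(self) -> None:
        known = []
        for step in FUNNEL_ORDER:
            n = self.counts.get(step)
            if n is None:
                continue
            if n < 0:
                raise ValidationError(f"{self.population}: {step} count {n} < 0")
            known.append((step, n))
        for (s1, n1), (s2, n2) in zip(known, known[1:]):
            if n2 > n1:
                raise ValidationError(
                    f"{self.population}: funnel not monotone ({s2}={n2} > {s1}={n1})"
                )
        if self.carriers_expected is not None and self.carriers_expected < 0:
            raise ValidationError("carriers_expected must be >= 0")

    def get(self, step: str) -> float | None:
        return self.counts.get(step)


@dataclass(frozen=True)
class SurgeryTally:
    elected: float
    eligible: float

    def __post_init__(self) -> None:
        if self.elected < 0 or self.eligible < 0 or self.elected > self.eligible:
            raise ValidationError(
                f"invalid surgery tally: elected {self.elected} of {self.eligible}"
            )


@dataclass(frozen=True)
class CarrierOutcomes:
    """Aggregate outcome tallies for the detected carriers of one population.

    ``affected`` counts newly identified carriers by cancer status
    (prior / concomitant / unaffected); ``stages`` maps (site, stage) to a
    count among affected carriers; ``surgery[name][group]`` holds
    elected/eligible tallies with eligibility already applied (oophorectomy:
    over 35 with at least one intact ovary; mastectomy: female carriers).
    """

    population: str
    affected: Mapping[str, float] = field(default_factory=dict)
    stages: Mapping[tuple[str, str], float] = field(default_factory=dict)
    surgery: Mapping[str, Mapping[str, SurgeryTally]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (site, stage), n in self.stages.items():
            if stage not in KNOWN_STAGES:
                raise ValidationError(f"unknown stage label {stage!r}")
            if n < 0:
                raise ValidationError(f"negative stage count for {(site, stage)}")

    def affected_fraction(self) -> Rate:
        """Carriers with a prior or concomitant cancer, among newly identified."""
        prior = self.affected.get("prior", 0)
        conc = self.affected.get("concomitant", 0)
        total = prior + conc + self.affected.get("unaffected", 0)
        return Rate(prior + conc, total if total > 0 else None)


@dataclass(frozen=True)
class CarrierFrequencyModel:
    """Population BRCA1/2 carrier frequencies, with an Ashkenazi adjustment."""

    freq_brca1: float = 0.00058
    freq_brca2: float = 0.00068
    aj_fraction: float = 0.0
    aj_carrier_rate: float = 0.025

    def __post_init__(self) -> None:
        for name in ("freq_brca1", "freq_brca2", "aj_fraction", "aj_carrier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


def expected_carriers(n: float, model: CarrierFrequencyModel | None = None) -> float:
    """Expected BRCA1/2 carriers among ``n`` women.

    ``n * [(1 - aj) * (f1 + f2) + aj * aj_rate]``; with no Ashkenazi fraction
    this reduces to ``n * 0.00126`` under the default frequencies.
    """
    if n < 0:
        raise ValidationError("population size must be >= 0")
    m = model if model is not None else CarrierFrequencyModel()
    base = m.freq_brca1 + m.freq_brca2
    return n * ((1.0 - m.aj_fraction) * base + m.aj_fraction * m.aj_carrier_rate)


def detection_rate(detected: float, expected: float, ndigits: int = 1) -> float:
    """Detected carriers as a percentage of those expected."""
    if expected <= 0:
        raise ValidationError("expected carrier count must be > 0")
    return round(100.0 * detected / expected, ndigits)


def funnel_rates(funnel: CascadeFunnel) -> dict[str, Rate]:
    """Step-to-step rates; a rate over a missing or zero count is undefined."""
    c = funnel.get
    return {
        "participation": Rate(c("informative"), c("screened")),
        "rst_positivity": Rate(c("rst_positive"), c("informative")),
        "referral_acceptance": Rate(c("referral_accepted"), c("rst_positive")),
        "attendance": Rate(c("attended"), c("referral_accepted")),
        "testing_uptake": Rate(c("tested"), c("attended")),
        "test_yield": Rate(c("carriers_detected"), c("tested")),
        "detection_vs_expected": Rate(c("carriers_detected"), funnel.carriers_expected),
    }


def surgery_uptake(outcomes: CarrierOutcomes, surgery: str) -> dict[str, Rate]:
    """Uptake among eligible carriers, per stored group plus overall."""
    if surgery not in SURGERIES:
        raise ValidationError(f"unknown surgery {surgery!r}")
    groups = outcomes.surgery.get(surgery, {})
    rates = {g: Rate(t.elected, t.eligible) for g, t in groups.items()}
    elected = sum(t.elected for t in groups.values())
    eligible = sum(t.eligible for t in groups.values())
    rates["overall"] = Rate(elected, eligible if eligible > 0 else None)
    return rates


def advanced_stage_fraction(outcomes: CarrierOutcomes, ndigits: int = 0) -> float:
    """Percent of known-stage cancers at stage III or IV (unknown excluded)."""
    known = sum(n for (_, stage), n in outcomes.stages.items() if stage != "unknown")
    if known == 0:
        raise ValidationError("no records with known stage")
    advanced = sum(
        n for (_, stage), n in outcomes.stages.items() if stage in ADVANCED_STAGES
    )
    value = round(100.0 * advanced / known, ndigits)
    return int(value) if ndigits == 0 else value


def packaged_fixture_paths() -> list[Path]:
    """Paths of the cascade fixture CSVs shipped with the package."""
    from importlib.resources import files

    data_dir = files("hbocsim") / "data"
    names = ("underserved_cascade.csv", "insured_cascade.csv", "combined_screening.csv")
    return [Path(str(data_dir / name)) for name in names]


@dataclass
class CascadeData:
    """Parsed fixture contents: per-population funnels, outcomes, metadata."""

    funnels: dict[str, CascadeFunnel] = field(default_factory=dict)
    outcomes: dict[str, CarrierOutcomes] = field(default_factory=dict)
    metadata: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        return sorted(self.funnels)


def read_fixture(paths: str | Path | Iterable[str | Path]) -> CascadeData:
    """Load one or more fixture CSV files into a :class:`CascadeData`."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for p in paths:
        df = pd.read_csv(p, dtype={"stratum": str})
        missing = {"population", "record", "stratum", "count"} - set(df.columns)
        if missing:
            raise ValidationError(f"{p}: fixture missing columns {sorted(missing)}")
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    return parse_fixture_frame(df)


def parse_fixture_frame(df: pd.DataFrame) -> CascadeData:
    data = CascadeData()
    for pop, rows in df.groupby("population"):
        counts: dict[str, float] = {}
        expected = None
        affected: dict[str, float] = {}
        stages: dict[tuple[str, str], float] = {}
        surgery: dict[str, dict[str, SurgeryTally]] = {}
        raw_surgery: dict[str, dict[str, dict[str, float]]] = {}
        meta: dict[str, float] = {}
        for _, row in rows.iterrows():
            record, stratum, n = row["record"], row["stratum"], float(row["count"])
            if record == "funnel":
                if stratum == "carriers_expected":
                    expected = n
                elif stratum in FUNNEL_ORDER:
                    counts[stratum] = n
                else:
                    raise ValidationError(f"{pop}: unknown funnel step {stratum!r}")
            elif record == "affected":
                affected[stratum] = n
            elif record == "stage":
                site, _, stage = stratum.partition(":")
                if not stage:
                    raise ValidationError(f"{pop}: stage stratum must be 'site:stage'")
                stages[(site, stage)] = n
            elif record == "metadata":
                meta[stratum] = n
            else:
                matched = False
                for surg in SURGERIES:
                    for kind in ("elected", "eligible"):
                        if record == f"{surg}_{kind}":
                            raw_surgery.setdefault(surg, {}).setdefault(stratum, {})[
                                kind
                            ] = n
                            matched = True
                if not matched:
                    raise ValidationError(f"{pop}: unknown record type {record!r}")
        for surg, groups in raw_surgery.items():
            surgery[surg] = {}
            for group, kinds in groups.items():
                if set(kinds) != {"elected", "eligible"}:
                    raise ValidationError(
                        f"{pop}: {surg} group {group!r} needs elected and eligible"
                    )
                surgery[surg][group] = SurgeryTally(kinds["elected"], kinds["eligible"])
        data.funnels[pop] = CascadeFunnel(
            population=pop, counts=counts, carriers_expected=expected
        )
        data.outcomes[pop] = CarrierOutcomes(
            population=pop, affected=affected, stages=stages, surgery=surgery
        )
        data.metadata[pop] = meta
    return data


def cascade_report(data: CascadeData) -> dict:
    """Full JSON-serialisable report: every rate re-derived from counts."""
    report: dict = {"populations": {}}
    for pop in data.populations:
        funnel = data.funnels[pop]
        outcomes = data.outcomes[pop]
        entry: dict = {
            "funnel_counts": {
                step: funnel.get(step)
                for step in FUNNEL_ORDER
                if funnel.get(step) is not None
            },
            "carriers_expected": funnel.carriers_expected,
            "rates": {k: r.to_dict() for k, r in funnel_rates(funnel).items()},
            "metadata": data.metadata.get(pop, {}),
        }
        entry["affected_fraction"] = outcomes.affected_fraction().to_dict()
        for surg in SURGERIES:
            if outcomes.surgery.get(surg):
                entry[f"{surg}_uptake"] = {
                    g: r.to_dict() for g, r in surgery_uptake(outcomes, surg).items()
                }
        if any(stage != "unknown" for _, stage in outcomes.stages):
            entry["advanced_stage_pct"] = advanced_stage_fraction(outcomes)
        report["populations"][pop] = entry
    return report


def fixture_frame(
    funnel: CascadeFunnel, outcomes: CarrierOutcomes | None = None
) -> pd.DataFrame:
    """Serialise a funnel (and optional outcomes) back to the fixture schema."""
    rows = []
    pop = funnel.population
    for step in FUNNEL_ORDER:
        n = funnel.get(step)
        if n is not None:
            rows.append((pop, "funnel", step, n))
    if funnel.carriers_expected is not None:
        rows.append((pop, "funnel", "carriers_expected", funnel.carriers_expected))
    if outcomes is not None:
        for group, n in outcomes.affected.items():
            rows.append((pop, "affected", group, n))
        for (site, stage), n in outcomes.stages.items():
            rows.append((pop, "stage", f"{site}:{stage}", n))
        for surg, groups in outcomes.surgery.items():
            for group, tally in groups.items():
                rows.append((pop, f"{surg}_elected", group, tally.elected))
                rows.append((pop, f"{surg}_eligible", group, tally.eligible))
    return pd.DataFrame(rows, columns=["population", "record", "stratum", "count"])
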