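"""Deterministic cohort model: entry, yearly recursion, reductions, chi-square."""

import numpy as np
import pytest
from scipy import stats

from hbocsim import (
    AgeDistribution,
    CohortModel,
    HazardSchedule,
    InterventionScenario,
    MAX_AGE,
    ValidationError,
    calibrate_hazard,
    compare_chisq,
    cumulative_from_hazard,
    default_schedules,
    initialize_at_risk,
    percent_reduction,
    run_scenario,
    step_year,
)
from hbocsim.cohort import ARMS, SITES


def constant_schedules(h, from_age=35):
    """All four (gene, site) schedules with constant hazard h from from_age."""
    hz = np.zeros(MAX_AGE + 1)
    hz[from_age:] = h
    return {
        (g, s): HazardSchedule(gene=g, site=s, hazard=hz.copy())
        for g in ("BRCA1", "BRCA2")
        for s in ("breast", "ovarian")
    }


def curves_of(schedules):
    return {k: cumulative_from_hazard(s) for k, s in schedules.items()}


class TestInitialize:
    def test_zero_carrier_frequency_gives_empty_cohort(self, schedules, curves):
        dist = AgeDistribution.truncated_normal(10_000)
        state = initialize_at_risk(dist, curves, {"BRCA1": 0.0, "BRCA2": 0.0})
        assert state.at_risk.sum() == 0.0
        assert state.pending.sum() == 0.0

    def test_prevalence_free_entry_at_35(self, curves):
        sched = constant_schedules(0.01)
        dist = AgeDistribution.single_age(35, 100_000)
        state = initialize_at_risk(dist, curves_of(sched), {"BRCA1": 0.00126, "BRCA2": 0.0})
        # F(35) = 0 under these schedules: 126 at-risk carriers for both sites
        for si in range(len(SITES)):
            assert state.at_risk[:, si].sum() == pytest.approx(126.0)

    def test_prevalence_subtraction_at_entry(self):
        sched = {
            (g, s): calibrate_hazard([(50, 0.20)], gene=g, site=s, start_age=25)
            for g in ("BRCA1", "BRCA2")
            for s in ("breast", "ovarian")
        }
        dist = AgeDistribution.single_age(50, 100_000)
        state = initialize_at_risk(dist, curves_of(sched), {"BRCA1": 0.001, "BRCA2": 0.0})
        # carriers = 100, F(50) = 0.20 -> 80 at risk per site
        assert state.at_risk[0, 0].sum() == pytest.approx(100.0 * 0.80, abs=1e-9)

    def test_missing_curve_is_configuration_error(self, curves):
        from hbocsim import ConfigurationError

        partial = {k: v for k, v in curves.items() if k != ("BRCA2", "ovarian")}
        with pytest.raises(ConfigurationError):
            initialize_at_risk(AgeDistribution.single_age(40, 100), partial)


class TestStepYear:
    def test_zero_hazard_changes_nothing_but_age(self, curves):
        sched = constant_schedules(0.0)
        dist = AgeDistribution.single_age(40, 1000)
        state = initialize_at_risk(dist, curves_of(sched), {"BRCA1": 0.1, "BRCA2": 0.0})
        before = state.at_risk.copy()
        state, inc = step_year(state, sched, InterventionScenario.baseline())
        assert inc.sum() == 0.0
        assert np.array_equal(state.at_risk, before)
        assert state.t == 1

    def test_incident_and_reset_arithmetic(self):
        sched = constant_schedules(0.01)
        dist = AgeDistribution.single_age(35, 100_000)  # F(35)=0: 100 at risk
        state = initialize_at_risk(
            dist, curves_of(sched), {"BRCA1": 0.001, "BRCA2": 0.0}
        )
        state, inc = step_year(state, sched, InterventionScenario.baseline())
        # at_risk=100, hazard=0.01 -> incident 1.0, pool resets to 99.0
        assert inc[SITES.index("breast")].sum() == pytest.approx(1.0)
        assert state.at_risk[0, 0].sum() == pytest.approx(99.0)

    def test_mastectomy_arm_counts_scaled_cases(self):
        sched = constant_schedules(0.02)
        dist = AgeDistribution.single_age(35, 100_000)  # F(35)=0: 100 at risk
        scenario = InterventionScenario(detection_rate=1.0, mastectomy_uptake=1.0)
        state = initialize_at_risk(
            dist, curves_of(sched), {"BRCA1": 0.001, "BRCA2": 0.0},
            scenario.arm_fractions(),
        )
        state, inc = step_year(state, sched, scenario)
        # per at-risk woman: 0.02 x 0.05 = 0.001 counted breast cases
        assert inc[SITES.index("breast")].sum() == pytest.approx(100.0 * 0.001)
        # ovarian cases are not protected by mastectomy
        assert inc[SITES.index("ovarian")].sum() == pytest.approx(100.0 * 0.02)


class TestRunScenario:
    def test_zero_detection_equals_baseline(self, synthetic_model):
        base = synthetic_model.baseline(30)
        null = synthetic_model.run(
            InterventionScenario(detection_rate=0.0, mastectomy_uptake=0.9,
                                 oophorectomy_uptake=0.9, horizon_years=30)
        )
        assert np.allclose(
            base.incidents.sum(axis=2), null.incidents.sum(axis=2), atol=1e-9
        )

    @pytest.mark.parametrize(
        "kwargs,site,expected",
        [
            (dict(oophorectomy_uptake=1.0), "ovarian", 95.0),
            (dict(mastectomy_uptake=1.0), "breast", 95.0),
            (dict(oophorectomy_uptake=1.0), "breast", 50.0),
        ],
    )
    def test_full_uptake_limits_single_age_cohort(self, schedules, kwargs, site, expected):
        dist = AgeDistribution.single_age(35, 100_000)
        model = CohortModel(dist, schedules)
        base = model.baseline(50)
        traj = model.run(
            InterventionScenario(detection_rate=1.0, horizon_years=50, **kwargs)
        )
        assert percent_reduction(base, traj, site) == pytest.approx(expected, abs=1e-6)

    def test_conservation_every_year(self, schedules, curves):
        scenario = InterventionScenario(
            detection_rate=0.5, mastectomy_uptake=0.3, oophorectomy_uptake=0.6,
            horizon_years=40,
        )
        dist = AgeDistribution.truncated_normal(50_000)
        state = initialize_at_risk(
            dist, curves, arm_fractions=scenario.arm_fractions()
        )
        for _ in range(scenario.horizon_years):
            state, _ = step_year(state, schedules, scenario)
            assert state.conservation_gap() < 1e-8

    def test_at_risk_counts_never_increase(self, schedules, curves):
        dist = AgeDistribution.single_age(40, 10_000)
        state = initialize_at_risk(dist, curves)
        prev = state.at_risk.copy()
        for _ in range(20):
            state, _ = step_year(state, schedules, InterventionScenario.baseline())
            assert np.all(state.at_risk <= prev + 1e-12)
            prev = state.at_risk.copy()

    def test_young_women_age_into_window(self, schedules, curves):
        # a 30-year-old stratum contributes nothing for 5 years, then enters
        dist = AgeDistribution.single_age(30, 100_000)
        traj = run_scenario(
            dist, InterventionScenario.baseline(10), schedules, {"BRCA1": 0.001, "BRCA2": 0.0}
        )
        breast = traj.per_year("breast")
        assert np.all(breast[:5] == 0.0)
        assert np.all(breast[5:] > 0.0)
        # at window entry, prevalence at 35 was subtracted
        F35 = cumulative_from_hazard(schedules[("BRCA1", "breast")]).F[35]
        assert traj.entry_pool["breast"] == pytest.approx(100.0 * (1 - F35))

    def test_closed_form_cumulative_single_age(self):
        h = 0.02
        sched = constant_schedules(h)
        dist = AgeDistribution.single_age(35, 1.0)
        traj = run_scenario(
            dist, InterventionScenario.baseline(30), sched, {"BRCA1": 1.0, "BRCA2": 0.0}
        )
        for t in (1, 10, 30):
            assert traj.cumulative("breast", t) == pytest.approx(
                1.0 - (1.0 - h) ** t, abs=1e-9
            )


class TestPercentReduction:
    def test_identical_trajectories_zero(self, synthetic_model):
        base = synthetic_model.baseline(30)
        assert percent_reduction(base, base, "breast") == 0.0

    def test_zero_baseline_returns_zero(self):
        sched = constant_schedules(0.0)
        dist = AgeDistribution.single_age(40, 1000)
        traj = run_scenario(dist, InterventionScenario.baseline(10), sched)
        assert percent_reduction(traj, traj, "ovarian") == 0.0

    def test_mismatched_horizons_rejected(self, synthetic_model):
        with pytest.raises(ValidationError):
            percent_reduction(
                synthetic_model.baseline(30), synthetic_model.baseline(40), "breast"
            )

    def test_insured_scenario_beats_underserved(self, synthetic_model):
        base = synthetic_model.baseline(30)
        under = synthetic_model.run(
            InterventionScenario(name="underserved", detection_rate=0.235,
                                 mastectomy_uptake=0.25, oophorectomy_uptake=0.40)
        )
        insured = synthetic_model.run(
            InterventionScenario(name="insured", detection_rate=0.766,
                                 mastectomy_uptake=0.405, oophorectomy_uptake=0.71)
        )
        for site in SITES:
            assert percent_reduction(base, insured, site) > percent_reduction(
                base, under, site
            )

    def test_reduction_monotone_in_detection(self, synthetic_model):
        base = synthetic_model.baseline(30)
        prev = -1.0
        for d in (0.0, 0.25, 0.5, 0.75, 1.0):
            traj = synthetic_model.run(
                InterventionScenario(detection_rate=d, mastectomy_uptake=0.4,
                                     oophorectomy_uptake=0.5)
            )
            red = percent_reduction(base, traj, "breast")
            assert red >= prev
            prev = red

    def test_reductions_bounded_by_95(self, synthetic_model):
        base = synthetic_model.baseline(30)
        traj = synthetic_model.run(
            InterventionScenario(detection_rate=1.0, mastectomy_uptake=1.0,
                                 oophorectomy_uptake=1.0)
        )
        assert percent_reduction(base, traj, "breast") <= 95.0 + 1e-9
        assert percent_reduction(base, traj, "ovarian") <= 95.0 + 1e-9


class TestChisq:
    def test_identical_arms_give_null_result(self, synthetic_model):
        base = synthetic_model.baseline(30)
        res = compare_chisq(base, base, "breast")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_by_two_matches_scipy(self):
        """Cross-check the Pearson formula against scipy's contingency test."""
        from hbocsim.cohort import ChisqResult  # noqa: F401 (documented type)

        table = np.array([[50, 950], [25, 975]], dtype=float)
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        stat = ((table - expected) ** 2 / expected).sum()
        ref_stat, ref_p, _, _ = stats.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref_stat)
        assert stats.chi2.sf(stat, 1) == pytest.approx(ref_p)

    def test_model_chisq_agrees_with_scipy(self, synthetic_model):
        base = synthetic_model.baseline(30)
        traj = synthetic_model.run(
            InterventionScenario(detection_rate=0.766, mastectomy_uptake=0.405,
                                 oophorectomy_uptake=0.71)
        )
        res = compare_chisq(base, traj, "ovarian")
        ref_stat, ref_p, _, _ = stats.chi2_contingency(res.table, correction=False)
        assert res.statistic == pytest.approx(ref_stat)
        assert res.p_value == pytest.approx(ref_p)
        assert not res.low_expected

    def test_degenerate_all_zero_cancers_flagged(self):
        sched = constant_schedules(0.0)
        dist = AgeDistribution.single_age(40, 1000)
        traj = run_scenario(dist, InterventionScenario.baseline(10), sched)
        res = compare_chisq(traj, traj, "breast")
        assert res.low_expected
        assert np.isnan(res.statistic)


class TestScenarioValidation:
    @pytest.mark.parametrize("field,value", [
        ("detection_rate", 1.2),
        ("mastectomy_uptake", -0.1),
        ("eff_mastectomy_breast", 2.0),
        ("horizon_years", 0),
    ])
    def test_out_of_range_parameters_rejected(self, field, value):
        with pytest.raises(ValidationError):
            InterventionScenario(**{field: value})

    def test_arm_fractions_partition_carriers(self):
        sc = InterventionScenario(detection_rate=0.7, mastectomy_uptake=0.4,
                                  oophorectomy_uptake=0.6)
        fracs = sc.arm_fractions()
        assert sum(fracs.values()) == pytest.approx(1.0)
        assert fracs["both"] == pytest.approx(0.7 * 0.4 * 0.6)
        assert set(fracs) == set(ARMS)


class TestAgeDistribution:
    def test_truncated_normal_total_and_bounds(self):
        dist = AgeDistribution.truncated_normal(1000)
        assert dist.total == pytest.approx(1000.0)
        assert dist.counts[:18].sum() == 0.0

    def test_rejects_negative_and_underage_counts(self):
        with pytest.raises(ValidationError):
            AgeDistribution({40: -5})
        with pytest.raises(ValidationError):
            AgeDistribution({10: 5})
        with pytest.raises(ValidationError):
            AgeDistribution({})

    def test_csv_round_trip(self, tmp_path):
        dist = AgeDistribution.truncated_normal(500)
        path = tmp_path / "ages.csv"
        dist.to_frame().to_csv(path, index=False)
        back = AgeDistribution.from_csv(path)
        assert np.allclose(back.counts, dist.counts)
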