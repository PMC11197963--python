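"""Comparisons, internal validation, sensitivity drivers and population
impact."""

import numpy as np
import pytest

import smokesim as sk
from smokesim.engine import SimResult
from smokesim.outcomes import UnknownScenarioError, default_population_weights
from smokesim.params import AgeSexSchedule, ValidationError


def _result(death_age_years, initial_age=45.0):
    spec = sk.CohortSpec(sex="female", initial_age=initial_age,
                         smoking_status="never",
                         n_persons=max(1, len(death_age_years)), seed=0)
    return SimResult(
        death_age_months=np.asarray(death_age_years) * 12,
        cohort_spec=spec, scenario_flags=sk.ScenarioFlags(), seed=0,
        n_persons=len(death_age_years),
    )


class TestLifeExpectancy:
    def test_degenerate_cohort(self):
        le, se = sk.life_expectancy(_result([70.0] * 10))
        assert (le, se) == (70.0, 0.0)

    def test_hand_mean_and_se(self):
        le, se = sk.life_expectancy(_result([60.0, 70.0]))
        assert le == pytest.approx(65.0)
        assert se == pytest.approx(5.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            sk.life_expectancy(_result([]))


class TestSurvivalCurve:
    def test_shape_and_integral(self, base_bundle, base_rates):
        spec = sk.CohortSpec(sex="male", initial_age=45.0,
                             smoking_status="current", n_persons=5000, seed=4)
        res = sk.simulate_cohort(spec, sk.ScenarioFlags(), base_bundle,
                                 base_rates)
        curve = sk.survival_curve(res)
        s = curve.survival.to_numpy()
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 0)
        assert s[-1] == 0.0
        # trapezoid integral of S(age) recovers LE - initial age
        integral = np.trapezoid(s, dx=1.0 / 12.0)
        le = sk.life_expectancy(res)[0]
        assert abs(integral - (le - 45.0)) < 1.0 / 12.0


class TestNullEquivalences:
    def test_hr_one_zero_smoking_deltas(self, base_bundle):
        rates = sk.derive_schedule(base_bundle,
                                   hr_override={"female": 1.0, "male": 1.0})
        comp = sk.compare_smoking_arms(base_bundle, rates, "female", 45.0,
                                       n=3000, seed=6)
        assert comp.ly_lost_smoking == 0.0
        assert comp.ly_gained_cessation == 0.0

    def test_hiv_disabled_both_arms_zero_hiv_delta(self, base_bundle,
                                                   base_rates):
        flags = sk.ScenarioFlags(hiv_enabled=False)
        spec = sk.CohortSpec(sex="male", initial_age=45.0,
                             smoking_status="current", n_persons=3000, seed=6)
        a = sk.simulate_cohort(spec, flags, base_bundle, base_rates)
        b = sk.simulate_cohort(spec, flags, base_bundle, base_rates)
        assert np.array_equal(a.death_age_months, b.death_age_months)


class TestCompareSmokingVsHiv:
    def test_smoking_loss_exceeds_hiv_loss(self, base_bundle, base_rates):
        for sex in ("female", "male"):
            comp = sk.compare_smoking_vs_hiv(base_bundle, base_rates, sex,
                                             45.0, n=20000, seed=8)
            assert comp.ly_lost_smoking > comp.ly_lost_hiv > 0

    def test_high_adherence_raises_gain(self, base_bundle, base_rates):
        base = sk.compare_smoking_arms(base_bundle, base_rates, "female",
                                       45.0, n=20000, seed=8)
        high = sk.compare_smoking_arms(
            base_bundle, base_rates, "female", 45.0, n=20000, seed=8,
            flags=sk.ScenarioFlags(high_adherence_full_engagement=True))
        assert high.ly_gained_cessation > base.ly_gained_cessation


class TestValidateInternal:
    def test_degenerate_prevalence_all_never(self, base_bundle):
        never_only = {
            "current": _flat_prev(0.0, "prevalence_current"),
            "former": _flat_prev(0.0, "prevalence_former"),
            "never": _flat_prev(1.0, "prevalence_never"),
        }
        # no smokers implies no smoking-attributable deaths
        bundle = base_bundle.replace(
            prevalence=never_only, pwh_prevalence=None,
            attributable_fraction=_flat_prev(0.0, "attributable_fraction"))
        rates = sk.derive_schedule(bundle)
        res = sk.validate_internal(bundle, rates, "female", 45.0, n=10000,
                                   seed=3)
        assert res["abs_difference"] < 0.6  # pure Monte Carlo noise

    def test_difference_shrinks_with_n(self, base_bundle, base_rates):
        d = {n: sk.validate_internal(base_bundle, base_rates, "female", 45.0,
                                     n=n, seed=3)["abs_difference"]
             for n in (2000, 50000)}
        assert d[50000] < d[2000]


def _flat_prev(value, name):
    from conftest import constant_schedule
    return constant_schedule(value, name)


class TestOneWaySensitivity:
    def test_unknown_scenario_rejected(self, base_bundle):
        with pytest.raises(UnknownScenarioError):
            sk.run_one_way_sensitivity(base_bundle, ["not_a_scenario"], n=10)

    def test_art_naive_requires_bundle(self, base_bundle):
        with pytest.raises(UnknownScenarioError):
            sk.run_one_way_sensitivity(base_bundle, ["art_naive"], n=10)

    def test_gain_decreases_with_quit_delay(self, base_bundle):
        table = sk.run_one_way_sensitivity(
            base_bundle, ["base", "quit_delay_2y", "quit_delay_10y"],
            sexes=("female",), ages=(45.0,), n=20000, seed=10)
        gains = table.set_index("scenario")["ly_gained_cessation"]
        assert gains["base"] > gains["quit_delay_2y"] > gains["quit_delay_10y"]

    def test_hr_override_scenarios_bracket_base(self, base_bundle):
        table = sk.run_one_way_sensitivity(
            base_bundle, ["base", "hr_low", "hr_high"],
            sexes=("male",), ages=(45.0,), n=20000, seed=10)
        gains = table.set_index("scenario")["ly_gained_cessation"]
        assert gains["hr_low"] < gains["base"] < gains["hr_high"]


class TestTwoWayGrid:
    def test_monotone_in_both_axes(self, base_bundle):
        grid = sk.run_two_way_grid(base_bundle, hr_values=(1.0, 2.0, 3.0),
                                   diseng_values=(0.0, 0.02),
                                   sexes=("female",), n=15000, seed=12)
        g = grid.gains["female"]
        assert np.all(np.diff(g, axis=0) >= 0)   # increasing in HR
        assert np.all(np.diff(g, axis=1) <= 0)   # decreasing in disengagement
        assert np.allclose(g[0], 0.0, atol=1e-9)  # HR = 1 row: no effect

    def test_empty_axis_rejected(self, base_bundle):
        with pytest.raises(ValidationError):
            sk.run_two_way_grid(base_bundle, hr_values=(), diseng_values=(0.0,))


class TestPopulationImpact:
    def test_hand_value(self):
        weights = default_population_weights()
        gains = {k: 3.0 for k in weights}
        inputs = sk.PopulationImpactInputs(
            n_smokers_total=620_000, quit_proportion=0.10,
            weights=weights, per_person_gain=gains)
        assert sk.population_impact(inputs) == pytest.approx(186_000.0)

    def test_linear_in_quit_proportion(self):
        weights = default_population_weights()
        gains = {k: 2.0 for k in weights}
        totals = [sk.population_impact(sk.PopulationImpactInputs(
            n_smokers_total=1000, quit_proportion=q, weights=weights,
            per_person_gain=gains)) for q in (0.0, 0.1, 0.2)]
        assert totals[0] == 0.0
        assert totals[2] == pytest.approx(2 * totals[1])

    def test_missing_gain_rejected(self):
        weights = default_population_weights()
        with pytest.raises(ValidationError, match="missing"):
            sk.population_impact(sk.PopulationImpactInputs(
                n_smokers_total=1000, quit_proportion=0.1, weights=weights,
                per_person_gain={}))
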