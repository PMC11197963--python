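"""Microsimulation engine: initialization, rate selection, the monthly
step, reproducibility and common-random-numbers pairing."""

import numpy as np
import pytest

import smokesim as sk
from smokesim.engine import StateError, nonaids_rate_for_person
from smokesim.params import AdherenceDistribution


def _spec(**kw):
    defaults = dict(sex="female", initial_age=45.0, smoking_status="never",
                    n_persons=1000, seed=1)
    defaults.update(kw)
    return sk.CohortSpec(**defaults)


class TestInitializePerson:
    def test_initial_cd4_matches_distribution(self, base_bundle):
        rng = np.random.default_rng(0)
        cd4 = [sk.initialize_person(_spec(n_persons=1), sk.ScenarioFlags(),
                                    base_bundle, rng).cd4 for _ in range(2000)]
        se = 318 / np.sqrt(len(cd4))
        assert abs(np.mean(cd4) - 789) < 3 * se

    def test_base_case_all_start_suppressed_and_engaged(self, base_bundle):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = sk.initialize_person(_spec(n_persons=1), sk.ScenarioFlags(),
                                     base_bundle, rng)
            assert p.suppressed and p.engaged and p.on_art

    def test_art_naive_lowest_stratum_starts_viraemic(self, art_naive_bundle):
        # force everyone into the 0-65% adherence stratum: initial
        # suppression probability there is zero
        bundle = art_naive_bundle.replace(
            adherence=AdherenceDistribution(probabilities=(0.0, 0.0, 0.0, 1.0)))
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = sk.initialize_person(_spec(n_persons=1), sk.ScenarioFlags(art_naive=True),
                                     bundle, rng)
            assert p.adherence_stratum == 3
            assert not p.suppressed
            assert p.on_art  # initiates ART, starts viraemic

    def test_former_cohort_quits_at_model_start(self, base_bundle):
        rng = np.random.default_rng(0)
        p = sk.initialize_person(_spec(smoking_status="former"),
                                 sk.ScenarioFlags(), base_bundle, rng)
        assert p.smoking_status == "former"
        assert p.quit_age_months == 45 * 12
        assert p.months_since_quit == 0


class TestNonAidsRateSelection:
    def test_quit_before_onset_is_never(self, base_rates, base_bundle):
        p = _person(age=50, status="former", quit_age=37, msq=13 * 12)
        rate = nonaids_rate_for_person(p, base_rates, base_bundle.smoking)
        assert rate == pytest.approx(base_rates.m_ns["female"][50])

    def test_within_lag_is_current(self, base_rates, base_bundle):
        p = _person(age=48, status="former", quit_age=45, msq=36)
        rate = nonaids_rate_for_person(p, base_rates, base_bundle.smoking)
        assert rate == pytest.approx(base_rates.m_cs["female"][48])

    def test_post_lag_retains_quit_age_fraction(self, base_rates, base_bundle):
        p = _person(age=55, status="former", quit_age=45, msq=10 * 12)
        rate = nonaids_rate_for_person(p, base_rates, base_bundle.smoking)
        f = base_rates.f_quit["female"][45]
        ns, cs = base_rates.m_ns["female"][55], base_rates.m_cs["female"][55]
        assert 0 < f < 1
        assert rate == pytest.approx(ns + f * (cs - ns))

    def test_current_below_onset_is_never_level(self, base_rates, base_bundle):
        p = _person(age=39, status="current")
        rate = nonaids_rate_for_person(p, base_rates, base_bundle.smoking)
        assert rate == pytest.approx(base_rates.m_ns["female"][39])

    def test_former_without_quit_age_is_an_error(self, base_rates, base_bundle):
        from smokesim.engine import nonaids_annual_rate
        with pytest.raises(StateError):
            nonaids_annual_rate("female", 600, 1, -1, 0, base_rates,
                                base_bundle.smoking)


def _person(age, status, quit_age=None, msq=0, **kw):
    defaults = dict(
        alive=True, age_months=age * 12, sex="female", smoking_status=status,
        quit_age_months=None if quit_age is None else quit_age * 12,
        months_since_quit=msq, cd4=600.0, adherence_stratum=0, on_art=True,
        suppressed=True, engaged=True, months_since_disengagement=0,
    )
    defaults.update(kw)
    return sk.PersonState(**defaults)


# draw vector: [return, disengage, viraemia, resuppress, oi, hiv_death, nonaids]
NOTHING = np.array([0.999, 0.999, 0.999, 0.999, 0.999, 0.999, 0.999])


class TestStepPerson:
    def test_no_return_draw_before_six_months(self, base_bundle, base_rates):
        p = _person(age=50, status="never", on_art=False, suppressed=False,
                    engaged=False, months_since_disengagement=3)
        draws = NOTHING.copy()
        draws[0] = 0.0  # would certainly return if a draw were permitted
        out = sk.step_person(p, base_bundle, base_rates, sk.ScenarioFlags(),
                             draws=draws)
        assert not out.engaged
        assert out.months_since_disengagement == 4

    def test_return_permitted_after_six_months(self, base_bundle, base_rates):
        p = _person(age=50, status="never", on_art=False, suppressed=False,
                    engaged=False, months_since_disengagement=6)
        draws = NOTHING.copy()
        draws[0] = 0.0
        out = sk.step_person(p, base_bundle, base_rates, sk.ScenarioFlags(),
                             draws=draws)
        assert out.engaged and out.on_art and not out.suppressed

    def test_severe_oi_forces_return_that_cycle(self, base_bundle, base_rates):
        p = _person(age=50, status="never", on_art=False, suppressed=False,
                    engaged=False, months_since_disengagement=8)
        draws = NOTHING.copy()
        draws[4] = 0.0  # severe OI occurs
        out = sk.step_person(p, base_bundle, base_rates, sk.ScenarioFlags(),
                             draws=draws)
        assert out.engaged and out.on_art

    def test_all_hazards_zero_only_ages(self, zero_hazard_bundle,
                                        zero_hazard_rates):
        p = _person(age=50, status="current")
        rng = np.random.default_rng(0)
        out = sk.step_person(p, zero_hazard_bundle, zero_hazard_rates,
                             sk.ScenarioFlags(), rng=rng)
        assert out.alive
        assert out.age_months == p.age_months + 1
        assert (out.cd4, out.suppressed, out.engaged) == (p.cd4, True, True)

    def test_dead_person_is_unchanged(self, base_bundle, base_rates):
        p = _person(age=50, status="never", alive=False,
                    death_age_months=50 * 12)
        out = sk.step_person(p, base_bundle, base_rates, sk.ScenarioFlags(),
                             draws=NOTHING)
        assert out == p

    def test_disengagement_stops_art_and_suppression(self, base_bundle,
                                                     base_rates):
        p = _person(age=50, status="never")
        draws = NOTHING.copy()
        draws[1] = 0.0  # disengages
        out = sk.step_person(p, base_bundle, base_rates, sk.ScenarioFlags(),
                             draws=draws)
        assert not out.engaged and not out.on_art and not out.suppressed


class TestSimulateCohort:
    def test_zero_mortality_everyone_reaches_cap(self, zero_hazard_bundle,
                                                 zero_hazard_rates):
        spec = _spec(n_persons=50, initial_age=95.0)
        res = sk.simulate_cohort(spec, sk.ScenarioFlags(), zero_hazard_bundle,
                                 zero_hazard_rates)
        assert np.all(res.death_age_years == 100.0)

    def test_bitwise_reproducibility(self, base_bundle, base_rates):
        spec = _spec(n_persons=2000)
        a = sk.simulate_cohort(spec, sk.ScenarioFlags(), base_bundle, base_rates)
        b = sk.simulate_cohort(spec, sk.ScenarioFlags(), base_bundle, base_rates)
        assert np.array_equal(a.death_age_months, b.death_age_months)

    def test_crn_former_quit_before_onset_equals_never(self, base_bundle,
                                                       base_rates):
        """Quitting before age 40 leaves no excess risk, so under common
        random numbers the former and never cohorts are identical person
        by person."""
        kw = dict(sex="male", initial_age=35.0, n_persons=3000, seed=7)
        former = sk.simulate_cohort(_spec(smoking_status="former", **kw),
                                    sk.ScenarioFlags(), base_bundle, base_rates)
        never = sk.simulate_cohort(_spec(smoking_status="never", **kw),
                                   sk.ScenarioFlags(), base_bundle, base_rates)
        assert np.array_equal(former.death_age_months, never.death_age_months)

    def test_death_ages_within_bounds(self, base_bundle, base_rates):
        spec = _spec(n_persons=2000)
        res = sk.simulate_cohort(spec, sk.ScenarioFlags(), base_bundle, base_rates)
        assert res.death_age_years.min() >= 45.0
        assert res.death_age_years.max() <= 100.0

    def test_smoking_status_stochastic_ordering(self, base_bundle, base_rates):
        les = {}
        for status in ("never", "former", "current"):
            res = sk.simulate_cohort(_spec(smoking_status=status,
                                           n_persons=20000, seed=5),
                                     sk.ScenarioFlags(), base_bundle, base_rates)
            les[status] = sk.life_expectancy(res)[0]
        assert les["never"] >= les["former"] >= les["current"]

    def test_disabling_hiv_never_decreases_le(self, base_bundle, base_rates):
        spec = _spec(smoking_status="current", n_persons=20000, seed=5)
        with_hiv = sk.simulate_cohort(spec, sk.ScenarioFlags(), base_bundle,
                                      base_rates)
        without = sk.simulate_cohort(spec, sk.ScenarioFlags(hiv_enabled=False),
                                     base_bundle, base_rates)
        assert sk.life_expectancy(without)[0] >= sk.life_expectancy(with_hiv)[0]
        # under CRN no person dies earlier without HIV
        assert np.all(without.death_age_months >= with_hiv.death_age_months)

    def test_higher_disengagement_never_increases_le(self, base_bundle,
                                                     base_rates):
        spec = _spec(smoking_status="current", n_persons=20000, seed=5)
        base = sk.simulate_cohort(spec, sk.ScenarioFlags(), base_bundle,
                                  base_rates)
        high = sk.simulate_cohort(
            spec, sk.ScenarioFlags(disengagement_override=0.02), base_bundle,
            base_rates)
        assert sk.life_expectancy(high)[0] <= sk.life_expectancy(base)[0]

    def test_delayed_quit_switches_status_mid_simulation(self, base_bundle,
                                                         base_rates):
        """A former-smoker cohort with a quit delay matches the current
        cohort until the scheduled quit month (CRN), then diverges."""
        kw = dict(sex="female", initial_age=45.0, n_persons=3000, seed=9)
        delayed = sk.simulate_cohort(
            _spec(smoking_status="former", quit_delay_months=120, **kw),
            sk.ScenarioFlags(), base_bundle, base_rates)
        current = sk.simulate_cohort(_spec(smoking_status="current", **kw),
                                     sk.ScenarioFlags(), base_bundle, base_rates)
        cut = 45 * 12 + 120
        before = delayed.death_age_months < cut
        assert np.array_equal(delayed.death_age_months[before],
                              current.death_age_months[before])
        assert sk.life_expectancy(delayed)[0] > sk.life_expectancy(current)[0]
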