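"""Cohort comparisons, validation, sensitivity analyses and population impact.

All comparisons are run under common random numbers: every arm uses the
same seed and cohort size, so arms with identical dynamics produce
identical death ages and deltas between arms are estimated with paired
precision.  Paired standard errors are reported where arms are CRN-paired;
independent arms combine standard errors root-sum-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .derivation import SmokingStratifiedRates, derive_schedule
from .engine import SimResult, simulate_cohort
from .params import (
    SEXES,
    SMOKING_STATUSES,
    CohortSpec,
    ParamBundle,
    PopulationImpactInputs,
    ScenarioFlags,
    ValidationError,
)

#: default cohort size per arm for the analysis drivers
DEFAULT_N = 200_000


class UnknownScenarioError(ValueError):
    """An unsupported sensitivity-scenario label was requested."""


def life_expectancy(result: SimResult) -> tuple[float, float]:
    """Mean age at death and its standard error, in years."""
    ages = result.death_age_years
    if len(ages) == 0:
        raise ValidationError("empty simulation result")
    se = float(ages.std(ddof=1) / np.sqrt(len(ages))) if len(ages) > 1 else 0.0
    return float(ages.mean()), se


def survival_curve(result: SimResult) -> pd.DataFrame:
    """Fraction surviving at each month of age.

    Survival at age ``a`` is the fraction of the cohort whose recorded
    death age (start-of-month convention) is at least ``a``: 1 at the
    initial age, non-increasing, and 0 one month past the last death.
    """
    init = int(round(result.cohort_spec.initial_age * 12))
    deaths = np.sort(result.death_age_months)
    last = int(deaths.max())
    ages = np.arange(init, last + 2)
    # fraction with death_age >= a, via a single sorted pass
    surv = 1.0 - np.searchsorted(deaths, ages, side="left") / len(deaths)
    return pd.DataFrame({"age_months": ages, "survival": surv})


def _paired_se(a: SimResult, b: SimResult) -> float:
    d = a.death_age_years - b.death_age_years
    return float(d.std(ddof=1) / np.sqrt(len(d)))


@dataclass(frozen=True)
class ComparisonResult:
    """Life expectancy by arm plus the headline deltas (years)."""

    le_by_arm: Mapping[str, tuple[float, float]]  # label -> (LE, SE)
    ly_lost_smoking: float                        # LE_NS - LE_CS
    ly_gained_cessation: float                    # LE_FS - LE_CS
    ly_lost_hiv: Optional[float] = None           # LE_CS,noHIV - LE_CS,HIV
    delta_se: Mapping[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"arm": k, "le": v[0], "se": v[1]} for k, v in self.le_by_arm.items()]
        return pd.DataFrame(rows)


def _arm_specs(sex: str, age: float, n: int, seed: int,
               quit_delay_months: int = 0) -> dict[str, CohortSpec]:
    mk = lambda status, delay=0: CohortSpec(
        sex=sex, initial_age=age, smoking_status=status,
        n_persons=n, seed=seed, quit_delay_months=delay,
    )
    return {
        "current": mk("current"),
        "former": mk("former", quit_delay_months),
        "never": mk("never"),
    }


def compare_smoking_arms(params: ParamBundle, rates: SmokingStratifiedRates,
                         sex: str, age: float, n: int = DEFAULT_N,
                         seed: int = 0, quit_delay_months: int = 0,
                         flags: ScenarioFlags = ScenarioFlags()
                         ) -> ComparisonResult:
    """CS/FS/NS arms under CRN; smoking-loss and cessation-gain deltas."""
    specs = _arm_specs(sex, age, n, seed, quit_delay_months)
    results = {k: simulate_cohort(s, flags, params, rates) for k, s in specs.items()}
    le = {k: life_expectancy(r) for k, r in results.items()}
    return ComparisonResult(
        le_by_arm=le,
        ly_lost_smoking=le["never"][0] - le["current"][0],
        ly_gained_cessation=le["former"][0] - le["current"][0],
        delta_se={
            "ly_lost_smoking": _paired_se(results["never"], results["current"]),
            "ly_gained_cessation": _paired_se(results["former"], results["current"]),
        },
    )


def compare_smoking_vs_hiv(params: ParamBundle, rates: SmokingStratifiedRates,
                           sex: str, age: float, n: int = DEFAULT_N,
                           seed: int = 0, high_adherence: bool = False
                           ) -> ComparisonResult:
    """Life-years lost from smoking versus life-years lost from HIV.

    Four CRN-paired arms: CS and NS with HIV, plus CS and NS with HIV
    disabled (identical except that HIV/AIDS mortality risks are removed).
    ``high_adherence`` applies full adherence and engagement to the
    HIV-enabled arms.
    """
    base_flags = ScenarioFlags(high_adherence_full_engagement=high_adherence)
    nohiv_flags = replace(base_flags, hiv_enabled=False)
    specs = _arm_specs(sex, age, n, seed)
    results = {
        "current": simulate_cohort(specs["current"], base_flags, params, rates),
        "former": simulate_cohort(specs["former"], base_flags, params, rates),
        "never": simulate_cohort(specs["never"], base_flags, params, rates),
        "current_nohiv": simulate_cohort(specs["current"], nohiv_flags, params, rates),
        "never_nohiv": simulate_cohort(specs["never"], nohiv_flags, params, rates),
    }
    le = {k: life_expectancy(r) for k, r in results.items()}
    return ComparisonResult(
        le_by_arm=le,
        ly_lost_smoking=le["never"][0] - le["current"][0],
        ly_gained_cessation=le["former"][0] - le["current"][0],
        ly_lost_hiv=le["current_nohiv"][0] - le["current"][0],
        delta_se={
            "ly_lost_smoking": _paired_se(results["never"], results["current"]),
            "ly_gained_cessation": _paired_se(results["former"], results["current"]),
            "ly_lost_hiv": _paired_se(results["current_nohiv"], results["current"]),
        },
    )


def validate_internal(params: ParamBundle, rates: SmokingStratifiedRates,
                      sex: str, initial_age: float, n: int = DEFAULT_N,
                      seed: int = 0) -> dict[str, float]:
    """Internal-validation check: the smoking-prevalence-weighted mean LE of
    separately simulated CS/FS/NS cohorts against the LE of one mixed
    cohort whose status is assigned at initialization by the same
    prevalence.  Returns the weighted LE, mixed LE and absolute difference
    in years."""
    flags = ScenarioFlags()
    prev = params.active_prevalence()
    weights = {s: prev[s].lookup(sex, initial_age) for s in SMOKING_STATUSES}
    le = {}
    for status in SMOKING_STATUSES:
        spec = CohortSpec(sex=sex, initial_age=initial_age,
                          smoking_status=status, n_persons=n, seed=seed)
        le[status] = life_expectancy(simulate_cohort(spec, flags, params, rates))[0]
    weighted = sum(weights[s] * le[s] for s in SMOKING_STATUSES)
    mixed_spec = CohortSpec(sex=sex, initial_age=initial_age,
                            smoking_status="mixed", n_persons=n, seed=seed + 1)
    mixed_le = life_expectancy(simulate_cohort(mixed_spec, flags, params, rates))[0]
    return {
        "weighted_le": weighted,
        "mixed_le": mixed_le,
        "abs_difference": abs(weighted - mixed_le),
        **{f"le_{s}": le[s] for s in SMOKING_STATUSES},
    }


#: sensitivity scenarios supported by :func:`run_one_way_sensitivity`
ONE_WAY_SCENARIOS = (
    "base",
    "quit_delay_2y",
    "quit_delay_5y",
    "quit_delay_10y",
    "hr_low",
    "hr_high",
    "pwh_prevalence",
    "high_adherence",
    "disengagement_high",
    "cd4_low",
    "cd4_high",
    "art_naive",
)

_QUIT_DELAYS = {"quit_delay_2y": 24, "quit_delay_5y": 60, "quit_delay_10y": 120}


def run_one_way_sensitivity(params: ParamBundle,
                            scenarios: Sequence[str],
                            sexes: Sequence[str] = SEXES,
                            ages: Sequence[float] = (45.0,),
                            n: int = DEFAULT_N, seed: int = 0,
                            art_naive_params: Optional[ParamBundle] = None
                            ) -> pd.DataFrame:
    """One comparison row per scenario × sex × age.

    Scenario labels: ``base``; ``quit_delay_{2,5,10}y`` (former smokers quit
    that long after model start); ``hr_low`` / ``hr_high`` (flat
    current-vs-never hazard ratios 1.2 both sexes / 3.0 female, 2.8 male);
    ``pwh_prevalence`` (PWH-specific prevalence in the derivation);
    ``high_adherence``; ``disengagement_high`` (1.6%/month);
    ``cd4_low`` / ``cd4_high`` (initial CD4 mean 200 / 800);
    ``art_naive`` (requires ``art_naive_params``; former smokers quit 2y
    after model start).
    """
    base_rates = derive_schedule(params)
    rows = []
    for scenario in scenarios:
        if scenario not in ONE_WAY_SCENARIOS:
            raise UnknownScenarioError(
                f"unknown scenario {scenario!r}; supported: {ONE_WAY_SCENARIOS}"
            )
        bundle, rates, flags = params, base_rates, ScenarioFlags()
        quit_delay = 0
        if scenario in _QUIT_DELAYS:
            quit_delay = _QUIT_DELAYS[scenario]
        elif scenario == "hr_low":
            rates = derive_schedule(params, hr_override={"female": 1.2, "male": 1.2})
        elif scenario == "hr_high":
            rates = derive_schedule(params, hr_override={"female": 3.0, "male": 2.8})
        elif scenario == "pwh_prevalence":
            rates = derive_schedule(params, prevalence_source="pwh")
        elif scenario == "high_adherence":
            flags = ScenarioFlags(high_adherence_full_engagement=True)
        elif scenario == "disengagement_high":
            flags = ScenarioFlags(disengagement_override=0.016)
        elif scenario == "cd4_low":
            flags = ScenarioFlags(initial_cd4_override=200.0)
        elif scenario == "cd4_high":
            flags = ScenarioFlags(initial_cd4_override=800.0)
        elif scenario == "art_naive":
            if art_naive_params is None:
                raise UnknownScenarioError(
                    "scenario 'art_naive' requires art_naive_params"
                )
            bundle = art_naive_params
            rates = derive_schedule(bundle)
            flags = ScenarioFlags(art_naive=True)
            quit_delay = 24
        for sex in sexes:
            for age in ages:
                comp = compare_smoking_arms(
                    bundle, rates, sex, age, n=n, seed=seed,
                    quit_delay_months=quit_delay, flags=flags,
                )
                rows.append({
                    "scenario": scenario, "sex": sex, "age": age,
                    "le_current": comp.le_by_arm["current"][0],
                    "le_former": comp.le_by_arm["former"][0],
                    "le_never": comp.le_by_arm["never"][0],
                    "ly_lost_smoking": comp.ly_lost_smoking,
                    "ly_gained_cessation": comp.ly_gained_cessation,
                    "se_gain": comp.delta_se["ly_gained_cessation"],
                })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SensitivityGrid:
    """Two-way grid of cessation gains over hazard ratio × disengagement."""

    hr_values: tuple[float, ...]
    diseng_values: tuple[float, ...]
    gains: Mapping[str, np.ndarray]  # sex -> array [hr, diseng]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex, grid in self.gains.items():
            for i, hr in enumerate(self.hr_values):
                for j, d in enumerate(self.diseng_values):
                    rows.append({"sex": sex, "hr_cs": hr,
                                 "monthly_disengagement": d,
                                 "ly_gained_cessation": grid[i, j]})
        return pd.DataFrame(rows)


#: default grid axes: flat hazard ratios and monthly disengagement probs
DEFAULT_HR_VALUES = (1.0, 1.5, 2.0, 2.5, 3.0)
DEFAULT_DISENG_VALUES = (0.0, 0.007, 0.016, 0.02)


def run_two_way_grid(params: ParamBundle,
                     hr_values: Sequence[float] = DEFAULT_HR_VALUES,
                     diseng_values: Sequence[float] = DEFAULT_DISENG_VALUES,
                     sexes: Sequence[str] = SEXES, age: float = 45.0,
                     n: int = DEFAULT_N, seed: int = 0) -> SensitivityGrid:
    """Cessation gains over a grid of flat current-vs-never hazard ratios
    (applied uniformly to all ages above the onset age) and monthly
    disengagement probabilities."""
    if not hr_values or not diseng_values:
        raise ValidationError("hr_values and diseng_values must be non-empty")
    gains = {sex: np.zeros((len(hr_values), len(diseng_values))) for sex in sexes}
    for i, hr in enumerate(hr_values):
        if hr > 1.0:
            rates = derive_schedule(params, hr_override={"female": hr, "male": hr})
        else:
            # HR 1 means smoking has no mortality effect at any age
            rates = derive_schedule(params, hr_override={"female": 1.0, "male": 1.0})
        for j, d in enumerate(diseng_values):
            flags = ScenarioFlags(disengagement_override=d)
            for sex in sexes:
                comp = compare_smoking_arms(params, rates, sex, age, n=n,
                                            seed=seed, flags=flags)
                gains[sex][i, j] = comp.ly_gained_cessation
    return SensitivityGrid(
        hr_values=tuple(hr_values), diseng_values=tuple(diseng_values),
        gains=gains,
    )


def population_impact(inputs: PopulationImpactInputs) -> float:
    """Total life-years gained if ``quit_proportion`` of the smoking
    population quit now: ``quit × Σ N_stratum × gain_stratum``."""
    total = 0.0
    for key, w in inputs.weights.items():
        if w == 0:
            continue
        if key not in inputs.per_person_gain:
            raise ValidationError(f"missing per-person gain for stratum {key}")
        total += inputs.n_smokers_total * w * inputs.per_person_gain[key]
    return inputs.quit_proportion * total


#: decade labels and the representative model entry age for each
POPULATION_DECADES = {"30-39": 35.0, "40-49": 45.0, "50-59": 55.0}


def default_population_weights(female_share: float = 0.08 / (0.08 + 0.37)
                               ) -> dict[tuple[str, str], float]:
    """Equal weights across age decades within sex, sexes scaled by the
    overall smoking-prevalence anchors (8% female / 37% male)."""
    weights = {}
    for sex, share in (("female", female_share), ("male", 1.0 - female_share)):
        for decade in POPULATION_DECADES:
            weights[(sex, decade)] = share / len(POPULATION_DECADES)
    return weights


def population_impact_from_model(params: ParamBundle,
                                 rates: SmokingStratifiedRates,
                                 quit_proportion: float,
                                 n_smokers_total: float = 620_000.0,
                                 weights: Optional[Mapping] = None,
                                 n: int = DEFAULT_N, seed: int = 0) -> float:
    """Population-level life-years gained, simulating the per-person
    cessation gain at each (sex, decade) stratum's representative age."""
    weights = dict(weights) if weights is not None else default_population_weights()
    gains = {}
    for (sex, decade), w in weights.items():
        if w == 0:
            continue
        age = POPULATION_DECADES[decade]
        comp = compare_smoking_arms(params, rates, sex, age, n=n, seed=seed)
        gains[(sex, decade)] = comp.ly_gained_cessation
    inputs = PopulationImpactInputs(
        n_smokers_total=n_smokers_total, quit_proportion=quit_proportion,
        weights=weights, per_person_gain=gains,
    )
    return population_impact(inputs)
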