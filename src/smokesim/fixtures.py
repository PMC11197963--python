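"""Synthetic parameter fixtures.

National calibration inputs behind the published analysis — life-table
mortality schedules, survey smoking prevalence by age and sex, GBD
smoking-attributable fractions, quit-age-stratified excess-risk retention,
and the CD4-stratified HIV event tables — are not printed in a reusable
form.  This module generates parameter bundles with the same statistical
structure so that every stage of the pipeline is testable without any
download:

* Gompertz-like age-increasing non-AIDS mortality (``a · exp(b · age)``);
* age- and sex-varying smoking prevalence around the national anchors
  (8% of females, 37% of males currently smoke);
* attributable fractions that are zero below age 40, rise with age and
  plateau, calibrated so the derived current-vs-never hazard ratios fall
  inside the published ranges (1.2−2.3 females, 1.1−1.9 males);
* quit-age-dependent excess-risk retention fractions in [0, 1], zero for
  cessation before age 40;
* CD4-stratified HIV mortality and severe-OI probabilities decreasing in
  CD4.  These HIV event tables, the CD4 dynamics and the resuppression
  probabilities are plausible synthetic defaults, NOT published values.

The base-case fixture embeds the published cohort parameters verbatim
(initial CD4 789/318 female and 600/303 male; adherence distribution
77.1/17.2/3.2/2.4%; monthly viraemia 0.2/0.3/18.0% by adherence;
disengagement 0.7%/month; return to care 1.3%/month), and the ART-naïve
fixture its published column (CD4 432/206 and 314/160; adherence
51.3/35.8/7.9/5.1%; initial suppression 96.4/85.1/0%; disengagement
1.6%/month during months 1−12).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .derivation import derive_schedule
from .params import (
    SEXES,
    AdherenceDistribution,
    AgeSexSchedule,
    HIVCareParams,
    ParamBundle,
    QuitAgeRetentionSchedule,
    SmokingParams,
    ValidationError,
    save_params,
)


class FixtureCalibrationError(ValidationError):
    """A generated fixture's derived hazard ratios fall outside the
    published ranges it is meant to respect."""


#: 5-year age bands covering [0, 100)
AGE_BANDS_5Y: tuple[tuple[float, float], ...] = tuple(
    (float(a), float(a + 5)) for a in range(0, 100, 5)
)

#: published current-vs-never hazard-ratio ranges the base case must respect
HR_CS_RANGE = {"female": (1.2, 2.3), "male": (1.1, 1.9)}

# synthetic HIV event tables (by CD4 stratum, worst to best) — not published
HIV_DEATH_MONTHLY = (0.01, 0.004, 0.0012, 0.0006, 0.0003)
SEVERE_OI_MONTHLY = (0.03, 0.012, 0.004, 0.0015, 0.0008)
RESUPPRESSION_MONTHLY = (0.5, 0.35)


def gompertz_schedule(a: float, b: float, sex: str,
                      age_bands: Sequence[tuple[float, float]] = AGE_BANDS_5Y,
                      name: str = "mortality") -> AgeSexSchedule:
    """Piecewise-constant Gompertz hazard ``a · exp(b · age_mid)`` per band."""
    if a <= 0 or b < 0:
        raise ValidationError("gompertz requires a > 0 and b >= 0")
    cap = int(max(hi for _, hi in age_bands))
    entries = tuple(
        (sex, lo, hi, a * math.exp(b * (lo + hi) / 2.0)) for lo, hi in age_bands
    )
    return AgeSexSchedule(entries=entries, age_cap=cap, name=name)


def _step_profile(profile: Sequence[tuple[float, float]], age: float) -> float:
    """Evaluate a coarse (age_lo, value) step profile at an age."""
    value = profile[0][1]
    for lo, v in profile:
        if age >= lo:
            value = v
    return value


def _schedule_from_profiles(profiles: Mapping[str, Sequence[tuple[float, float]]],
                            name: str,
                            age_bands: Sequence[tuple[float, float]] = AGE_BANDS_5Y
                            ) -> AgeSexSchedule:
    cap = int(max(hi for _, hi in age_bands))
    entries = []
    for sex, profile in profiles.items():
        for lo, hi in age_bands:
            entries.append((sex, lo, hi, _step_profile(profile, (lo + hi) / 2.0)))
    return AgeSexSchedule(entries=tuple(entries), age_cap=cap, name=name)


@dataclass(frozen=True)
class FixtureSpec:
    """Calibration constants for the synthetic base case.

    Gompertz level ``a`` (annual rate at age 0) and log-slope ``b`` per sex
    set the overall non-AIDS mortality level; the attributable-fraction,
    prevalence and retention profiles are coarse step functions of age
    evaluated on the 5-year band grid.
    """

    gompertz_a: Mapping[str, float] = field(
        default_factory=lambda: {"female": 8.3e-5, "male": 1.39e-4})
    gompertz_b: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.095, "male": 0.095})
    af_profile: Mapping[str, tuple] = field(default_factory=lambda: {
        "female": ((0, 0.0), (40, 0.045), (45, 0.06), (50, 0.075), (55, 0.085),
                   (60, 0.09), (70, 0.085), (75, 0.07), (80, 0.06), (85, 0.05),
                   (90, 0.045), (95, 0.04)),
        "male": ((0, 0.0), (40, 0.13), (45, 0.17), (50, 0.21), (55, 0.24),
                 (60, 0.25), (65, 0.23), (70, 0.21), (75, 0.18), (80, 0.15),
                 (85, 0.13), (90, 0.11), (95, 0.10)),
    })
    prev_current_profile: Mapping[str, tuple] = field(default_factory=lambda: {
        "female": ((0, 0.0), (15, 0.05), (25, 0.08), (35, 0.09), (55, 0.08),
                   (65, 0.06), (75, 0.04)),
        "male": ((0, 0.0), (15, 0.25), (25, 0.35), (35, 0.40), (55, 0.35),
                 (65, 0.28), (75, 0.20)),
    })
    prev_former_profile: Mapping[str, tuple] = field(default_factory=lambda: {
        "female": ((0, 0.0), (15, 0.01), (25, 0.02), (35, 0.03), (45, 0.04),
                   (55, 0.05), (65, 0.06)),
        "male": ((0, 0.0), (15, 0.02), (25, 0.05), (35, 0.08), (45, 0.10),
                 (55, 0.13), (65, 0.15), (75, 0.16)),
    })
    retention_profile: Mapping[str, tuple] = field(default_factory=lambda: {
        "female": ((0, 0.0), (40, 0.15), (45, 0.25), (50, 0.32), (55, 0.40),
                   (60, 0.45)),
        "male": ((0, 0.0), (40, 0.12), (45, 0.20), (50, 0.28), (55, 0.35),
                 (60, 0.40)),
    })
    #: multiplier on current/former prevalence for the PWH-specific scenario
    pwh_prevalence_factor: float = 1.3


def _prevalence_schedules(spec: FixtureSpec, factor: float = 1.0
                          ) -> dict[str, AgeSexSchedule]:
    current = _schedule_from_profiles(
        {s: tuple((lo, min(0.95, v * factor)) for lo, v in spec.prev_current_profile[s])
         for s in SEXES}, "prevalence_current")
    former = _schedule_from_profiles(
        {s: tuple((lo, min(0.95, v * factor)) for lo, v in spec.prev_former_profile[s])
         for s in SEXES}, "prevalence_former")
    never_entries = []
    for sex in SEXES:
        for lo, hi in AGE_BANDS_5Y:
            p_ns = 1.0 - current.lookup(sex, lo) - former.lookup(sex, lo)
            if p_ns < 0:
                raise ValidationError(
                    f"prevalence exceeds 1 in band [{lo}, {hi}) sex={sex}"
                )
            never_entries.append((sex, lo, hi, p_ns))
    never = AgeSexSchedule(entries=tuple(never_entries), age_cap=100,
                           name="prevalence_never")
    return {"current": current, "former": former, "never": never}


def _check_hr_calibration(bundle: ParamBundle) -> None:
    rates = derive_schedule(bundle)
    onset = bundle.smoking.onset_age
    for sex in SEXES:
        lo, hi = HR_CS_RANGE[sex]
        hr = rates.hr_cs(sex)[onset:]
        if hr.min() < lo - 1e-9 or hr.max() > hi + 1e-9:
            raise FixtureCalibrationError(
                f"derived HR_CS for {sex} spans [{hr.min():.3f}, {hr.max():.3f}], "
                f"outside the published range [{lo}, {hi}]"
            )


def make_base_case_fixture(seed: int = 0,
                           spec: Optional[FixtureSpec] = None) -> ParamBundle:
    """The base-case parameter bundle: published cohort parameters verbatim,
    synthetic schedules calibrated to the published hazard-ratio ranges.

    Deterministic: the same seed yields an identical bundle (the base case
    uses no random draws; the seed is kept for interface symmetry with the
    random fixture).
    """
    spec = spec or FixtureSpec()
    mortality_entries = []
    for sex in SEXES:
        sched = gompertz_schedule(spec.gompertz_a[sex], spec.gompertz_b[sex], sex)
        mortality_entries.extend(sched.entries)
    mortality = AgeSexSchedule(entries=tuple(mortality_entries), age_cap=100,
                               name="mortality")
    af = _schedule_from_profiles(spec.af_profile, "attributable_fraction")
    prevalence = _prevalence_schedules(spec)
    pwh_prevalence = _prevalence_schedules(spec, factor=spec.pwh_prevalence_factor)
    retention_entries = []
    for sex in SEXES:
        prof = spec.retention_profile[sex]
        edges = [lo for lo, _ in prof] + [100.0]
        for (lo, f), hi in zip(prof, edges[1:]):
            retention_entries.append((sex, lo, hi, f))
    retention = QuitAgeRetentionSchedule(entries=tuple(retention_entries),
                                         age_cap=100)

    hiv = HIVCareParams(
        initial_cd4_mean={"female": 789.0, "male": 600.0},
        initial_cd4_sd={"female": 318.0, "male": 303.0},
        initial_suppression_prob=(1.0, 1.0, 1.0, 1.0),
        # viraemia strata ≥95 / 31−94 / ≤30 mapped onto the adherence
        # strata: the lumped 0−65 stratum gets the ≤30 probability
        monthly_viraemia_prob=(0.002, 0.003, 0.003, 0.18),
        monthly_resuppression_prob=RESUPPRESSION_MONTHLY,
        monthly_disengagement_prob=(0.007, 0.007),
        hiv_death_monthly_prob=HIV_DEATH_MONTHLY,
        severe_oi_monthly_prob=SEVERE_OI_MONTHLY,
        monthly_return_prob=0.013,
        min_months_before_return=6,
    )
    adherence = AdherenceDistribution(probabilities=(0.771, 0.172, 0.032, 0.024))

    bundle = ParamBundle(
        mortality=mortality,
        attributable_fraction=af,
        prevalence=prevalence,
        pwh_prevalence=pwh_prevalence,
        retention=retention,
        adherence=adherence,
        hiv=hiv,
        smoking=SmokingParams(),
        age_cap=100,
    )
    _check_hr_calibration(bundle)
    return bundle


def make_art_naive_fixture(seed: int = 0,
                           spec: Optional[FixtureSpec] = None) -> ParamBundle:
    """Base case overridden with the published ART-naïve column: lower
    initial CD4, poorer adherence, stratified initial suppression, and
    higher first-year disengagement."""
    base = make_base_case_fixture(seed=seed, spec=spec)
    hiv = HIVCareParams(
        initial_cd4_mean={"female": 432.0, "male": 314.0},
        initial_cd4_sd={"female": 206.0, "male": 160.0},
        initial_suppression_prob=(0.964, 0.851, 0.851, 0.0),
        monthly_viraemia_prob=base.hiv.monthly_viraemia_prob,
        monthly_resuppression_prob=base.hiv.monthly_resuppression_prob,
        monthly_disengagement_prob=(0.016, 0.007),
        hiv_death_monthly_prob=base.hiv.hiv_death_monthly_prob,
        severe_oi_monthly_prob=base.hiv.severe_oi_monthly_prob,
        monthly_return_prob=base.hiv.monthly_return_prob,
        min_months_before_return=base.hiv.min_months_before_return,
    )
    adherence = AdherenceDistribution(probabilities=(0.513, 0.358, 0.079, 0.051))
    return base.replace(hiv=hiv, adherence=adherence)


def make_random_fixture(seed: int) -> ParamBundle:
    """A randomised bundle with the base case's structure, for property
    tests: Gompertz level/slope, attributable-fraction plateaus, prevalence
    anchors and retention ramps are jittered within realistic ranges."""
    rng = np.random.default_rng(seed)
    base = FixtureSpec()

    def jitter_profile(profile, scale_lo, scale_hi, cap=0.9):
        scale = rng.uniform(scale_lo, scale_hi)
        return tuple((lo, min(cap, v * scale)) for lo, v in profile)

    spec = FixtureSpec(
        gompertz_a={s: base.gompertz_a[s] * rng.uniform(0.6, 1.6) for s in SEXES},
        gompertz_b={s: rng.uniform(0.08, 0.11) for s in SEXES},
        af_profile={s: jitter_profile(base.af_profile[s], 0.6, 1.2, cap=0.6)
                    for s in SEXES},
        prev_current_profile={
            s: jitter_profile(base.prev_current_profile[s], 0.7, 1.3)
            for s in SEXES},
        prev_former_profile={
            s: jitter_profile(base.prev_former_profile[s], 0.7, 1.3)
            for s in SEXES},
        retention_profile={
            s: jitter_profile(base.retention_profile[s], 0.5, 1.5, cap=1.0)
            for s in SEXES},
    )
    mortality_entries = []
    for sex in SEXES:
        sched = gompertz_schedule(spec.gompertz_a[sex], spec.gompertz_b[sex], sex)
        mortality_entries.extend(sched.entries)
    mortality = AgeSexSchedule(entries=tuple(mortality_entries), age_cap=100,
                               name="mortality")
    af = _schedule_from_profiles(spec.af_profile, "attributable_fraction")
    prevalence = _prevalence_schedules(spec)
    retention_entries = []
    for sex in SEXES:
        prof = spec.retention_profile[sex]
        edges = [lo for lo, _ in prof] + [100.0]
        for (lo, f), hi in zip(prof, edges[1:]):
            retention_entries.append((sex, lo, hi, f))
    retention = QuitAgeRetentionSchedule(entries=tuple(retention_entries),
                                         age_cap=100)
    base_bundle = make_base_case_fixture()
    return ParamBundle(
        mortality=mortality,
        attributable_fraction=af,
        prevalence=prevalence,
        retention=retention,
        adherence=base_bundle.adherence,
        hiv=base_bundle.hiv,
        smoking=SmokingParams(),
        age_cap=100,
    )


def write_fixture(kind: str, out_dir, seed: int = 0) -> Path:
    """Write a fixture bundle (``base`` / ``art-naive`` / ``random``) as a
    config + CSV schedules; returns the config path."""
    makers = {
        "base": make_base_case_fixture,
        "art-naive": make_art_naive_fixture,
        "random": make_random_fixture,
    }
    if kind not in makers:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(makers)}")
    bundle = makers[kind](seed)
    return save_params(bundle, out_dir)
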