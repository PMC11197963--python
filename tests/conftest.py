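import numpy as np
import pytest

import smokesim as sk
from smokesim.params import AgeSexSchedule, HIVCareParams


@pytest.fixture(scope="session")
def base_bundle():
    return sk.make_base_case_fixture()


@pytest.fixture(scope="session")
def base_rates(base_bundle):
    return sk.derive_schedule(base_bundle)


@pytest.fixture(scope="session")
def art_naive_bundle():
    return sk.make_art_naive_fixture()


def constant_schedule(value: float, name: str = "schedule") -> AgeSexSchedule:
    # 5-year bands to stay band-compatible with the fixture schedules
    entries = tuple(
        (sex, float(lo), float(lo + 5), value)
        for sex in ("female", "male") for lo in range(0, 100, 5)
    )
    return AgeSexSchedule(entries=entries, age_cap=100, name=name)


@pytest.fixture(scope="session")
def zero_hazard_bundle(base_bundle):
    """Every hazard zero: nothing can happen except ageing."""
    hiv = HIVCareParams(
        initial_cd4_mean={"female": 600.0, "male": 600.0},
        initial_cd4_sd={"female": 0.0, "male": 0.0},
        initial_suppression_prob=(1.0, 1.0, 1.0, 1.0),
        monthly_viraemia_prob=(0.0, 0.0, 0.0, 0.0),
        monthly_resuppression_prob=(0.0, 0.0),
        monthly_disengagement_prob=(0.0, 0.0),
        hiv_death_monthly_prob=(0.0,) * 5,
        severe_oi_monthly_prob=(0.0,) * 5,
        monthly_return_prob=0.0,
        cd4_gain_per_month_suppressed=0.0,
        cd4_decline_per_month_unsuppressed=0.0,
    )
    return base_bundle.replace(
        mortality=constant_schedule(0.0, "mortality"),
        attributable_fraction=constant_schedule(0.0, "attributable_fraction"),
        hiv=hiv,
    )


@pytest.fixture(scope="session")
def zero_hazard_rates(zero_hazard_bundle):
    return sk.derive_schedule(zero_hazard_bundle)


def constant_mortality_bundle(base_bundle, monthly_q: float):
    """Bundle whose non-AIDS mortality gives a constant monthly death
    probability ``monthly_q`` at every age, with no smoking effect."""
    annual_rate = sk.monthly_prob_to_rate(monthly_q)
    return base_bundle.replace(
        mortality=constant_schedule(annual_rate, "mortality"),
        attributable_fraction=constant_schedule(0.0, "attributable_fraction"),
    )
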