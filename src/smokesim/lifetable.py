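"""Deterministic monthly life-table expectation.

For scenarios without HIV event dynamics (HIV disabled) a person's death
time is an inhomogeneous geometric random variable with monthly death
probability ``q_t`` determined only by sex, age and the smoking-state
rules.  The expected age at death then has a closed form, which serves as
a brute-force oracle for the Monte Carlo engine: both components build
``q_t`` from the same rate-selection function, so the smoking onset, lag
and quit-age logic cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .derivation import SmokingStratifiedRates
from .engine import _STATUS_CODE, CURRENT, FORMER, nonaids_annual_rate, simulate_cohort
from .params import CohortSpec, ParamBundle, ScenarioFlags, ValidationError


class UnsupportedScenarioError(ValidationError):
    """The life-table oracle only covers HIV-disabled scenarios."""


@dataclass(frozen=True)
class MortalityPath:
    """Monthly death probabilities from an initial age to the age cap.

    ``q[t]`` is the probability of dying in month ``t`` (0-based months on
    model) given survival to its start; the path ends at the age cap, where
    any survivor mass is recorded as dying at the cap.
    """

    q: np.ndarray
    initial_age_months: int
    cap_months: int

    def __post_init__(self):
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValidationError("monthly death probabilities must lie in [0, 1]")


def build_mortality_path(spec: CohortSpec, params: ParamBundle,
                         rates: SmokingStratifiedRates) -> MortalityPath:
    """Monthly non-AIDS death probabilities for a homogeneous cohort,
    reproducing the engine's smoking-state trajectory (scheduled quit,
    post-cessation lag, quit-age retention) deterministically."""
    if spec.smoking_status == "mixed":
        raise UnsupportedScenarioError("mixed cohorts have no single mortality path")
    init = int(round(spec.initial_age * 12))
    cap = params.age_cap * 12
    T = cap - init
    t = np.arange(T)
    age_months = init + t

    code = _STATUS_CODE[spec.smoking_status]
    status = np.full(T, code, dtype=np.int8)
    quit_age = np.full(T, -1, dtype=np.int64)
    msq = np.zeros(T, dtype=np.int64)
    if code == FORMER:
        delay = spec.quit_delay_months
        # smokes until `delay` months on model, then quits
        status[t < delay] = CURRENT
        quit_month = init + delay
        quit_age[t >= delay] = quit_month
        msq[t >= delay] = t[t >= delay] - delay

    rate = nonaids_annual_rate(spec.sex, age_months, status, quit_age, msq,
                               rates, params.smoking)
    q = -np.expm1(-np.asarray(rate) / 12.0)
    return MortalityPath(q=q, initial_age_months=init, cap_months=cap)


def expected_age_at_death(path: MortalityPath) -> float:
    """Closed-form expected age at death (years), start-of-month convention.

    ``E = Σ_t age_t · q_t · Π_{u<t}(1 − q_u) + S_T · age_cap`` where the
    final term records survivors at the cap.
    """
    q = path.q
    surv_before = np.concatenate([[1.0], np.cumprod(1.0 - q)])
    die_at = q * surv_before[:-1]
    ages_years = (path.initial_age_months + np.arange(len(q))) / 12.0
    return float(np.sum(die_at * ages_years) + surv_before[-1] * path.cap_months / 12.0)


def oracle_vs_engine(spec: CohortSpec, flags: ScenarioFlags,
                     params: ParamBundle, rates: SmokingStratifiedRates
                     ) -> tuple[float, float, float]:
    """Compare the deterministic expectation with a Monte Carlo run.

    Returns ``(oracle_le, mc_le, mc_se)``.  Only valid when HIV dynamics
    are disabled (the oracle does not model the care cascade).
    """
    if flags.hiv_enabled:
        raise UnsupportedScenarioError(
            "the life-table oracle requires hiv_enabled=False"
        )
    oracle_le = expected_age_at_death(build_mortality_path(spec, params, rates))
    result = simulate_cohort(spec, flags, params, rates)
    ages = result.death_age_years
    mc_le = float(ages.mean())
    mc_se = float(ages.std(ddof=1) / np.sqrt(len(ages))) if len(ages) > 1 else 0.0
    return oracle_le, mc_le, mc_se
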