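"""Monthly-cycle individual-level simulation of HIV care and mortality.

Each simulated person carries an HIV care state (CD4 count, ART adherence
stratum, engagement in care, virologic suppression, regimen line) and a
smoking state (never/former/current, age at cessation).  Every month, in a
fixed documented order, the person faces:

1. a return-to-care draw if disengaged for at least the minimum wait;
2. a disengagement draw if engaged (stops ART, ends suppression);
3. a viraemia draw while suppressed and, while viraemic, a resuppression
   draw (with a switch to the second regimen line after a sustained
   failure window);
4. a CD4 update (gain toward a ceiling while suppressed, decline otherwise);
5. a severe-OI draw by CD4 stratum (an OI while out of care forces a
   return to care that cycle);
6. an HIV-death draw by CD4 stratum (skipped when HIV is disabled);
7. a non-AIDS-death draw whose annual rate depends on sex, age and smoking
   state (no effect below the onset age; former smokers keep
   current-smoker mortality during the post-cessation lag);
8. ageing and counter updates, including any scheduled mid-simulation quit.

Mortality draws come last within the month so they see the month's updated
CD4 count.  Death age is recorded with the start-of-month convention (the
age the person had entering the cycle in which they died); survivors at the
age cap are recorded as dying at the cap.

The engine is vectorised over persons.  Each month it consumes one fixed
block of uniform draws per person — the same block shape regardless of
scenario flags or vital status — so two cohorts simulated with the same
seed and size are driven by identical random numbers, person by person.
This gives exact common-random-numbers (CRN) pairing across scenario arms:
arms whose dynamics coincide produce identical death ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .derivation import SmokingStratifiedRates
from .params import (
    CD4_STRATUM_EDGES,
    SEXES,
    CohortSpec,
    ParamBundle,
    ScenarioFlags,
    SmokingParams,
    ValidationError,
)

# smoking status codes used in the state arrays
NEVER, FORMER, CURRENT = 0, 1, 2
_STATUS_CODE = {"never": NEVER, "former": FORMER, "current": CURRENT}
_STATUS_NAME = {v: k for k, v in _STATUS_CODE.items()}

# fixed order of the per-month uniform draw block (CRN alignment)
_N_DRAWS = 7
(D_RETURN, D_DISENGAGE, D_VIRAEMIA, D_RESUPPRESS,
 D_OI, D_HIV_DEATH, D_NONAIDS_DEATH) = range(_N_DRAWS)


class StateError(ValueError):
    """A person state is internally inconsistent."""


@dataclass
class PersonState:
    """One simulated individual (scalar view of the cohort state arrays)."""

    alive: bool
    age_months: int
    sex: str
    smoking_status: str
    quit_age_months: Optional[int]
    months_since_quit: int
    cd4: float
    adherence_stratum: int
    on_art: bool
    suppressed: bool
    engaged: bool
    months_since_disengagement: int
    regimen_line: int = 1
    months_viraemic: int = 0
    months_in_model: int = 0
    scheduled_quit_month: Optional[int] = None
    death_age_months: Optional[int] = None

    def __post_init__(self):
        if self.suppressed and not self.on_art:
            raise StateError("suppressed requires on_art")
        if self.on_art and not self.engaged:
            raise StateError("on_art requires engaged")
        if self.cd4 < 0:
            raise StateError("cd4 must be >= 0")
        if self.smoking_status == "former" and self.quit_age_months is None:
            raise StateError("former smoker requires quit_age_months")


@dataclass(frozen=True)
class SimResult:
    """Per-person death ages for one cohort."""

    death_age_months: np.ndarray
    cohort_spec: CohortSpec
    scenario_flags: ScenarioFlags
    seed: int
    n_persons: int
    statuses: Optional[np.ndarray] = None  # per-person status codes (mixed cohorts)

    @property
    def death_age_years(self) -> np.ndarray:
        return self.death_age_months / 12.0


# ---------------------------------------------------------------------------
# smoking rate selection (single source of truth, shared with the oracle)
# ---------------------------------------------------------------------------

def nonaids_annual_rate(sex: str, age_months, status, quit_age_months,
                        months_since_quit, rates: SmokingStratifiedRates,
                        smoking: SmokingParams):
    """Annual non-AIDS mortality rate(s) given smoking state.

    Vectorised over the state arguments.  The selection rules: never smokers
    and anyone below the onset age get the never-smoker rate (the derivation
    forces current = never below onset); current smokers get the
    current-smoker rate; former smokers who quit before the onset age get
    the never-smoker rate; former smokers within the post-cessation lag get
    the current-smoker rate; thereafter they retain the quit-age-dependent
    fraction of the current-vs-never excess.
    """
    age_months = np.asarray(age_months)
    status = np.asarray(status)
    quit_age_months = np.asarray(quit_age_months)
    months_since_quit = np.asarray(months_since_quit)
    scalar = age_months.ndim == 0
    age_months, status, quit_age_months, months_since_quit = np.atleast_1d(
        age_months, status, quit_age_months, months_since_quit
    )
    if np.any((status == FORMER) & (quit_age_months < 0)):
        raise StateError("former smoker with missing quit age")

    age_yr = np.minimum(age_months // 12, rates.age_cap - 1).astype(np.int64)
    m_ns = rates.m_ns[sex][age_yr]
    m_cs = rates.m_cs[sex][age_yr]

    mult = np.zeros(age_yr.shape, dtype=float)          # never: no excess
    mult[status == CURRENT] = 1.0
    former = status == FORMER
    if former.any():
        quit_yr = np.clip(quit_age_months // 12, 0, rates.age_cap - 1).astype(np.int64)
        onset_months = smoking.onset_age * 12
        quit_before_onset = quit_age_months < onset_months
        in_lag = months_since_quit < smoking.cessation_lag_months
        f = rates.f_quit[sex][quit_yr]
        m = np.where(quit_before_onset, 0.0, np.where(in_lag, 1.0, f))
        mult[former] = m[former]

    rate = m_ns + mult * (m_cs - m_ns)
    return float(rate[0]) if scalar else rate


def nonaids_rate_for_person(state: PersonState, rates: SmokingStratifiedRates,
                            smoking: SmokingParams) -> float:
    """Annual non-AIDS mortality rate for one person (scalar wrapper)."""
    quit = -1 if state.quit_age_months is None else state.quit_age_months
    return nonaids_annual_rate(
        state.sex, state.age_months, _STATUS_CODE[state.smoking_status],
        quit, state.months_since_quit, rates, smoking,
    )


# ---------------------------------------------------------------------------
# cohort state (struct of arrays)
# ---------------------------------------------------------------------------

@dataclass
class _CohortState:
    sex: str
    alive: np.ndarray
    age_months: np.ndarray
    status: np.ndarray
    quit_age_months: np.ndarray       # -1 when not applicable
    months_since_quit: np.ndarray
    cd4: np.ndarray
    adh: np.ndarray                   # adherence stratum index 0..3
    on_art: np.ndarray
    suppressed: np.ndarray
    engaged: np.ndarray
    months_since_diseng: np.ndarray
    regimen_line: np.ndarray
    months_viraemic: np.ndarray
    months_in_model: np.ndarray
    death_age_months: np.ndarray      # -1 while alive
    scheduled_quit_month: int = -1    # cohort-level delayed quit (-1: none)


def _init_cohort(spec: CohortSpec, flags: ScenarioFlags, params: ParamBundle,
                 rng: np.random.Generator) -> _CohortState:
    """Initialise the cohort state arrays.

    Draw order is fixed — mixed-status assignment (when applicable), CD4,
    adherence stratum, initial suppression — so that cohorts differing only
    in smoking status consume identical draws (CRN pairing).
    """
    n = spec.n_persons
    init_age_months = int(round(spec.initial_age * 12))

    if spec.smoking_status == "mixed":
        prev = params.active_prevalence()
        p = np.array([
            prev["never"].lookup(spec.sex, spec.initial_age),
            prev["former"].lookup(spec.sex, spec.initial_age),
            prev["current"].lookup(spec.sex, spec.initial_age),
        ])
        u = rng.random(n)
        status = np.searchsorted(np.cumsum(p), u, side="right").astype(np.int8)
        status = np.minimum(status, 2)
    else:
        status = np.full(n, _STATUS_CODE[spec.smoking_status], dtype=np.int8)

    hiv = params.hiv
    mean = (flags.initial_cd4_override
            if flags.initial_cd4_override is not None
            else hiv.initial_cd4_mean[spec.sex])
    sd = hiv.initial_cd4_sd[spec.sex]
    cd4 = np.maximum(0.0, rng.normal(mean, sd, n))

    adh_p = params.adherence.normalized()
    adh = np.searchsorted(np.cumsum(adh_p), rng.random(n), side="right").astype(np.int8)
    adh = np.minimum(adh, len(adh_p) - 1)
    if flags.high_adherence_full_engagement:
        adh[:] = 0

    supp_p = np.asarray(hiv.initial_suppression_prob)[adh]
    suppressed = rng.random(n) < supp_p

    scheduled = -1
    quit_age = np.full(n, -1, dtype=np.int64)
    msq = np.zeros(n, dtype=np.int64)
    former = status == FORMER
    if spec.quit_delay_months > 0:
        # smoke until the scheduled month, then quit
        scheduled = spec.quit_delay_months
        status = np.where(former, CURRENT, status).astype(np.int8)
    else:
        quit_age[former] = init_age_months

    return _CohortState(
        sex=spec.sex,
        alive=np.ones(n, dtype=bool),
        age_months=np.full(n, init_age_months, dtype=np.int64),
        status=status,
        quit_age_months=quit_age,
        months_since_quit=msq,
        cd4=cd4,
        adh=adh,
        on_art=np.ones(n, dtype=bool),
        suppressed=suppressed,
        engaged=np.ones(n, dtype=bool),
        months_since_diseng=np.zeros(n, dtype=np.int64),
        regimen_line=np.ones(n, dtype=np.int8),
        months_viraemic=np.zeros(n, dtype=np.int16),
        months_in_model=np.zeros(n, dtype=np.int64),
        death_age_months=np.full(n, -1, dtype=np.int64),
        scheduled_quit_month=scheduled,
    )


def initialize_person(spec: CohortSpec, flags: ScenarioFlags,
                      params: ParamBundle,
                      rng: np.random.Generator) -> PersonState:
    """Initialise a single person (scalar wrapper over the cohort init)."""
    c = _init_cohort(replace(spec, n_persons=1), flags, params, rng)
    return _person_from_cohort(c, 0)


def _person_from_cohort(c: _CohortState, i: int) -> PersonState:
    return PersonState(
        alive=bool(c.alive[i]),
        age_months=int(c.age_months[i]),
        sex=c.sex,
        smoking_status=_STATUS_NAME[int(c.status[i])],
        quit_age_months=(None if c.quit_age_months[i] < 0 else int(c.quit_age_months[i])),
        months_since_quit=int(c.months_since_quit[i]),
        cd4=float(c.cd4[i]),
        adherence_stratum=int(c.adh[i]),
        on_art=bool(c.on_art[i]),
        suppressed=bool(c.suppressed[i]),
        engaged=bool(c.engaged[i]),
        months_since_disengagement=int(c.months_since_diseng[i]),
        regimen_line=int(c.regimen_line[i]),
        months_viraemic=int(c.months_viraemic[i]),
        months_in_model=int(c.months_in_model[i]),
        scheduled_quit_month=(None if c.scheduled_quit_month < 0
                              else int(c.scheduled_quit_month)),
        death_age_months=(None if c.death_age_months[i] < 0
                          else int(c.death_age_months[i])),
    )


def _cohort_from_person(state: PersonState) -> _CohortState:
    quit = -1 if state.quit_age_months is None else state.quit_age_months
    return _CohortState(
        sex=state.sex,
        alive=np.array([state.alive]),
        age_months=np.array([state.age_months], dtype=np.int64),
        status=np.array([_STATUS_CODE[state.smoking_status]], dtype=np.int8),
        quit_age_months=np.array([quit], dtype=np.int64),
        months_since_quit=np.array([state.months_since_quit], dtype=np.int64),
        cd4=np.array([state.cd4], dtype=float),
        adh=np.array([state.adherence_stratum], dtype=np.int8),
        on_art=np.array([state.on_art]),
        suppressed=np.array([state.suppressed]),
        engaged=np.array([state.engaged]),
        months_since_diseng=np.array([state.months_since_disengagement], dtype=np.int64),
        regimen_line=np.array([state.regimen_line], dtype=np.int8),
        months_viraemic=np.array([state.months_viraemic], dtype=np.int16),
        months_in_model=np.array([state.months_in_model], dtype=np.int64),
        death_age_months=np.array(
            [-1 if state.death_age_months is None else state.death_age_months],
            dtype=np.int64,
        ),
        scheduled_quit_month=(-1 if state.scheduled_quit_month is None
                              else state.scheduled_quit_month),
    )


# ---------------------------------------------------------------------------
# the monthly step
# ---------------------------------------------------------------------------

def _step(c: _CohortState, params: ParamBundle, rates: SmokingStratifiedRates,
          flags: ScenarioFlags, draws: np.ndarray, cap_months: int) -> None:
    """Advance the whole cohort one month in place.  ``draws`` is the
    (n, 7) uniform block for this month."""
    hiv = params.hiv
    a = c.alive

    # (1) return to care: background draw after the minimum wait,
    #     plus a forced return upon a severe OI (step 5)
    p_return = hiv.monthly_return_prob
    can_return = a & ~c.engaged & (c.months_since_diseng >= hiv.min_months_before_return)
    returns = can_return & (draws[:, D_RETURN] < p_return)
    c.engaged[returns] = True
    c.on_art[returns] = True          # resumes ART, initially viraemic
    c.months_viraemic[returns] = 0

    # (2) disengagement (stops ART, ends suppression)
    if flags.high_adherence_full_engagement:
        p_dis = np.zeros(2)
    elif flags.disengagement_override is not None:
        p_dis = np.full(2, flags.disengagement_override)
    else:
        p_dis = np.asarray(hiv.monthly_disengagement_prob)
    band = (c.months_in_model >= 12).astype(np.int8)
    diseng = a & c.engaged & (draws[:, D_DISENGAGE] < p_dis[band])
    c.engaged[diseng] = False
    c.on_art[diseng] = False
    c.suppressed[diseng] = False
    c.months_since_diseng[diseng] = 0

    # (3) viraemia while suppressed; resuppression while viraemic on ART
    #     (persons newly viraemic this month cannot resuppress this month)
    vir_candidates = a & c.on_art & c.suppressed
    resupp_candidates = a & c.on_art & ~c.suppressed
    p_vir = np.asarray(hiv.monthly_viraemia_prob)[c.adh]
    new_vir = vir_candidates & (draws[:, D_VIRAEMIA] < p_vir)
    c.suppressed[new_vir] = False
    c.months_viraemic[new_vir] = 0
    p_resupp = np.asarray(hiv.monthly_resuppression_prob)[c.regimen_line - 1]
    resupp = resupp_candidates & (draws[:, D_RESUPPRESS] < p_resupp)
    c.suppressed[resupp] = True
    c.months_viraemic[resupp] = 0
    still_vir = resupp_candidates & ~resupp
    c.months_viraemic[still_vir] += 1
    switch = still_vir & (c.regimen_line == 1) & \
        (c.months_viraemic >= hiv.line_switch_months)
    c.regimen_line[switch] = 2
    c.months_viraemic[switch] = 0

    # (4) CD4 update
    up = a & c.suppressed
    down = a & ~c.suppressed
    c.cd4[up] = np.minimum(c.cd4[up] + hiv.cd4_gain_per_month_suppressed,
                           hiv.cd4_ceiling)
    c.cd4[down] = np.maximum(c.cd4[down] - hiv.cd4_decline_per_month_unsuppressed,
                             0.0)

    if flags.hiv_enabled:
        stratum = np.searchsorted(CD4_STRATUM_EDGES, c.cd4, side="right")
        # (5) severe OI; an OI while out of care forces a return this cycle
        p_oi = np.asarray(hiv.severe_oi_monthly_prob)[stratum]
        oi = a & (draws[:, D_OI] < p_oi)
        forced = oi & ~c.engaged
        c.engaged[forced] = True
        c.on_art[forced] = True
        c.months_viraemic[forced] = 0
        # (6) HIV death
        p_hd = np.asarray(hiv.hiv_death_monthly_prob)[stratum]
        hiv_death = a & (draws[:, D_HIV_DEATH] < p_hd)
        c.death_age_months[hiv_death] = c.age_months[hiv_death]
        c.alive[hiv_death] = False
        a = c.alive

    # (7) non-AIDS death
    rate = nonaids_annual_rate(c.sex, c.age_months, c.status,
                               c.quit_age_months, c.months_since_quit,
                               rates, params.smoking)
    q = -np.expm1(-np.asarray(rate) / 12.0)
    na_death = a & (draws[:, D_NONAIDS_DEATH] < q)
    c.death_age_months[na_death] = c.age_months[na_death]
    c.alive[na_death] = False
    a = c.alive

    # (8) ageing and counters; scheduled mid-simulation quit; age cap
    c.age_months[a] += 1
    c.months_in_model[a] += 1
    c.months_since_quit[a & (c.status == FORMER)] += 1
    c.months_since_diseng[a & ~c.engaged] += 1
    if c.scheduled_quit_month >= 0:
        quits = a & (c.status == CURRENT) & \
            (c.months_in_model == c.scheduled_quit_month)
        c.status[quits] = FORMER
        c.quit_age_months[quits] = c.age_months[quits]
        c.months_since_quit[quits] = 0
    capped = a & (c.age_months >= cap_months)
    c.death_age_months[capped] = cap_months
    c.alive[capped] = False


def step_person(state: PersonState, params: ParamBundle,
                rates: SmokingStratifiedRates, flags: ScenarioFlags,
                rng: Optional[np.random.Generator] = None,
                draws: Optional[np.ndarray] = None) -> PersonState:
    """Advance a single person one month.  A dead input is returned
    unchanged.  ``draws`` (length 7, in the documented event order) may be
    supplied instead of ``rng`` to force specific event outcomes in tests."""
    if not state.alive:
        return replace(state)
    if draws is None:
        if rng is None:
            raise ValueError("supply rng or draws")
        draws = rng.random(_N_DRAWS)
    c = _cohort_from_person(state)
    _step(c, params, rates, flags, np.asarray(draws, dtype=float).reshape(1, -1),
          cap_months=params.age_cap * 12)
    return _person_from_cohort(c, 0)


def simulate_cohort(spec: CohortSpec, flags: ScenarioFlags,
                    params: ParamBundle,
                    rates: SmokingStratifiedRates) -> SimResult:
    """Run every person in the cohort to death or the age cap.

    Deterministic for a fixed ``spec.seed``; the same seed and cohort size
    yield CRN-paired draws across scenario arms.
    """
    rng = np.random.default_rng(spec.seed)
    c = _init_cohort(spec, flags, params, rng)
    cap_months = params.age_cap * 12
    n = spec.n_persons
    max_cycles = cap_months - int(round(spec.initial_age * 12))
    for _ in range(max_cycles):
        if not c.alive.any():
            break
        draws = rng.random((n, _N_DRAWS))
        _step(c, params, rates, flags, draws, cap_months)
    # anyone still alive has reached the cap inside _step; guard anyway
    c.death_age_months[c.alive] = cap_months
    c.alive[:] = False
    return SimResult(
        death_age_months=c.death_age_months.copy(),
        cohort_spec=spec,
        scenario_flags=flags,
        seed=spec.seed,
        n_persons=n,
        statuses=c.status.copy() if spec.smoking_status == "mixed" else None,
    )
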