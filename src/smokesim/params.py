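"""Parameter model: domain types, validation, and schedule/config I/O.

Every quantity the simulation uses enters through this module: age/sex
schedules of annual non-AIDS mortality rates, smoking prevalence and
smoking-attributable fractions; the quit-age-keyed excess-risk retention
schedule; the ART adherence distribution; HIV care-cascade parameters; and
the cohort / scenario descriptors.

Conventions
-----------
* Age bands are half-open ``[age_lo, age_hi)`` in years; individual age is
  tracked in integer months and band lookup uses ``floor(age_months / 12)``.
* Mortality inputs are annual per-person hazard rates; they are converted to
  monthly probabilities once per cycle via ``1 - exp(-rate / 12)``.
* The simulation horizon is capped at ``age_cap`` (100 years by default);
  survivors are recorded as dying at the cap.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

SEXES = ("female", "male")
SMOKING_STATUSES = ("current", "former", "never")

#: ART adherence strata, highest to lowest percent adherence.
ADHERENCE_STRATA = ("95-100", "80-94", "66-79", "0-65")

#: CD4 stratum upper edges (cells/µl); strata are <50, 50-200, 200-350,
#: 350-500, >500, ordered worst to best.
CD4_STRATUM_EDGES = (50.0, 200.0, 350.0, 500.0)

DEFAULT_AGE_CAP = 100


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


class SchemaError(ValueError):
    """A schedule or config file is structurally invalid (coverage gaps,
    band mismatches, missing columns)."""


# ---------------------------------------------------------------------------
# rate / probability conversion
# ---------------------------------------------------------------------------

def rate_to_monthly_prob(annual_rate):
    """Convert an annual hazard rate to a monthly death probability.

    Uses the exponential-survival identity ``1 - exp(-rate / 12)``.
    Accepts scalars or arrays; rates must be non-negative.
    """
    r = np.asarray(annual_rate, dtype=float)
    if np.any(r < 0):
        raise ValidationError("annual_rate must be >= 0")
    out = -np.expm1(-r / 12.0)
    return float(out) if np.isscalar(annual_rate) or out.ndim == 0 else out


def monthly_prob_to_rate(monthly_prob):
    """Inverse of :func:`rate_to_monthly_prob`: ``-12 * log(1 - p)``."""
    p = np.asarray(monthly_prob, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValidationError("monthly probability must be in [0, 1)")
    out = -12.0 * np.log1p(-p)
    return float(out) if np.isscalar(monthly_prob) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def _check_band_coverage(bands: Sequence[tuple[float, float]], sex: str,
                         age_cap: float, what: str) -> None:
    """Bands must be non-overlapping and cover [0, age_cap) exactly."""
    ordered = sorted(bands)
    cursor = 0.0
    for lo, hi in ordered:
        if hi <= lo:
            raise SchemaError(f"{what}: empty band [{lo}, {hi}) for sex={sex}")
        if lo > cursor:
            raise SchemaError(
                f"{what}: coverage gap at ages {cursor:g}-{lo:g} for sex={sex}"
            )
        if lo < cursor:
            raise SchemaError(
                f"{what}: overlapping bands at age {lo:g} for sex={sex}"
            )
        cursor = hi
    if cursor < age_cap:
        raise SchemaError(
            f"{what}: coverage gap at ages {cursor:g}-{age_cap:g} for sex={sex}"
        )


@dataclass(frozen=True)
class AgeSexSchedule:
    """Piecewise-constant value over half-open age bands, by sex.

    ``entries`` is a list of ``(sex, age_lo, age_hi, value)``.  Bands per sex
    must be non-overlapping and cover ``[0, age_cap)``.
    """

    entries: tuple[tuple[str, float, float, float], ...]
    age_cap: int = DEFAULT_AGE_CAP
    name: str = "schedule"

    def __post_init__(self):
        if not self.entries:
            raise SchemaError(f"{self.name}: no entries")
        by_sex: dict[str, list[tuple[float, float]]] = {}
        for sex, lo, hi, value in self.entries:
            if sex not in SEXES:
                raise SchemaError(f"{self.name}: unknown sex {sex!r}")
            if not math.isfinite(value):
                raise ValidationError(
                    f"{self.name}: non-finite value in band [{lo}, {hi}) sex={sex}"
                )
            by_sex.setdefault(sex, []).append((lo, hi))
        # coverage is checked per sex present; a bundle requires both sexes,
        # which is enforced where the schedule is consumed
        for sex, bands in by_sex.items():
            _check_band_coverage(bands, sex, self.age_cap, self.name)

    def bands(self, sex: str) -> list[tuple[float, float]]:
        return sorted((lo, hi) for s, lo, hi, _ in self.entries if s == sex)

    def lookup(self, sex: str, age_years: float) -> float:
        if not (0 <= age_years < self.age_cap):
            raise KeyError(f"{self.name}: age {age_years} outside [0, {self.age_cap})")
        for s, lo, hi, value in self.entries:
            if s == sex and lo <= age_years < hi:
                return value
        raise KeyError(f"{self.name}: no band for sex={sex}, age={age_years}")

    def values_by_year(self, sex: str) -> np.ndarray:
        """Value per integer age year ``0 .. age_cap-1`` (fast lookup table)."""
        out = np.empty(self.age_cap, dtype=float)
        out.fill(np.nan)
        for s, lo, hi, value in self.entries:
            if s == sex:
                out[int(math.ceil(lo)):int(math.ceil(hi))] = value
        if np.isnan(out).any():
            raise SchemaError(f"{self.name}: incomplete coverage for sex={sex}")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.entries), columns=["sex", "age_lo", "age_hi", "value"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, age_cap: int = DEFAULT_AGE_CAP,
                   name: str = "schedule") -> "AgeSexSchedule":
        required = {"sex", "age_lo", "age_hi", "value"}
        if not required.issubset(df.columns):
            raise SchemaError(f"{name}: missing columns {sorted(required - set(df.columns))}")
        entries = tuple(
            (str(r.sex), float(r.age_lo), float(r.age_hi), float(r.value))
            for r in df.itertuples()
        )
        return cls(entries=entries, age_cap=age_cap, name=name)

    @classmethod
    def from_csv(cls, path, age_cap: int = DEFAULT_AGE_CAP,
                 name: Optional[str] = None) -> "AgeSexSchedule":
        return cls.from_frame(pd.read_csv(path), age_cap=age_cap,
                              name=name or Path(path).stem)


@dataclass(frozen=True)
class QuitAgeRetentionSchedule:
    """Fraction ``f`` of the current-vs-never excess mortality risk retained
    by a former smoker, keyed by sex and age at cessation.

    ``f = 0`` is required for any band lying entirely below age 40: quitting
    before 40 leaves no excess risk.
    """

    entries: tuple[tuple[str, float, float, float], ...]  # sex, lo, hi, f
    age_cap: int = DEFAULT_AGE_CAP
    name: str = "retention"

    def __post_init__(self):
        if not self.entries:
            raise SchemaError(f"{self.name}: no entries")
        by_sex: dict[str, list[tuple[float, float]]] = {}
        for sex, lo, hi, f in self.entries:
            if sex not in SEXES:
                raise SchemaError(f"{self.name}: unknown sex {sex!r}")
            if not (0.0 <= f <= 1.0):
                raise ValidationError(
                    f"{self.name}: f={f} outside [0, 1] in quit-age band [{lo}, {hi}) sex={sex}"
                )
            if hi <= 40.0 and f != 0.0:
                raise ValidationError(
                    f"{self.name}: f must be 0 for quit ages below 40 "
                    f"(band [{lo}, {hi}) sex={sex} has f={f})"
                )
            by_sex.setdefault(sex, []).append((lo, hi))
        for sex, bands in by_sex.items():
            _check_band_coverage(bands, sex, self.age_cap, self.name)

    def lookup(self, sex: str, quit_age_years: float) -> float:
        for s, lo, hi, f in self.entries:
            if s == sex and lo <= quit_age_years < hi:
                return f
        raise KeyError(f"{self.name}: no band for sex={sex}, quit_age={quit_age_years}")

    def values_by_year(self, sex: str) -> np.ndarray:
        out = np.empty(self.age_cap, dtype=float)
        out.fill(np.nan)
        for s, lo, hi, f in self.entries:
            if s == sex:
                out[int(math.ceil(lo)):int(math.ceil(hi))] = f
        if np.isnan(out).any():
            raise SchemaError(f"{self.name}: incomplete coverage for sex={sex}")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.entries),
            columns=["sex", "quit_age_lo", "quit_age_hi", "f"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, age_cap: int = DEFAULT_AGE_CAP) -> "QuitAgeRetentionSchedule":
        df = pd.read_csv(path)
        required = {"sex", "quit_age_lo", "quit_age_hi", "f"}
        if not required.issubset(df.columns):
            raise SchemaError(f"retention: missing columns {sorted(required - set(df.columns))}")
        entries = tuple(
            (str(r.sex), float(r.quit_age_lo), float(r.quit_age_hi), float(r.f))
            for r in df.itertuples()
        )
        return cls(entries=entries, age_cap=age_cap, name=Path(path).stem)


# ---------------------------------------------------------------------------
# distributions and care parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdherenceDistribution:
    """Proportion of the cohort in each ART adherence stratum.

    Published proportions are rounded to one decimal percent and may sum to
    99.9 or 100.1; sums within ``tol`` of 1 are accepted and renormalised.
    """

    probabilities: tuple[float, float, float, float]
    tol: float = 5e-3

    def __post_init__(self):
        p = self.probabilities
        if len(p) != len(ADHERENCE_STRATA):
            raise ValidationError(
                f"adherence: expected {len(ADHERENCE_STRATA)} strata, got {len(p)}"
            )
        if any(x < 0 for x in p):
            raise ValidationError(f"adherence: negative probability in {p}")
        if abs(sum(p) - 1.0) > self.tol:
            raise ValidationError(
                f"adherence: probabilities sum to {sum(p):.6f}, not 1"
            )

    def normalized(self) -> np.ndarray:
        p = np.asarray(self.probabilities, dtype=float)
        return p / p.sum()

    def as_dict(self) -> dict[str, float]:
        return dict(zip(ADHERENCE_STRATA, self.probabilities))


def _check_probs(name: str, values: Iterable[float], errors: list[str]) -> None:
    for i, v in enumerate(values):
        if not (0.0 <= v <= 1.0):
            errors.append(f"{name}[{i}]={v} outside [0, 1]")


@dataclass(frozen=True)
class HIVCareParams:
    """HIV care-cascade parameters on the monthly cycle.

    CD4 dynamics and the CD4-stratified HIV-death / severe-OI probability
    tables are configurable with synthetic defaults supplied by the fixture
    generator; they are not published quantities.
    """

    initial_cd4_mean: Mapping[str, float]
    initial_cd4_sd: Mapping[str, float]
    #: initial virologic suppression probability by adherence stratum
    initial_suppression_prob: tuple[float, float, float, float]
    #: monthly probability of viraemia while suppressed, by adherence stratum
    monthly_viraemia_prob: tuple[float, float, float, float]
    #: monthly probability of resuppression while viraemic, by regimen line
    monthly_resuppression_prob: tuple[float, float]
    #: monthly probability of disengagement, by months-on-model band (1-12, 13+)
    monthly_disengagement_prob: tuple[float, float]
    #: monthly probability of HIV/AIDS death by CD4 stratum, worst to best
    hiv_death_monthly_prob: tuple[float, float, float, float, float]
    #: monthly probability of a severe OI by CD4 stratum, worst to best
    severe_oi_monthly_prob: tuple[float, float, float, float, float]
    monthly_return_prob: float = 0.013
    min_months_before_return: int = 6
    n_regimen_lines: int = 2
    line_switch_months: int = 6
    cd4_gain_per_month_suppressed: float = 30.0
    cd4_ceiling: float = 900.0
    cd4_decline_per_month_unsuppressed: float = 4.0

    def __post_init__(self):
        errors: list[str] = []
        for sex in SEXES:
            if sex not in self.initial_cd4_mean or sex not in self.initial_cd4_sd:
                errors.append(f"initial_cd4 missing sex {sex!r}")
            elif self.initial_cd4_mean[sex] < 0 or self.initial_cd4_sd[sex] < 0:
                errors.append(f"initial_cd4 negative for sex {sex!r}")
        _check_probs("initial_suppression_prob", self.initial_suppression_prob, errors)
        _check_probs("monthly_viraemia_prob", self.monthly_viraemia_prob, errors)
        _check_probs("monthly_resuppression_prob", self.monthly_resuppression_prob, errors)
        _check_probs("monthly_disengagement_prob", self.monthly_disengagement_prob, errors)
        _check_probs("hiv_death_monthly_prob", self.hiv_death_monthly_prob, errors)
        _check_probs("severe_oi_monthly_prob", self.severe_oi_monthly_prob, errors)
        _check_probs("monthly_return_prob", [self.monthly_return_prob], errors)
        for name in ("hiv_death_monthly_prob", "severe_oi_monthly_prob"):
            vals = getattr(self, name)
            if any(vals[i] < vals[i + 1] for i in range(len(vals) - 1)):
                errors.append(f"{name} must be non-increasing in CD4 stratum: {vals}")
        if self.min_months_before_return < 0:
            errors.append("min_months_before_return must be >= 0")
        if errors:
            raise ValidationError("; ".join(errors))


@dataclass(frozen=True)
class SmokingParams:
    """Rules governing how smoking modifies non-AIDS mortality.

    Smoking has no mortality effect below ``onset_age`` (40y); a former
    smoker keeps current-smoker mortality for ``cessation_lag_months`` (5y)
    after quitting.  ``hr_override`` replaces the attributable-fraction-based
    derivation of current-smoker rates with a flat hazard ratio by sex
    (sensitivity analysis only).
    """

    onset_age: int = 40
    cessation_lag_months: int = 60
    hr_override: Optional[Mapping[str, float]] = None
    prevalence_source: str = "general"

    def __post_init__(self):
        if self.onset_age < 0 or self.cessation_lag_months < 0:
            raise ValidationError("onset_age and cessation_lag_months must be >= 0")
        if self.prevalence_source not in ("general", "pwh"):
            raise ValidationError(
                f"prevalence_source must be 'general' or 'pwh', got {self.prevalence_source!r}"
            )
        if self.hr_override is not None:
            for sex in SEXES:
                if sex not in self.hr_override:
                    raise ValidationError(f"hr_override missing sex {sex!r}")
                if self.hr_override[sex] < 1.0:
                    raise ValidationError("hr_override must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """One simulated cohort: homogeneous sex, entry age and smoking status.

    ``smoking_status='mixed'`` draws each person's status at initialization
    from the prevalence schedule (internal validation).  ``quit_delay_months``
    applies to former-smoker cohorts: 0 quits at model start, a positive
    value smokes until that month on model and then quits.
    """

    sex: str
    initial_age: float
    smoking_status: str
    n_persons: int
    seed: int
    quit_delay_months: int = 0

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.smoking_status not in SMOKING_STATUSES + ("mixed",):
            raise ValidationError(f"unknown smoking_status {self.smoking_status!r}")
        if self.n_persons < 1:
            raise ValidationError("n_persons must be >= 1")
        if self.quit_delay_months < 0:
            raise ValidationError("quit_delay_months must be >= 0")
        if self.quit_delay_months > 0 and self.smoking_status != "former":
            raise ValidationError(
                "quit_delay_months is only meaningful for former-smoker cohorts"
            )


@dataclass(frozen=True)
class ScenarioFlags:
    """Scenario switches applied on top of a parameter bundle."""

    hiv_enabled: bool = True
    high_adherence_full_engagement: bool = False
    art_naive: bool = False
    disengagement_override: Optional[float] = None
    initial_cd4_override: Optional[float] = None

    def __post_init__(self):
        if self.disengagement_override is not None and not (
            0.0 <= self.disengagement_override <= 1.0
        ):
            raise ValidationError("disengagement_override must be in [0, 1]")
        if self.initial_cd4_override is not None and self.initial_cd4_override < 0:
            raise ValidationError("initial_cd4_override must be >= 0")


@dataclass(frozen=True)
class PopulationImpactInputs:
    """Inputs for the population-level life-years-gained projection.

    ``weights`` maps ``(sex, decade_label)`` to the share of the smoking
    population in that stratum; ``per_person_gain`` maps the same keys to
    the per-person life-years gained by cessation at the stratum's
    representative model age.
    """

    n_smokers_total: float
    quit_proportion: float
    weights: Mapping[tuple[str, str], float]
    per_person_gain: Mapping[tuple[str, str], float]

    def __post_init__(self):
        if not (0.0 <= self.quit_proportion <= 1.0):
            raise ValidationError("quit_proportion must be in [0, 1]")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"weights sum to {total}, not 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("weights must be >= 0")


# ---------------------------------------------------------------------------
# the bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamBundle:
    """Everything the model needs, validated.

    ``prevalence`` and (optionally) ``pwh_prevalence`` map smoking status to
    an :class:`AgeSexSchedule` of prevalence proportions.
    """

    mortality: AgeSexSchedule
    attributable_fraction: AgeSexSchedule
    prevalence: Mapping[str, AgeSexSchedule]
    retention: QuitAgeRetentionSchedule
    adherence: AdherenceDistribution
    hiv: HIVCareParams
    smoking: SmokingParams = field(default_factory=SmokingParams)
    pwh_prevalence: Optional[Mapping[str, AgeSexSchedule]] = None
    age_cap: int = DEFAULT_AGE_CAP

    def __post_init__(self):
        for status in SMOKING_STATUSES:
            if status not in self.prevalence:
                raise SchemaError(f"prevalence missing status {status!r}")
        if self.pwh_prevalence is not None:
            for status in SMOKING_STATUSES:
                if status not in self.pwh_prevalence:
                    raise SchemaError(f"pwh_prevalence missing status {status!r}")
        # prevalence must sum to 1 in every band
        prev = self.active_prevalence("general")
        for sex in SEXES:
            total = sum(prev[s].values_by_year(sex) for s in SMOKING_STATUSES)
            if np.max(np.abs(total - 1.0)) > 1e-9:
                bad = int(np.argmax(np.abs(total - 1.0)))
                raise ValidationError(
                    f"prevalence proportions sum to {total[bad]:.9f} at age {bad} "
                    f"(sex={sex}); must sum to 1"
                )
        for status, sched in self.prevalence.items():
            for sex in SEXES:
                v = sched.values_by_year(sex)
                if np.any((v < 0) | (v > 1)):
                    raise ValidationError(f"prevalence[{status}] outside [0, 1] for {sex}")
        af_ok = True
        for sex in SEXES:
            af = self.attributable_fraction.values_by_year(sex)
            if np.any((af < 0) | (af >= 1)):
                raise ValidationError(f"attributable fraction outside [0, 1) for {sex}")
            m = self.mortality.values_by_year(sex)
            if np.any(m < 0):
                raise ValidationError(f"mortality rates negative for {sex}")

    def active_prevalence(self, source: Optional[str] = None) -> Mapping[str, AgeSexSchedule]:
        src = source or self.smoking.prevalence_source
        if src == "pwh":
            if self.pwh_prevalence is None:
                raise ValidationError(
                    "prevalence_source='pwh' but no pwh_prevalence schedules supplied"
                )
            return self.pwh_prevalence
        return self.prevalence

    def replace(self, **changes) -> "ParamBundle":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

_SCHEDULE_KEYS = {
    "mortality": "mortality",
    "attributable_fraction": "attributable_fraction",
    "prevalence_current": ("prevalence", "current"),
    "prevalence_former": ("prevalence", "former"),
    "prevalence_never": ("prevalence", "never"),
    "retention": "retention",
}


def load_params(config_path, schedule_dir=None) -> ParamBundle:
    """Read a YAML config plus the CSV schedules it references.

    Relative schedule paths resolve against ``schedule_dir`` (default: the
    config file's directory).  The returned bundle is fully validated;
    violations raise :class:`SchemaError` or :class:`ValidationError` naming
    the offending field.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = Path(schedule_dir) if schedule_dir is not None else config_path.parent
    age_cap = int(cfg.get("age_cap", DEFAULT_AGE_CAP))

    sched_cfg = cfg.get("schedules", {})

    def _sched_path(key: str) -> Path:
        if key not in sched_cfg:
            raise SchemaError(f"config missing schedules.{key}")
        return base / sched_cfg[key]

    mortality = AgeSexSchedule.from_csv(_sched_path("mortality"), age_cap, "mortality")
    af = AgeSexSchedule.from_csv(
        _sched_path("attributable_fraction"), age_cap, "attributable_fraction"
    )
    prevalence = {
        status: AgeSexSchedule.from_csv(
            _sched_path(f"prevalence_{status}"), age_cap, f"prevalence_{status}"
        )
        for status in SMOKING_STATUSES
    }
    pwh_prevalence = None
    if any(f"pwh_prevalence_{s}" in sched_cfg for s in SMOKING_STATUSES):
        pwh_prevalence = {
            status: AgeSexSchedule.from_csv(
                _sched_path(f"pwh_prevalence_{status}"), age_cap,
                f"pwh_prevalence_{status}"
            )
            for status in SMOKING_STATUSES
        }
    retention = QuitAgeRetentionSchedule.from_csv(_sched_path("retention"), age_cap)

    adh_cfg = cfg.get("adherence")
    if adh_cfg is None:
        raise SchemaError("config missing adherence section")
    adherence = AdherenceDistribution(
        probabilities=tuple(float(adh_cfg[s]) for s in ADHERENCE_STRATA)
    )

    hiv_cfg = dict(cfg.get("hiv", {}))
    for key in ("initial_suppression_prob", "monthly_viraemia_prob",
                "monthly_resuppression_prob", "monthly_disengagement_prob",
                "hiv_death_monthly_prob", "severe_oi_monthly_prob"):
        if key in hiv_cfg:
            hiv_cfg[key] = tuple(float(v) for v in hiv_cfg[key])
    hiv = HIVCareParams(**hiv_cfg)

    smoking_cfg = dict(cfg.get("smoking", {}))
    smoking = SmokingParams(**smoking_cfg)

    return ParamBundle(
        mortality=mortality,
        attributable_fraction=af,
        prevalence=prevalence,
        retention=retention,
        adherence=adherence,
        hiv=hiv,
        smoking=smoking,
        pwh_prevalence=pwh_prevalence,
        age_cap=age_cap,
    )


def save_params(bundle: ParamBundle, out_dir) -> Path:
    """Write a bundle as ``config.yaml`` plus CSV schedules; returns the
    config path.  ``load_params(save_params(b)) == b`` up to float round-trip
    through text."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    schedules = {
        "mortality": ("mortality.csv", bundle.mortality),
        "attributable_fraction": ("attributable_fraction.csv", bundle.attributable_fraction),
        "retention": ("retention.csv", bundle.retention),
    }
    for status in SMOKING_STATUSES:
        schedules[f"prevalence_{status}"] = (
            f"prevalence_{status}.csv", bundle.prevalence[status]
        )
    if bundle.pwh_prevalence is not None:
        for status in SMOKING_STATUSES:
            schedules[f"pwh_prevalence_{status}"] = (
                f"pwh_prevalence_{status}.csv", bundle.pwh_prevalence[status]
            )
    sched_cfg = {}
    for key, (fname, sched) in schedules.items():
        sched.to_csv(out_dir / fname)
        sched_cfg[key] = fname

    hiv = bundle.hiv
    cfg = {
        "age_cap": bundle.age_cap,
        "schedules": sched_cfg,
        "adherence": {s: float(p) for s, p in bundle.adherence.as_dict().items()},
        "hiv": {
            "initial_cd4_mean": {k: float(v) for k, v in hiv.initial_cd4_mean.items()},
            "initial_cd4_sd": {k: float(v) for k, v in hiv.initial_cd4_sd.items()},
            "initial_suppression_prob": list(hiv.initial_suppression_prob),
            "monthly_viraemia_prob": list(hiv.monthly_viraemia_prob),
            "monthly_resuppression_prob": list(hiv.monthly_resuppression_prob),
            "monthly_disengagement_prob": list(hiv.monthly_disengagement_prob),
            "hiv_death_monthly_prob": list(hiv.hiv_death_monthly_prob),
            "severe_oi_monthly_prob": list(hiv.severe_oi_monthly_prob),
            "monthly_return_prob": hiv.monthly_return_prob,
            "min_months_before_return": hiv.min_months_before_return,
            "n_regimen_lines": hiv.n_regimen_lines,
            "line_switch_months": hiv.line_switch_months,
            "cd4_gain_per_month_suppressed": hiv.cd4_gain_per_month_suppressed,
            "cd4_ceiling": hiv.cd4_ceiling,
            "cd4_decline_per_month_unsuppressed": hiv.cd4_decline_per_month_unsuppressed,
        },
        "smoking": {
            "onset_age": bundle.smoking.onset_age,
            "cessation_lag_months": bundle.smoking.cessation_lag_months,
            "hr_override": (dict(bundle.smoking.hr_override)
                            if bundle.smoking.hr_override else None),
            "prevalence_source": bundle.smoking.prevalence_source,
        },
    }
    config_path = out_dir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return config_path
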