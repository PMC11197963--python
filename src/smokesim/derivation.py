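"""Derivation of smoking-status-stratified non-AIDS mortality rates.

The overall non-AIDS mortality rate ``m`` in an age/sex band is decomposed
into never- (NS), former- (FS) and current-smoker (CS) rates using three
assumptions:

1. **Weighted average.** ``m = p_cs·m_CS + p_fs·m_FS + p_ns·m_NS`` with
   smoking-prevalence weights ``p``.
2. **Attributable fraction.** The gap between the overall and never-smoker
   rates is the smoking-attributable fraction ``AF`` of overall mortality:
   ``m_NS = m·(1 − AF)``.
3. **Excess-risk retention.** A former smoker retains a fraction ``f`` of
   the current-vs-never excess: ``m_FS = m_NS + f·(m_CS − m_NS)``, with
   ``f`` keyed by age at cessation.

Substituting 2 and 3 into 1 gives the closed form

    m_CS = m_NS + AF·m / (p_cs + f·p_fs)

For sensitivity analyses a flat hazard ratio can replace the AF-based
current-smoker rate: ``m_CS = HR·m_NS`` for ages at or above the smoking
mortality onset age, with ``m_NS`` still taken from the AF identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .params import (
    SEXES,
    SMOKING_STATUSES,
    AgeSexSchedule,
    ParamBundle,
    QuitAgeRetentionSchedule,
    SchemaError,
    ValidationError,
)


class InfeasibleSystemError(ValidationError):
    """Attributable deaths exist but nobody is exposed (p_cs + f·p_fs = 0)."""


def never_smoker_rate(m_overall: float, af: float) -> float:
    """Never-smoker rate from the attributable-fraction identity
    ``m_NS = m_overall · (1 − AF)``."""
    if m_overall < 0:
        raise ValidationError("m_overall must be >= 0")
    if not (0.0 <= af < 1.0):
        raise ValidationError(f"attributable fraction must be in [0, 1), got {af}")
    return m_overall * (1.0 - af)


def excess_retention_fraction(hr_fs: float, hr_cs: float) -> float:
    """Fraction of the current-vs-never excess risk retained by a former
    smoker, ``(HR_FS − 1) / (HR_CS − 1)``, clipped to [0, 1]."""
    if hr_cs <= 1.0:
        raise ValidationError(f"hr_cs must exceed 1, got {hr_cs}")
    if hr_fs < 1.0:
        raise ValidationError(f"hr_fs must be >= 1, got {hr_fs}")
    return min(1.0, max(0.0, (hr_fs - 1.0) / (hr_cs - 1.0)))


def solve_rates(m_overall: float, p_cs: float, p_fs: float, p_ns: float,
                af: float, f: float) -> tuple[float, float, float]:
    """Solve the three-assumption system for one band.

    Returns ``(m_CS, m_FS, m_NS)`` in annual-rate units.  The
    prevalence-weighted average of the returned rates reconstructs
    ``m_overall`` exactly (to float precision).
    """
    if abs(p_cs + p_fs + p_ns - 1.0) > 1e-9:
        raise ValidationError(
            f"prevalence proportions sum to {p_cs + p_fs + p_ns}, not 1"
        )
    if min(p_cs, p_fs, p_ns) < 0:
        raise ValidationError("prevalence proportions must be >= 0")
    if not (0.0 <= f <= 1.0):
        raise ValidationError(f"retention fraction f={f} outside [0, 1]")
    m_ns = never_smoker_rate(m_overall, af)
    exposed = p_cs + f * p_fs
    if af > 0 and m_overall > 0 and exposed <= 0:
        raise InfeasibleSystemError(
            "attributable fraction > 0 but p_cs + f·p_fs = 0: "
            "attributable deaths with no one exposed"
        )
    if exposed <= 0 or af == 0 or m_overall == 0:
        return m_ns, m_ns, m_ns
    excess_cs = af * m_overall / exposed
    m_cs = m_ns + excess_cs
    m_fs = m_ns + f * excess_cs
    return m_cs, m_fs, m_ns


@dataclass(frozen=True)
class SmokingStratifiedRates:
    """Derived never/former/current non-AIDS mortality rates.

    Per sex the rates are expanded to one value per integer age year for
    fast lookup: ``m_ns[sex][age]``, ``m_cs[sex][age]`` (annual rates) and
    ``f_quit[sex][quit_age]`` (excess-risk retention by age at cessation).
    A former smoker's rate is ``m_ns + f_quit[quit_age]·(m_cs − m_ns)``.
    ``table`` holds the band-level derivation with hazard ratios.
    """

    m_ns: Mapping[str, np.ndarray]
    m_cs: Mapping[str, np.ndarray]
    f_quit: Mapping[str, np.ndarray]
    table: pd.DataFrame
    age_cap: int
    onset_age: int

    def hr_cs(self, sex: str) -> np.ndarray:
        """Current-vs-never hazard ratio per age year (1 where m_ns = 0)."""
        ns, cs = self.m_ns[sex], self.m_cs[sex]
        return np.where(ns > 0, cs / np.where(ns > 0, ns, 1.0), 1.0)

    def m_fs(self, sex: str, quit_age_years: int) -> np.ndarray:
        """Former-smoker rate per age year for a given age at cessation
        (post-lag; the lag is applied by the rate-selection rules)."""
        f = self.f_quit[sex][quit_age_years]
        return self.m_ns[sex] + f * (self.m_cs[sex] - self.m_ns[sex])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def derive_schedule(bundle: ParamBundle,
                    hr_override: Optional[Mapping[str, float]] = None,
                    prevalence_source: Optional[str] = None
                    ) -> SmokingStratifiedRates:
    """Apply :func:`solve_rates` band by band across both sexes.

    All input schedules must share identical age bands.  ``hr_override``
    (defaulting to the bundle's ``smoking.hr_override``) switches to the
    flat-hazard-ratio mode for ages at or above the onset age.
    """
    mort = bundle.mortality
    af_sched = bundle.attributable_fraction
    prev = bundle.active_prevalence(prevalence_source)
    retention = bundle.retention
    smoking = bundle.smoking
    if hr_override is None:
        hr_override = smoking.hr_override

    ref_bands = {sex: mort.bands(sex) for sex in SEXES}
    for name, sched in [("attributable_fraction", af_sched)] + [
        (f"prevalence_{s}", prev[s]) for s in SMOKING_STATUSES
    ]:
        for sex in SEXES:
            if sched.bands(sex) != ref_bands[sex]:
                raise SchemaError(
                    f"schedule {name} bands do not match mortality bands for sex={sex}"
                )

    m_ns: dict[str, np.ndarray] = {}
    m_cs: dict[str, np.ndarray] = {}
    f_quit: dict[str, np.ndarray] = {}
    rows = []
    onset = smoking.onset_age

    for sex in SEXES:
        ns_y = np.zeros(bundle.age_cap)
        cs_y = np.zeros(bundle.age_cap)
        f_quit[sex] = retention.values_by_year(sex)
        quit_bands = sorted(
            (lo, hi, f) for s, lo, hi, f in retention.entries if s == sex
        )
        for lo, hi in ref_bands[sex]:
            mid_age = lo  # any age inside the band; piecewise constant
            m = mort.lookup(sex, mid_age)
            af = af_sched.lookup(sex, mid_age)
            p_cs = prev["current"].lookup(sex, mid_age)
            p_fs = prev["former"].lookup(sex, mid_age)
            p_ns = prev["never"].lookup(sex, mid_age)
            band_mns = never_smoker_rate(m, af)
            if hr_override is not None:
                hr = hr_override[sex] if lo >= onset else 1.0
                band_mcs = hr * band_mns
            else:
                # representative f for the weighted-average solve: the
                # retention at this band's own ages (FS in this band quit at
                # various ages; band-level f enters only through p_fs·f)
                f_here = _band_mean_retention(retention, sex, lo, hi)
                band_mcs, _, band_mns = solve_rates(m, p_cs, p_fs, p_ns, af, f_here)
            lo_i, hi_i = int(math.ceil(lo)), int(math.ceil(min(hi, bundle.age_cap)))
            ns_y[lo_i:hi_i] = band_mns
            cs_y[lo_i:hi_i] = band_mcs
            hr_cs_band = band_mcs / band_mns if band_mns > 0 else 1.0
            for q_lo, q_hi, f in quit_bands:
                band_mfs = band_mns + f * (band_mcs - band_mns)
                hr_fs_band = band_mfs / band_mns if band_mns > 0 else 1.0
                rows.append({
                    "sex": sex, "age_lo": lo, "age_hi": hi,
                    "quit_age_lo": q_lo, "quit_age_hi": q_hi,
                    "m_ns": band_mns, "m_fs": band_mfs, "m_cs": band_mcs,
                    "hr_fs": hr_fs_band, "hr_cs": hr_cs_band,
                })
        m_ns[sex] = ns_y
        m_cs[sex] = cs_y

    return SmokingStratifiedRates(
        m_ns=m_ns, m_cs=m_cs, f_quit=f_quit,
        table=pd.DataFrame(rows), age_cap=bundle.age_cap, onset_age=onset,
    )


def _band_mean_retention(retention: QuitAgeRetentionSchedule, sex: str,
                         lo: float, hi: float) -> float:
    """Mean retention fraction over quit ages in [lo, hi) (uniform weight
    per year of age), used as the band-level f in the weighted-average
    solve."""
    lo_i, hi_i = int(math.ceil(lo)), int(math.ceil(hi))
    vals = retention.values_by_year(sex)[lo_i:min(hi_i, len(retention.values_by_year(sex)))]
    return float(vals.mean()) if len(vals) else 0.0
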