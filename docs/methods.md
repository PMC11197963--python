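# Methods

## Model structure

The engine simulates individuals on a monthly cycle from cohort entry to
death or age 100 (the age cap; survivors are recorded as dying at the
cap).  State per person: age in integer months, sex, smoking status
(never/former/current) with age at cessation, CD4 count, ART adherence
stratum (95−100 / 80−94 / 66−79 / 0−65%), engagement in care, ART and
suppression flags, regimen line, and event counters.

Events are applied within each month in a fixed, documented order:

1. **Return to care** — a disengaged person may return (resuming ART,
   initially viraemic) by a background monthly probability (1.3%/month)
   once at least 6 months have elapsed since disengagement, or is forced
   back the same cycle by a severe opportunistic infection (OI, drawn at
   step 5).
2. **Disengagement** — engaged persons disengage by a monthly probability
   keyed to months on model (months 1−12 vs 13+, 0.7%/month in the base
   case); disengagement stops ART and ends suppression the same month.
3. **Viraemia / resuppression** — suppressed persons on ART rebound by an
   adherence-stratum probability (0.2 / 0.3 / 0.3 / 18.0%/month); viraemic
   persons on ART may resuppress by a regimen-line probability; after a
   6-month failure window on line 1 they switch to line 2.  Newly viraemic
   persons cannot resuppress in the same month.
4. **CD4 update** — +30 cells/µl per month toward a 900 ceiling while
   suppressed; −4 cells/µl per month otherwise (floor 0).
5. **Severe OI** — drawn by CD4 stratum (<50 / 50−200 / 200−350 /
   350−500 / >500 cells/µl); its only modelled consequence is the forced
   return to care.
6. **HIV/AIDS death** — drawn by CD4 stratum; skipped entirely when the
   scenario disables HIV.
7. **Non-AIDS death** — monthly probability `1 − exp(−rate/12)` from the
   annual smoking-stratified rate (below).
8. **Ageing** — counters advance; a scheduled mid-simulation quit switches
   a current smoker to former at the configured month on model.

Mortality draws come last so they see the month's updated CD4.  Death age
uses the start-of-month convention (the age held on entering the fatal
cycle); the life-table oracle uses the identical convention.

The ordering of steps within the month, like any discrete-time model's, is
a convention; it is fixed and documented rather than derived.

## Smoking-stratified mortality

Given an overall annual non-AIDS rate `m` per age band and sex, smoking
prevalences `p_cs, p_fs, p_ns`, attributable fraction `AF` and excess-risk
retention `f`, the derivation solves the three-assumption system in closed
form (see README).  "The difference between overall and never-smoker
mortality is proportional to the attributable fraction" is implemented as
the standard attributable-fraction identity `m_NS = m·(1 − AF)` — the only
normalisation under which `AF` is a fraction of deaths.  The band-level
former-smoker rate used in the weighted average takes the mean retention
over that band's quit ages; an individual's `f` is frozen at their
quit-age band at the moment of cessation.

Rate-selection rules (shared verbatim by the engine and the oracle, so the
two cannot drift): no smoking effect below age 40 (`AF = 0` there by
construction); current smokers use `m_CS`; former smokers who quit before
40 use `m_NS`; former smokers within the 5-year cessation lag use `m_CS`;
thereafter `m_NS + f(quit age)·(m_CS − m_NS)`.

For sensitivity analyses a flat hazard ratio replaces the AF-based
current-smoker rate (`m_CS = HR·m_NS` at ages ≥ 40, with `m_NS` still from
the AF identity), applied uniformly across ages.

Rates are annual per-person hazards converted once per month via
`1 − exp(−rate/12)`; age bands are half-open `[lo, hi)` years, with
band lookup by `floor(age_months/12)`.

## Randomness and common random numbers

The engine is vectorised over persons.  Each month it consumes one
`(n, 7)` block of uniforms — one column per event in the order above —
for **all** persons, alive or dead, whatever the scenario flags.  Because
the draw structure never depends on state, two cohorts with the same seed
and size are driven by identical randomness person by person.  Arms whose
dynamics coincide therefore produce *identical* death ages (exact null
equivalences: former-quit-before-40 ≡ never; HR ≡ 1 ⇒ zero smoking
deltas; HIV disabled in both arms ⇒ zero HIV delta), and deltas between
differing arms are paired, with empirical paired standard errors.
Initialization draws (mixed-status assignment where applicable, CD4,
adherence, initial suppression) follow the same fixed-order rule.
Simulation is bitwise reproducible for a fixed seed.

## Synthetic fixtures: what they emulate, and what they do not

The published analysis rests on calibration inputs that are not printed
in reusable form: national life tables, survey smoking prevalence by age
and sex, GBD attributable fractions, quit-age-stratified hazard ratios,
and the HIV natural-history tables of a long-lived microsimulation
platform.  The fixture generator reproduces their *structure*:

* overall non-AIDS mortality is Gompertz (`a·e^{b·age}`, b ≈ 0.095/yr,
  levels chosen so adult mortality is in a realistic southern-African
  non-AIDS range);
* prevalence steps by age and sex around the national anchors (8% of
  females, 37% of males currently smoking);
* attributable fractions are zero below 40, rise and plateau with age,
  and are calibrated so the derived current-vs-never hazard ratios fall
  inside the published ranges (1.2−2.3 females, 1.1−1.9 males);
* retention fractions rise with quit age from 0 (quit < 40) to ≈ 0.45
  (females) / 0.40 (males), keeping former-vs-never hazard ratios near
  the published 1−1.5 / 1−1.3 spans;
* a PWH-specific prevalence variant scales current/former prevalence by
  1.3 (renormalising never) for the corresponding sensitivity analysis.

The published cohort-care parameters are embedded verbatim (initial CD4
789/318 and 600/303 — ART-naïve 432/206 and 314/160; adherence
77.1/17.2/3.2/2.4 — ART-naïve 51.3/35.8/7.9/5.1; viraemia 0.2/0.3/18.0
with the lumped 0−65% adherence stratum mapped to the ≤30% viraemia
probability, configurable; initial suppression 100% — ART-naïve
96.4/85.1/0; disengagement 0.7%/month — ART-naïve 1.6%/month in year 1;
return 1.3%/month).  Published adherence proportions are rounded to 0.1%
and may sum to 99.9 or 100.1%; they are accepted and renormalised.

The CD4 dynamics (±30/−4 cells/µl/month, ceiling 900), the CD4-stratified
HIV-death and severe-OI monthly probabilities, the resuppression
probabilities (50%/35% per month by line) and the 6-month line-switch
window are **synthetic defaults**, not published values; they are isolated
behind the config so calibrated tables can be dropped in.  Consequently
the absolute life-expectancy levels and the HIV-attributable loss this
package prints characterise the synthetic base case, not the published
calibration: passing tests demonstrate the algebraic identities, the
engine/oracle agreement, the exact CRN equivalences and the ordering and
sensitivity structure of the analysis — not agreement with externally
calibrated life-expectancy values.

## Analysis conventions

* Life expectancy is the mean **age at death** of the cohort; its
  standard error is the sample SE of death ages.
* Survival at age *a* is the fraction with recorded death age ≥ *a*
  (1 at entry, 0 one month past the last death); its trapezoid integral
  recovers LE − entry age to within half a month.
* Default analysis size is 200,000 persons per arm with logged seeds —
  Monte Carlo SE of an LE is then ≈ 0.03 years, and paired deltas are an
  order of magnitude tighter; users can scale `n` up.
* The two-way sensitivity grid defaults to flat hazard ratios
  {1.0, 1.5, 2.0, 2.5, 3.0} × monthly disengagement
  {0.0, 0.7, 1.6, 2.0}%/month.
* Population impact multiplies per-person cessation gains, simulated at
  representative ages 35/45/55 for the 30−39/40−49/50−59 decades, by
  stratum counts and the quit proportion.  Default stratum weights are
  equal across decades within sex, sexes scaled by the 8%/37% prevalence
  anchors (the exact population weighting is not published); they are
  configurable.
* The quit-delay scenarios start the 5-year cessation lag at the quit
  month (not at model entry).

## Degenerate inputs and numerical choices

* `AF ≥ 1`, probabilities outside [0, 1], band-coverage gaps and
  band-mismatched schedules raise typed validation errors naming the
  offending field.
* `AF > 0` with nobody exposed (`p_cs + f·p_fs = 0`) is an infeasible
  system and raises rather than returning infinite rates.
* The weighted-average conservation identity holds to 1e-12 relative by
  construction; the closed form is cross-checked in the tests against a
  numerical root-finder solving the three simultaneous equations.
* CD4 is truncated below at 0 at initialization (normal draw) and during
  decline.

## Known limitations

No HIV transmission, no smoking relapse or initiation, no TB/comorbidity
structure, no costs.  The care cascade is deliberately compact (two
regimen lines, a single background return probability); richer regimen
sequencing would change absolute LE levels but not the comparisons'
structure.  The life-table oracle covers only HIV-disabled scenarios — a
deterministic treatment of the full care cascade would require a large
multi-state transition matrix and is out of scope.
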