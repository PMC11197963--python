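# smokesim

Monte Carlo microsimulation of the life-expectancy impact of tobacco
smoking and smoking cessation among virologically suppressed people with
HIV (PWH) on antiretroviral therapy (ART), in a South-Africa-like
epidemiological setting.

The package is aimed at health-policy modellers and epidemiologists who
want to quantify, at the individual and population level, how many
life-years smoking costs PWH in care — and how many of those years
smoking cessation recovers — relative to the life-years lost to treated
HIV itself.

## The model

Individuals are simulated on a monthly cycle from cohort entry (age 35,
45 or 55) until death or age 100.  Each month a person faces, in fixed
order: return to HIV care (if disengaged ≥ 6 months, or forced by a
severe opportunistic infection), disengagement from care (stopping ART),
virologic rebound and resuppression (by ART-adherence stratum, with a
second regimen line after sustained failure), a CD4 update, CD4-stratified
HIV/AIDS mortality, and non-AIDS mortality stratified by smoking status.

Smoking enters through the non-AIDS mortality rate.  Given an overall
non-AIDS rate *m* in an age/sex band, smoking prevalences
*p*<sub>CS</sub>, *p*<sub>FS</sub>, *p*<sub>NS</sub>
(current/former/never), a smoking-attributable fraction *AF* and a
quit-age-dependent excess-risk retention fraction *f* ∈ [0, 1], the
stratified rates solve:

```
m  = p_CS·m_CS + p_FS·m_FS + p_NS·m_NS      (weighted average)
m_NS = m·(1 − AF)                            (attributable fraction)
m_FS = m_NS + f·(m_CS − m_NS)                (excess-risk retention)
⇒ m_CS = m_NS + AF·m / (p_CS + f·p_FS)
```

Smoking has no mortality effect below age 40; a person who quits keeps
current-smoker mortality for 5 years (the cessation lag) and thereafter
retains the fraction *f* of the current-vs-never excess, frozen at their
quit-age band.  Derived current-vs-never hazard ratios in the packaged
base case span 1.2−2.3 (females) and 1.1−1.9 (males).

Cohort arms are simulated under common random numbers, so arms whose
dynamics coincide (e.g. a never smoker and a former smoker who quit
before 40) produce *identical* death ages person by person, and deltas
between arms are estimated with paired precision.  A deterministic
monthly life table provides a closed-form oracle for every HIV-disabled
scenario.

National calibration inputs (life tables, survey prevalence, GBD
attributable fractions, CD4-stratified event tables) are not shipped;
a synthetic fixture generator produces parameter bundles with the same
statistical structure, anchored to the published cohort parameters
(initial CD4 789/318 female, 600/303 male; adherence distribution
77.1/17.2/3.2/2.4%; disengagement 0.7%/month; return to care 1.3%/month)
and calibrated to the published hazard-ratio ranges.  See
`docs/methods.md` for what the fixture does and does not emulate.

## Worked example

```python
import smokesim as sk

bundle = sk.make_base_case_fixture()
rates = sk.derive_schedule(bundle)
for sex in ("female", "male"):
    comp = sk.compare_smoking_vs_hiv(bundle, rates, sex, 45.0,
                                     n=50_000, seed=1)
    le = {k: v[0] for k, v in comp.le_by_arm.items()}
    print(f"{sex}: LE CS {le['current']:.1f}, FS {le['former']:.1f}, "
          f"NS {le['never']:.1f} | smoking loss {comp.ly_lost_smoking:.1f}, "
          f"cessation gain {comp.ly_gained_cessation:.1f}, "
          f"HIV loss {comp.ly_lost_hiv:.1f}")
```

prints

```
female: LE CS 64.2, FS 67.2, NS 69.3 | smoking loss 5.1, cessation gain 3.0, HIV loss 0.9
male: LE CS 62.4, FS 65.0, NS 66.4 | smoking loss 4.0, cessation gain 2.6, HIV loss 0.8
```

Life expectancy (LE) is reported as **age at death**, not remaining
years.  A 45-year-old female PWH who keeps smoking dies on average at
64.2; quitting at 45 adds 3.0 life-years, never having smoked adds 5.1 —
more than the 0.9 life-years she loses to (treated, mostly suppressed)
HIV itself.  Scaled to a smoking PWH population of 620,000, a 10−25%
quit proportion yields roughly 170,000−430,000 life-years gained
(`sk.population_impact_from_model`).

The same analyses are available from the shell via the `smokesim` CLI
(`make-fixture`, `derive-rates`, `simulate`, `oracle`, `compare`,
`validate-internal`, `sensitivity`, `two-way`, `population-impact`); every
run writes a JSON manifest for bitwise reproduction.

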