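# Methods

## Scope and data model

`ehrepi` computes descriptive epidemiology (annual incidence, point and
period prevalence) from two tables — a patient registry (one row per
patient with registration, optional quality-start, optional transfer-out
and death dates, and the practice's last collection date) and a clinical
event stream (patient, date, code) — plus a disease definition (code
list, chronicity class, expected duration). Cohort membership is by exact
string match on codes; cross-dictionary code mapping, native database
extracts and free-text records are out of scope. Practice-migration
deduplication is reduced to a per-patient `duplicate_excluded` input
flag, since computing it requires source-database internals.

## Interval conventions

All interval arithmetic is closed-start/half-open-end; human-facing dates
print the last included day. This removes every ±1-day ambiguity:

- A calendar year is `[1 Jan, 1 Jan next year)`, so 31 December belongs
  to its year.
- "90 days or more after registration" means the day at offset exactly 90
  is the first incident-eligible day.
- An expected duration of *D* days gives the episode `[t, t + D)`: the
  event day plus the following *D* − 1 days.
- A prior record at exactly *t* − *D* is inside the recurrence look-back
  `[t − D, t)` and blocks incidence at *t*.
- Episodes that overlap **or abut** (gap of zero days) merge: a
  continuation record arriving within or exactly at the end of the
  expected duration is treated as the same illness.

## Eligibility and follow-up

Follow-up runs from `max(registration, quality-start)` (quality-start only
where the source applies an up-to-standard rule) to
`min(transfer-out, death, last collection)`. Patients are excluded when
they fail the quality flag, are marked duplicate, or have fewer than one
day of follow-up; every exclusion is written with its reason.

Events dated before follow-up start still set the presentation date — the
patient is prevalent from the start of observation — but can never be
incident, because incidence requires the record inside follow-up. Events
dated before 1900 or after the registry's latest collection date are
flagged rather than dropped: visibility over silent loss.

## Incidence

The numerator counts incident **events** (a recurrent disease can make
the same patient incident more than once per year). The denominator is
person-time at risk, partitioned by calendar year: for patient *p* and
year *y* the at-risk interval starts at
`max(1 Jan y, follow-up start, registration + 90d)` and ends at
`min(1 Jan y+1, follow-up end + 1d)` under the half-open convention, minus
time inside exposure episodes. For lifelong disease this reduces to
censoring at onset. For recurrent disease the published formula names
only "the onset of the specific disease event"; we censor at each
episode's start and re-admit at-risk time when the episode's expected
duration elapses, keeping numerator and denominator consistent for
repeatable events. This is an interpretation and is documented as such.

Denominator eligibility ("at least 90 days' registration") is evaluated
on the registration-to-follow-up-end span; the wash-in also bounds the
at-risk start, so no person-time accrues during it. Days convert to
person-years at 365.25 days/year — a stated convention, used everywhere.

Rates are per `scale` person-years. In auto mode the scale is the
smallest power of ten in 10²–10⁶ that makes the period-average rate at
least 1, mirroring the practice of choosing denominators by the magnitude
of the numerator while staying deterministic; an explicit `--scale`
overrides. A zero denominator yields a missing rate, never a division
error.

## Prevalence

Point prevalence is evaluated at 30 June of every year (never 1 July).
The numerator is patients whose follow-up and some exposure episode both
cover 30 June; the denominator is all followed patients covering 30 June.
Period prevalence (acute disease) counts patients whose follow-up and
exposure overlap any part of the year, each patient once regardless of
episode count, over the same mid-year denominator. That denominator
follows the literal definition even though it is asymmetric with the
numerator: a patient with a January episode who transfers out in March is
counted in the numerator but absent from the denominator. Such patients
are listed in a consistency report; the rate is left as defined. The
90-day wash-in applies only to incidence, never to prevalence
denominators. The chronicity-to-measure mapping (acute → period,
otherwise point) is a default the caller can override.

## Concordance

Lin's coefficient is computed with population (1/n) moments by default,
matching the original estimator; a sample-moment variant is available via
`moments="sample"`. When both series are constant with equal means the
coefficient is 0/0 and is reported as an error, not as perfect agreement.
Confidence intervals use the Fisher z-transform with Lin's asymptotic
variance; this is a documented choice of interval, not a claim about how
any particular published interval was obtained. Interpretation bands are
half-open as listed (< 0.90 poor; 0.90 ≤ ρc < 0.95 moderate; 0.95 ≤ ρc
< 0.99 substantial; ρc ≥ 0.99 almost perfect), so 0.95 is substantial and
0.99 almost perfect. Multi-disease pooled coefficients are computed on
values as printed (each study's own denominator scale); re-expression to
a common per-100,000 scale is possible by transforming the inputs before
alignment.

## Synthetic registries and ground truth

The generator emulates: staggered registration (uniform over a span
defaulting to five years before the observation window through its end,
so cohorts mix long-registered and recently registered patients),
competing transfer-out and death as independent constant hazards, and
disease onset as a constant hazard from registration, all resolved as the
minimum of exponential waiting times. Lifelong disease emits exactly one
onset record; acute disease samples the next onset from a recurrence
hazard that starts only when the previous episode's duration has elapsed,
so inter-event gaps exceed the duration by construction. Waiting times
are floored to whole days; the sub-day truncation is negligible at the
hazards of interest (≪ 1/365 per day).

What it does **not** emulate: realistic code dictionaries, practice-level
clustering, secular recording trends, seasonality, or age structure.
Passing recovery tests therefore shows the estimators are correct under
the stated rules, not that real-world recording artefacts are handled.

The configured onset hazard is the analytic incidence truth. Expected
prevalence has no convenient closed form under staggered entry and
censoring, so ground truth is Monte-Carlo: an independent replicate
(default 20,000 trajectories, seed stream decoupled from the registry
draw) evaluates exposure directly on sampled trajectories — never through
the estimator code — and reports binomial standard errors. For recurrent
disease the replicate fixes each trajectory's first onset and resamples
recurrences per evaluation year; per-year expectations are unaffected,
joint across-year trajectories are not represented.

## Problem sizes in the test suite

Oracle-equivalence tests run 220 randomized patients over a 10-year
window against an exhaustive day-by-day enumeration, exact to the day.
Hazard recovery simulates 50,000 lifelong patients at 0.005/person-year
(≈ 2,500 incident cases, ≈ 490,000 person-years), where the pooled
estimate must land within three Monte-Carlo standard errors of the
configured hazard. The concordance core is cross-checked against an
independently coded moment formula on 1,000 random vectors to 1e-12.

## Known limitations

- Exact code matching only; no phenotype refinement.
- No age/sex standardisation (an optional sex split is the only
  stratification envisioned); comparisons against standardised external
  series will disagree by construction.
- The period-prevalence asymmetry above means period rates can in
  principle exceed 1 in pathological populations; the consistency report
  is the guard rail.
- Duplicate detection is an input, not a computation.
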