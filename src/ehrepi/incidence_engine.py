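"""Annual incidence with calendar-year person-time denominators.

A matching record is incident when it falls inside follow-up, at least 90
days after registration (the wash-in, so that prevalent disease recorded at
registration is not mistaken for onset), and — for lifelong disease — is
the patient's first-ever record, or — for recurrent disease — has no
matching record within the expected duration before it.

Person-time at risk is partitioned by calendar year.  For each patient and
year the at-risk interval starts at the latest of 1 January, follow-up
start, and registration + 90 days, ends at the earliest of 31 December
(inclusive) and follow-up end, and excludes time inside exposure episodes:
a lifelong patient is censored at onset, while for recurrent diseases
at-risk time resumes when each episode ends.  Days convert to person-years
at 365.25 days/year.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .cohort_builder import (
    ExposureEpisode,
    FollowUp,
    build_all_episodes,
    derive_follow_ups,
    matching_event_dates,
)
from .registry_model import (
    Chronicity,
    ClinicalEvent,
    DiseaseDefinition,
    ObservationWindow,
    PatientRecord,
)

WASH_IN_DAYS = 90
DAYS_PER_YEAR = 365.25
AUTO_SCALES = (10**2, 10**3, 10**4, 10**5, 10**6)


@dataclass(frozen=True)
class AnnualEstimate:
    """One year's estimate.  ``denominator`` is person-years for incidence
    and persons for prevalence; ``rate`` is per ``scale`` denominator units
    and is ``None`` when the denominator is zero."""

    year: int
    numerator: int
    denominator: float
    rate: Optional[float]
    scale: int


def identify_incident_events(
    d: DiseaseDefinition,
    event_dates: list[dt.date],
    registration_date: dt.date,
    fu: FollowUp,
) -> list[dt.date]:
    """Incident record dates for one patient.

    ``event_dates`` must be every matching date for the patient (records
    outside follow-up participate in the first-ever / look-back rules even
    though they cannot themselves be incident).
    """
    dates = sorted(set(event_dates))
    wash_in_end = registration_date + dt.timedelta(days=WASH_IN_DAYS)
    incident: list[dt.date] = []
    for i, t in enumerate(dates):
        if not fu.covers(t):
            continue
        if t < wash_in_end:  # "90 days or more" after registration: day 90 counts
            continue
        if d.chronicity is Chronicity.lifelong:
            if i != 0:
                continue
        elif i > 0 and (t - dates[i - 1]).days <= d.expected_duration_days:
            # a record within the look-back window blocks incidence
            continue
        incident.append(t)
    return incident


def _subtract(
    start: dt.date,
    end_exclusive: dt.date,
    holes: Iterable[tuple[dt.date, dt.date]],
) -> int:
    """Days in [start, end_exclusive) not covered by the hole intervals
    (each half-open, assumed sorted and disjoint)."""
    total = 0
    cursor = start
    for h_start, h_end in holes:
        if h_end <= cursor:
            continue
        if h_start >= end_exclusive:
            break
        if h_start > cursor:
            total += (min(h_start, end_exclusive) - cursor).days
        cursor = max(cursor, min(h_end, end_exclusive))
    if cursor < end_exclusive:
        total += (end_exclusive - cursor).days
    return max(0, total)


def patient_person_days(
    year: int,
    fu: FollowUp,
    registration_date: dt.date,
    episodes: list[ExposureEpisode],
) -> int:
    """At-risk days one patient contributes to one calendar year.

    Requires at least 90 days between registration and follow-up end
    (denominator eligibility); ineligible patients contribute zero.
    """
    if (fu.end - registration_date).days < WASH_IN_DAYS:
        return 0
    a = max(dt.date(year, 1, 1), fu.start, registration_date + dt.timedelta(days=WASH_IN_DAYS))
    b_exclusive = min(dt.date(year + 1, 1, 1), fu.end_exclusive)
    if b_exclusive <= a:
        return 0
    holes = [(ep.onset, ep.end_exclusive) for ep in episodes]
    return _subtract(a, b_exclusive, holes)


def person_time_by_year(
    year: int,
    followups: dict[str, FollowUp],
    registration_dates: dict[str, dt.date],
    episodes: dict[str, list[ExposureEpisode]],
) -> int:
    """Total at-risk person-days for one calendar year, summed over all
    eligible patients (cases and non-cases alike)."""
    return sum(
        patient_person_days(year, fu, registration_dates[pid], episodes.get(pid, []))
        for pid, fu in followups.items()
    )


def choose_scale(total_numerator: int, total_denominator: float) -> int:
    """Smallest power of ten in 10^2..10^6 making the period-average rate
    at least 1; the largest if none does."""
    if total_denominator <= 0 or total_numerator == 0:
        return AUTO_SCALES[-1]
    base = total_numerator / total_denominator
    for s in AUTO_SCALES:
        if base * s >= 1:
            return s
    return AUTO_SCALES[-1]


def annual_incidence(
    d: DiseaseDefinition,
    patients: Iterable[PatientRecord],
    events: Iterable[ClinicalEvent],
    window: ObservationWindow | None = None,
    scale: Optional[int] = None,
    uts_applies: bool = True,
) -> list[AnnualEstimate]:
    """Annual incidence rates over the observation window.

    ``scale=None`` selects the denominator scale automatically from the
    magnitude of the period-average rate.
    """
    window = window or ObservationWindow()
    patients = list(patients)
    events = list(events)
    followups, _ = derive_follow_ups(patients, uts_applies)
    registrations = {p.patient_id: p.registration_date for p in patients}
    episodes = build_all_episodes(d, events, followups)
    match_dates = matching_event_dates(events, d)

    numerators: dict[int, int] = {y: 0 for y in window.years}
    for pid, dates in match_dates.items():
        fu = followups.get(pid)
        if fu is None:
            continue
        for t in identify_incident_events(d, dates, registrations[pid], fu):
            if window.start_date <= t <= window.end_date and t.year in numerators:
                numerators[t.year] += 1

    person_years = {
        y: person_time_by_year(y, followups, registrations, episodes) / DAYS_PER_YEAR
        for y in window.years
    }
    if scale is None:
        scale = choose_scale(
            sum(numerators.values()), sum(person_years.values())
        )
    return [
        AnnualEstimate(
            year=y,
            numerator=numerators[y],
            denominator=person_years[y],
            rate=(numerators[y] / person_years[y] * scale) if person_years[y] > 0 else None,
            scale=scale,
        )
        for y in window.years
    ]


def write_incidence(
    disease: str, estimates: list[AnnualEstimate], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "disease": disease,
                "year": e.year,
                "numerator": e.numerator,
                "person_years": round(e.denominator, 4),
                "rate": round(e.rate, 6) if e.rate is not None else "",
                "scale": e.scale,
            }
            for e in estimates
        ],
        columns=["disease", "year", "numerator", "person_years", "rate", "scale"],
    ).to_csv(path, index=False)
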