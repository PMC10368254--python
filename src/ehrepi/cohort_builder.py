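"""Follow-up derivation, cohort selection and exposure episodes.

Follow-up runs from the later of registration and (where the source applies
an up-to-standard quality rule) the practice's quality start date, to the
earliest of transfer-out, death and the practice's last collection date.
Patients need at least one day of follow-up; those without are excluded,
as are patients failing the data-quality or duplicate flags.

A patient enters a disease cohort at their presentation date — the first
event carrying one of the disease's codes (exact string match).  Exposure
episodes then follow the chronicity class: a lifelong disease exposes the
patient from presentation to the end of follow-up; otherwise each distinct
event day opens an episode of the expected duration, and overlapping or
abutting episodes are merged into one illness.

Interval convention: episodes are closed-start/half-open-end internally
(``end_exclusive``); the human-facing ``end`` is the last exposed day.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .registry_model import Chronicity, ClinicalEvent, DiseaseDefinition, PatientRecord

ONE_DAY = dt.timedelta(days=1)


@dataclass(frozen=True)
class FollowUp:
    patient_id: str
    start: dt.date
    end: dt.date  # last day of follow-up (inclusive)

    @property
    def end_exclusive(self) -> dt.date:
        return self.end + ONE_DAY

    def covers(self, day: dt.date) -> bool:
        return self.start <= day <= self.end


@dataclass(frozen=True)
class Exclusion:
    patient_id: str
    reason: str


@dataclass(frozen=True)
class ExposureEpisode:
    """One merged interval of disease exposure.  ``end`` is the last exposed
    day; open-ended lifelong exposure is already clipped to follow-up end."""

    patient_id: str
    onset: dt.date
    end: dt.date

    @property
    def end_exclusive(self) -> dt.date:
        return self.end + ONE_DAY

    def covers(self, day: dt.date) -> bool:
        return self.onset <= day <= self.end

    def overlaps(self, start: dt.date, end_exclusive: dt.date) -> bool:
        return self.onset < end_exclusive and start < self.end_exclusive


def derive_follow_up(
    p: PatientRecord, uts_applies: bool
) -> FollowUp | Exclusion:
    """Derive a patient's follow-up window, or the reason they are excluded.

    Exclusion reasons: ``unacceptable_quality``, ``duplicate``,
    ``no_follow_up`` (fewer than one day between derived start and end).
    """
    if not p.acceptable_quality:
        return Exclusion(p.patient_id, "unacceptable_quality")
    if p.duplicate_excluded:
        return Exclusion(p.patient_id, "duplicate")
    start = p.registration_date
    if uts_applies and p.quality_start_date is not None:
        start = max(start, p.quality_start_date)
    end_candidates = [p.last_collection_date]
    if p.transfer_out_date is not None:
        end_candidates.append(p.transfer_out_date)
    if p.death_date is not None:
        end_candidates.append(p.death_date)
    end = min(end_candidates)
    if end < start:
        return Exclusion(p.patient_id, "no_follow_up")
    return FollowUp(p.patient_id, start, end)


def derive_follow_ups(
    patients: Iterable[PatientRecord], uts_applies: bool
) -> tuple[dict[str, FollowUp], list[Exclusion]]:
    """Vector form of :func:`derive_follow_up` over a registry."""
    followups: dict[str, FollowUp] = {}
    exclusions: list[Exclusion] = []
    for p in patients:
        result = derive_follow_up(p, uts_applies)
        if isinstance(result, FollowUp):
            followups[p.patient_id] = result
        else:
            exclusions.append(result)
    return followups, exclusions


def matching_event_dates(
    events: Iterable[ClinicalEvent], d: DiseaseDefinition
) -> dict[str, list[dt.date]]:
    """Per patient, the sorted distinct dates of events coded for disease ``d``.

    Same-day duplicates collapse to one: recurrence logic is defined on
    distinct dates.
    """
    per_patient: dict[str, set[dt.date]] = {}
    for e in events:
        if e.code in d.codes:
            per_patient.setdefault(e.patient_id, set()).add(e.event_date)
    return {pid: sorted(dates) for pid, dates in per_patient.items()}


def select_disease_cohort(
    events: Iterable[ClinicalEvent],
    d: DiseaseDefinition,
    followups: dict[str, FollowUp],
) -> dict[str, dt.date]:
    """Presentation date (earliest matching event) per followed patient.

    Events before follow-up start still set the presentation date — the
    patient is prevalent from the start of observation — but can never be
    incident (incidence requires the record inside follow-up).
    """
    return {
        pid: dates[0]
        for pid, dates in matching_event_dates(events, d).items()
        if pid in followups
    }


def merge_intervals(
    intervals: list[tuple[dt.date, dt.date]]
) -> list[tuple[dt.date, dt.date]]:
    """Merge overlapping or abutting [start, end_exclusive) intervals."""
    merged: list[tuple[dt.date, dt.date]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def build_exposure_episodes(
    d: DiseaseDefinition,
    event_dates: list[dt.date],
    fu: FollowUp,
) -> list[ExposureEpisode]:
    """Build merged exposure episodes for one patient.

    Lifelong: one episode from presentation to follow-up end.  Otherwise one
    half-open window of ``expected_duration_days`` per distinct event day;
    overlapping or abutting windows merge (a repeat record within the
    expected duration is a continuation of the same illness, not a new one).
    Episode ends are clipped to follow-up end — a patient cannot be observed
    prevalent beyond observation — but onsets may precede follow-up start.
    Episodes starting after follow-up end are dropped.
    """
    if not event_dates:
        return []
    dates = sorted(set(event_dates))
    if d.chronicity is Chronicity.lifelong:
        onset = dates[0]
        if onset > fu.end:
            return []
        return [ExposureEpisode(fu.patient_id, onset, fu.end)]
    duration = dt.timedelta(days=d.expected_duration_days)
    raw = [(t, t + duration) for t in dates if t <= fu.end]
    return [
        ExposureEpisode(fu.patient_id, start, min(end_excl, fu.end_exclusive) - ONE_DAY)
        for start, end_excl in merge_intervals(raw)
    ]


def build_all_episodes(
    d: DiseaseDefinition,
    events: Iterable[ClinicalEvent],
    followups: dict[str, FollowUp],
) -> dict[str, list[ExposureEpisode]]:
    """Exposure episodes for every followed patient with matching events."""
    episodes: dict[str, list[ExposureEpisode]] = {}
    for pid, dates in matching_event_dates(events, d).items():
        fu = followups.get(pid)
        if fu is None:
            continue
        eps = build_exposure_episodes(d, dates, fu)
        if eps:
            episodes[pid] = eps
    return episodes


def write_exclusions(exclusions: list[Exclusion], path: str | Path) -> None:
    pd.DataFrame(
        [{"patient_id": e.patient_id, "reason": e.reason} for e in exclusions],
        columns=["patient_id", "reason"],
    ).to_csv(path, index=False)


def write_episodes(
    episodes: dict[str, list[ExposureEpisode]], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {"patient_id": ep.patient_id, "onset": ep.onset, "end": ep.end}
            for eps in episodes.values()
            for ep in eps
        ],
        columns=["patient_id", "onset", "end"],
    ).to_csv(path, index=False)
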