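"""Annual point and period prevalence.

Point prevalence (chronic and other non-acute disease) counts patients
whose follow-up and disease exposure both cover the mid-year index date,
30 June; the denominator is every followed patient whose follow-up covers
30 June.  Period prevalence (acute disease) counts patients whose
follow-up and exposure each overlap any part of the calendar year, while
the denominator remains the mid-year population.  That denominator choice
makes the period measure slightly asymmetric: a patient can qualify for
the numerator (say, a January episode before leaving the practice in
March) without being in the mid-year denominator.  Such patients are
counted as defined and surfaced in a consistency report rather than
silently reconciled.

Prevalence denominators do not apply the 90-day incidence wash-in.
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
)
from .incidence_engine import AnnualEstimate, choose_scale
from .registry_model import (
    Chronicity,
    ClinicalEvent,
    DiseaseDefinition,
    ObservationWindow,
    PatientRecord,
)


@dataclass(frozen=True)
class ConsistencyFlag:
    """A patient in the period-prevalence numerator for a year but absent
    from its mid-year denominator."""

    patient_id: str
    year: int


def midpoint(year: int) -> dt.date:
    return dt.date(year, 6, 30)


def point_prevalence(
    year: int,
    episodes: dict[str, list[ExposureEpisode]],
    followups: dict[str, FollowUp],
    scale: int,
) -> AnnualEstimate:
    """Prevalence on 30 June: exposed-and-followed over followed."""
    mid = midpoint(year)
    denominator = sum(1 for fu in followups.values() if fu.covers(mid))
    numerator = sum(
        1
        for pid, eps in episodes.items()
        if followups[pid].covers(mid) and any(ep.covers(mid) for ep in eps)
    )
    rate = numerator / denominator * scale if denominator > 0 else None
    return AnnualEstimate(year, numerator, float(denominator), rate, scale)


def period_prevalence(
    year: int,
    episodes: dict[str, list[ExposureEpisode]],
    followups: dict[str, FollowUp],
    scale: int,
) -> tuple[AnnualEstimate, list[ConsistencyFlag]]:
    """Prevalence over the whole year (acute disease), mid-year denominator.

    Each patient counts once however many episodes they have in the year.
    Returns the estimate plus flags for numerator patients missing from the
    denominator.
    """
    year_start = dt.date(year, 1, 1)
    year_end_exclusive = dt.date(year + 1, 1, 1)
    mid = midpoint(year)
    denominator = sum(1 for fu in followups.values() if fu.covers(mid))
    numerator = 0
    flags: list[ConsistencyFlag] = []
    for pid, eps in episodes.items():
        fu = followups[pid]
        fu_overlaps = fu.start < year_end_exclusive and year_start <= fu.end
        if fu_overlaps and any(
            ep.overlaps(year_start, year_end_exclusive) for ep in eps
        ):
            numerator += 1
            if not fu.covers(mid):
                flags.append(ConsistencyFlag(pid, year))
    rate = numerator / denominator * scale if denominator > 0 else None
    return AnnualEstimate(year, numerator, float(denominator), rate, scale), flags


def annual_prevalence(
    d: DiseaseDefinition,
    patients: Iterable[PatientRecord],
    events: Iterable[ClinicalEvent],
    window: ObservationWindow | None = None,
    scale: Optional[int] = None,
    uts_applies: bool = True,
    prevalence_type: Optional[str] = None,
) -> tuple[list[AnnualEstimate], list[ConsistencyFlag], str]:
    """Annual prevalence series over the window.

    ``prevalence_type`` is ``"point"`` or ``"period"``; by default acute
    disease gets period prevalence and everything else point prevalence.
    Returns (estimates, consistency flags, resolved prevalence type).
    """
    window = window or ObservationWindow()
    if prevalence_type is None:
        prevalence_type = (
            "period" if d.chronicity is Chronicity.acute else "point"
        )
    if prevalence_type not in {"point", "period"}:
        raise ValueError(f"unknown prevalence type {prevalence_type!r}")

    patients = list(patients)
    followups, _ = derive_follow_ups(patients, uts_applies)
    episodes = build_all_episodes(d, list(events), followups)

    if scale is None:
        # auto-scale on the period-average proportion, as for incidence
        nums, dens = 0, 0.0
        for y in window.years:
            if prevalence_type == "point":
                est = point_prevalence(y, episodes, followups, 1)
            else:
                est, _ = period_prevalence(y, episodes, followups, 1)
            nums += est.numerator
            dens += est.denominator
        scale = choose_scale(nums, dens)

    estimates: list[AnnualEstimate] = []
    all_flags: list[ConsistencyFlag] = []
    for y in window.years:
        if prevalence_type == "point":
            estimates.append(point_prevalence(y, episodes, followups, scale))
        else:
            est, flags = period_prevalence(y, episodes, followups, scale)
            estimates.append(est)
            all_flags.extend(flags)
    return estimates, all_flags, prevalence_type


def write_prevalence(
    disease: str,
    prevalence_type: str,
    estimates: list[AnnualEstimate],
    path: str | Path,
) -> None:
    pd.DataFrame(
        [
            {
                "disease": disease,
                "year": e.year,
                "prevalence_type": prevalence_type,
                "numerator": e.numerator,
                "population": int(e.denominator),
                "rate": round(e.rate, 6) if e.rate is not None else "",
                "scale": e.scale,
            }
            for e in estimates
        ],
        columns=[
            "disease",
            "year",
            "prevalence_type",
            "numerator",
            "population",
            "rate",
            "scale",
        ],
    ).to_csv(path, index=False)


def write_consistency(flags: list[ConsistencyFlag], path: str | Path) -> None:
    pd.DataFrame(
        [{"patient_id": f.patient_id, "year": f.year} for f in flags],
        columns=["patient_id", "year"],
    ).to_csv(path, index=False)
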