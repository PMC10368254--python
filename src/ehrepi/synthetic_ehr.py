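"""Synthetic registries with known ground truth.

The generator emulates a primary-care research registry: patients enter at
staggered registration dates (uniform over a configurable span, allowing
entry before the observation window opens), leave by transfer-out or death
as competing constant hazards, and acquire disease by a constant onset
hazard from entry.  Lifelong disease produces a single onset record;
acute disease produces recurrent records, each new onset sampled from a
recurrence hazard that starts only when the previous episode's expected
duration has elapsed — so inter-event gaps exceed the duration by
construction.  Competing risks are resolved as the minimum of independent
exponential waiting times, which keeps the configured onset hazard the
exact analytic truth for incidence.

Expected prevalence has no convenient closed form under staggered entry
and censoring, so the ground truth carries Monte-Carlo estimates from an
independent large replicate, evaluated directly on sampled trajectories
(never through the estimator code), with binomial standard errors.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, model_validator

from .registry_model import (
    Chronicity,
    ClinicalEvent,
    DiseaseDefinition,
    ObservationWindow,
    PatientRecord,
    Sex,
)

DAYS_PER_YEAR = 365.25


class SimulationConfig(BaseModel):
    """Parameters of one synthetic registry draw.

    Hazards are per person-year; zero disables the process.  The
    registration span defaults to five years before the observation window
    through its end, so cohorts include both long-registered and recently
    registered patients.
    """

    n_patients: int
    window: ObservationWindow = ObservationWindow()
    registration_start: Optional[dt.date] = None
    registration_end: Optional[dt.date] = None
    exit_hazard: float = 0.0
    death_hazard: float = 0.0
    onset_hazard: float = 0.01
    chronicity: Chronicity = Chronicity.lifelong
    expected_duration_days: Optional[int] = None
    recurrence_hazard: float = 0.0
    disease_name: str = "synthetic"
    code: str = "D001"
    seed: int
    truth_replicates: int = 20_000

    @model_validator(mode="after")
    def _defaults_and_checks(self) -> "SimulationConfig":
        if self.registration_start is None:
            self.registration_start = self.window.start_date - dt.timedelta(
                days=int(5 * DAYS_PER_YEAR)
            )
        if self.registration_end is None:
            self.registration_end = self.window.end_date
        if self.registration_start > self.registration_end:
            raise ValueError("registration span is inverted")
        if self.registration_end > self.window.end_date:
            raise ValueError("registration must not start after the window ends")
        for name in ("exit_hazard", "death_hazard", "onset_hazard", "recurrence_hazard"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.chronicity is not Chronicity.lifelong and (
            self.expected_duration_days is None or self.expected_duration_days < 1
        ):
            raise ValueError("expected_duration_days required for non-lifelong disease")
        return self

    def disease_definition(self) -> DiseaseDefinition:
        return DiseaseDefinition(
            name=self.disease_name,
            chronicity=self.chronicity,
            expected_duration_days=(
                None
                if self.chronicity is Chronicity.lifelong
                else self.expected_duration_days
            ),
            codes=frozenset({self.code}),
        )


@dataclass
class GroundTruth:
    """Analytic incidence truth plus Monte-Carlo prevalence truth.

    ``point_prevalence`` / ``period_prevalence`` map year to
    (expected value, standard error); the period map is filled only for
    acute disease.
    """

    true_incidence_rate: float
    point_prevalence: dict[int, tuple[float, float]]
    period_prevalence: dict[int, tuple[float, float]]
    n_replicates: int


def _exp_wait_days(rng: np.random.Generator, hazard: float, size: int) -> np.ndarray:
    """Exponential waiting times in days for a per-person-year hazard."""
    if hazard <= 0:
        return np.full(size, np.inf)
    return rng.exponential(DAYS_PER_YEAR / hazard, size=size)


def _onset_offsets(
    rng: np.random.Generator,
    first_wait: float,
    horizon_days: float,
    chronicity: Chronicity,
    duration_days: Optional[int],
    recurrence_hazard: float,
) -> list[int]:
    """Integer day offsets (from registration) of each onset record."""
    onsets: list[int] = []
    t = first_wait
    while t <= horizon_days:
        onsets.append(int(t))
        if chronicity is Chronicity.lifelong:
            break
        if recurrence_hazard <= 0:
            break
        # next at-risk period starts when the current episode's duration ends
        t = int(t) + duration_days + rng.exponential(DAYS_PER_YEAR / recurrence_hazard)
    return onsets


def simulate_registry(
    c: SimulationConfig,
) -> tuple[list[PatientRecord], list[ClinicalEvent], GroundTruth]:
    """Draw one synthetic registry; byte-reproducible from the seed."""
    rng = np.random.default_rng(c.seed)
    n = c.n_patients
    span = (c.registration_end - c.registration_start).days
    reg_offsets = rng.integers(0, span + 1, size=n)
    exit_waits = _exp_wait_days(rng, c.exit_hazard, n)
    death_waits = _exp_wait_days(rng, c.death_hazard, n)
    first_onsets = _exp_wait_days(rng, c.onset_hazard, n)
    sexes = rng.integers(0, 2, size=n)

    last_collection = c.window.end_date
    patients: list[PatientRecord] = []
    events: list[ClinicalEvent] = []
    for i in range(n):
        pid = f"P{i:06d}"
        reg = c.registration_start + dt.timedelta(days=int(reg_offsets[i]))
        transfer = (
            reg + dt.timedelta(days=int(exit_waits[i]))
            if np.isfinite(exit_waits[i])
            and reg + dt.timedelta(days=int(exit_waits[i])) <= last_collection
            else None
        )
        death = (
            reg + dt.timedelta(days=int(death_waits[i]))
            if np.isfinite(death_waits[i])
            and reg + dt.timedelta(days=int(death_waits[i])) <= last_collection
            else None
        )
        fu_end = min(
            [d for d in (transfer, death, last_collection) if d is not None]
        )
        patients.append(
            PatientRecord(
                patient_id=pid,
                registration_date=reg,
                transfer_out_date=transfer,
                death_date=death,
                last_collection_date=last_collection,
                sex=Sex.female if sexes[i] == 0 else Sex.male,
            )
        )
        horizon = (fu_end - reg).days
        for offset in _onset_offsets(
            rng,
            first_onsets[i],
            horizon,
            c.chronicity,
            c.expected_duration_days,
            c.recurrence_hazard,
        ):
            events.append(
                ClinicalEvent(
                    patient_id=pid,
                    event_date=reg + dt.timedelta(days=offset),
                    code=c.code,
                )
            )
    truth = _prevalence_truth(c)
    return patients, events, truth


def _prevalence_truth(c: SimulationConfig) -> GroundTruth:
    """Monte-Carlo expected prevalence from an independent replicate.

    Exposure at each mid-year date (and over each year, for acute disease)
    is evaluated directly on freshly sampled trajectories; the replicate
    uses a seed stream decoupled from the registry draw.
    """
    rng = np.random.default_rng(np.random.SeedSequence([c.seed, 0x7AB1E]))
    m = c.truth_replicates
    span = (c.registration_end - c.registration_start).days
    reg = rng.integers(0, span + 1, size=m).astype(float)  # days since span start
    far = 1e12  # sentinel for "never happens" (infinite waiting time)
    exit_w = np.nan_to_num(_exp_wait_days(rng, c.exit_hazard, m), posinf=far)
    death_w = np.nan_to_num(_exp_wait_days(rng, c.death_hazard, m), posinf=far)
    onset_w = np.floor(
        np.nan_to_num(_exp_wait_days(rng, c.onset_hazard, m), posinf=far)
    )
    last_day = (c.window.end_date - c.registration_start).days
    fu_end = np.minimum(
        reg + np.minimum(np.floor(exit_w), np.floor(death_w)), last_day
    )
    onset_day = reg + onset_w  # first onset, absolute day index

    duration = c.expected_duration_days or 0
    point: dict[int, tuple[float, float]] = {}
    period: dict[int, tuple[float, float]] = {}
    for year in c.window.years:
        mid = (dt.date(year, 6, 30) - c.registration_start).days
        followed = (reg <= mid) & (mid <= fu_end)
        n_f = int(followed.sum())
        if n_f == 0:
            continue
        if c.chronicity is Chronicity.lifelong:
            exposed = onset_day <= mid
        else:
            # recurrent episodes: exposed at mid iff some onset in (mid-duration, mid];
            # approximated by first-episode coverage plus renewal episodes
            exposed = _recurrent_exposed_at(
                rng, onset_day, mid, duration, c.recurrence_hazard
            )
        p = float((exposed & followed).sum()) / n_f
        point[year] = (p, float(np.sqrt(max(p * (1 - p), 1e-12) / n_f)))
        if c.chronicity is Chronicity.acute:
            y0 = (dt.date(year, 1, 1) - c.registration_start).days
            y1 = (dt.date(year + 1, 1, 1) - c.registration_start).days
            fu_overlap = (reg < y1) & (y0 <= fu_end)
            num = _recurrent_overlap_year(
                rng, onset_day, y0, y1, duration, c.recurrence_hazard, fu_end
            )
            q = float((num & fu_overlap).sum()) / n_f
            period[year] = (q, float(np.sqrt(max(q * (1 - q), 1e-12) / n_f)))
    return GroundTruth(
        true_incidence_rate=c.onset_hazard,
        point_prevalence=point,
        period_prevalence=period,
        n_replicates=m,
    )


def _episode_starts(
    rng: np.random.Generator,
    first: float,
    limit: float,
    duration: int,
    recurrence_hazard: float,
) -> list[float]:
    starts = []
    t = first
    while t <= limit:
        starts.append(t)
        if recurrence_hazard <= 0:
            break
        t = t + duration + rng.exponential(DAYS_PER_YEAR / recurrence_hazard)
    return starts


def _recurrent_exposed_at(
    rng: np.random.Generator,
    onset_day: np.ndarray,
    mid: float,
    duration: int,
    recurrence_hazard: float,
) -> np.ndarray:
    out = np.zeros(onset_day.size, dtype=bool)
    for i, first in enumerate(onset_day):
        for s in _episode_starts(rng, first, mid, duration, recurrence_hazard):
            if s <= mid < s + duration:
                out[i] = True
                break
    return out


def _recurrent_overlap_year(
    rng: np.random.Generator,
    onset_day: np.ndarray,
    y0: float,
    y1: float,
    duration: int,
    recurrence_hazard: float,
    fu_end: np.ndarray,
) -> np.ndarray:
    out = np.zeros(onset_day.size, dtype=bool)
    for i, first in enumerate(onset_day):
        limit = min(y1, fu_end[i])
        for s in _episode_starts(rng, first, limit, duration, recurrence_hazard):
            if s < y1 and s + duration > y0:
                out[i] = True
                break
    return out


# ---------------------------------------------------------------------------
# Worked fixtures


# Most-recent-year prevalence per published comparator study and the matching
# platform estimate, each on the study's own printed scale.  Missing published
# values are recorded as "Not available" and dropped during alignment.
TABLE2_PREVALENCE_PUBLISHED: dict[str, object] = {
    "charcot_marie_tooth": 29.5,
    "diabetic_retinopathy": 22.01,
    "guillain_barre": 40.1,
    "idiopathic_pulmonary_fibrosis": 10.57,
    "inflammatory_myopathy": 25.0,
    "lyme_disease": "Not available",
    "lennox_gastaut": 0.289,
    "motor_neurone_disease": 12.6,
    "muscular_dystrophy": 29.5,
    "myasthenia_gravis": 33.7,
    "nonvalvular_atrial_fibrillation": "Not available",
    "optic_neuritis": 114.8,
    "osteoarthritis": 10.77,
    "systemic_sclerosis": 307.0,
}
TABLE2_PREVALENCE_CANDIDATE: dict[str, float] = {
    "charcot_marie_tooth": 27.7,
    "diabetic_retinopathy": 20.03,
    "guillain_barre": 40.0,
    "idiopathic_pulmonary_fibrosis": 10.32,
    "inflammatory_myopathy": 24.5,
    "lyme_disease": 17.28,
    "lennox_gastaut": 0.167,
    "motor_neurone_disease": 12.3,
    "muscular_dystrophy": 31.1,
    "myasthenia_gravis": 32.9,
    "nonvalvular_atrial_fibrillation": 2.02,
    "optic_neuritis": 98.4,
    "osteoarthritis": 10.61,
    "systemic_sclerosis": 305.0,
}

FIXTURE_NAMES = (
    "table2_prevalence",
    "washin_boundary",
    "recurrence_window",
    "period_asymmetry",
)


def make_worked_fixture(name: str, outdir: str | Path) -> dict[str, Path]:
    """Write one of the deterministic worked fixtures; returns its files.

    ``table2_prevalence``: the labelled published-vs-platform most-recent-
    year prevalence pairs.  ``washin_boundary``: two otherwise identical
    patients whose single record falls 89 and 90 days after registration.
    ``recurrence_window``: a 28-day acute disease with records at day 0,
    20 and 60 of a year.  ``period_asymmetry``: a patient with a January
    episode who leaves the practice before 30 June, triggering the period-
    prevalence numerator/denominator asymmetry.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "table2_prevalence":
        ref = outdir / "reference.csv"
        cand = outdir / "candidate.csv"
        pd.DataFrame(
            {"label": list(TABLE2_PREVALENCE_PUBLISHED),
             "value": list(TABLE2_PREVALENCE_PUBLISHED.values())}
        ).to_csv(ref, index=False)
        pd.DataFrame(
            {"label": list(TABLE2_PREVALENCE_CANDIDATE),
             "value": list(TABLE2_PREVALENCE_CANDIDATE.values())}
        ).to_csv(cand, index=False)
        return {"reference": ref, "candidate": cand}
    if name == "washin_boundary":
        return _registry_fixture(
            outdir,
            patients=[
                ("A", "2010-01-01", "2010-12-31"),
                ("B", "2010-01-01", "2010-12-31"),
            ],
            events=[("A", "2010-03-31", "D1"), ("B", "2010-04-01", "D1")],
            disease={"name": "washin", "chronicity": "lifelong", "codes": ["D1"]},
            window=("2010-01-01", "2010-12-31"),
        )
    if name == "recurrence_window":
        return _registry_fixture(
            outdir,
            patients=[("A", "2009-01-01", "2010-12-31")],
            events=[
                ("A", "2010-01-01", "D2"),
                ("A", "2010-01-21", "D2"),
                ("A", "2010-03-02", "D2"),
            ],
            disease={
                "name": "recurrent",
                "chronicity": "acute",
                "expected_duration_days": 28,
                "codes": ["D2"],
            },
            window=("2010-01-01", "2010-12-31"),
        )
    if name == "period_asymmetry":
        return _registry_fixture(
            outdir,
            patients=[
                ("X", "2009-01-01", "2010-12-31", "2010-03-01"),
                ("Y", "2009-01-01", "2010-12-31"),
                ("Z", "2009-01-01", "2010-12-31"),
            ],
            events=[("X", "2010-01-10", "D3"), ("Y", "2010-07-15", "D3")],
            disease={
                "name": "asymmetric",
                "chronicity": "acute",
                "expected_duration_days": 28,
                "codes": ["D3"],
            },
            window=("2010-01-01", "2010-12-31"),
        )
    raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")


def _registry_fixture(
    outdir: Path,
    patients: list[tuple],
    events: list[tuple[str, str, str]],
    disease: dict,
    window: tuple[str, str],
) -> dict[str, Path]:
    patients_path = outdir / "patients.csv"
    events_path = outdir / "events.csv"
    disease_path = outdir / "disease.yaml"
    window_path = outdir / "window.yaml"
    rows = []
    for p in patients:
        pid, reg, lc = p[0], p[1], p[2]
        transfer = p[3] if len(p) > 3 else ""
        rows.append(
            {
                "patient_id": pid,
                "registration_date": reg,
                "quality_start_date": "",
                "transfer_out_date": transfer,
                "death_date": "",
                "last_collection_date": lc,
                "sex": "female",
                "acceptable_quality": "true",
                "duplicate_excluded": "false",
            }
        )
    pd.DataFrame(rows).to_csv(patients_path, index=False)
    pd.DataFrame(
        [{"patient_id": p, "event_date": d, "code": code} for p, d, code in events]
    ).to_csv(events_path, index=False)
    disease_path.write_text(yaml.safe_dump(disease, sort_keys=False))
    window_path.write_text(
        yaml.safe_dump({"start_date": window[0], "end_date": window[1]})
    )
    return {
        "patients": patients_path,
        "events": events_path,
        "disease": disease_path,
        "window": window_path,
    }
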