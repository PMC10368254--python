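"""Domain types and I/O for patient registries, clinical event streams and
disease definitions.

The registry model mirrors the administrative skeleton of a UK primary-care
research database: each patient carries a practice registration date, an
optional data-quality ("up-to-standard") start date, optional transfer-out
and death dates, and the practice's last data-collection date.  Clinical
events are (patient, date, code) triples; a disease is defined by a code
list plus a chronicity class that selects the exposure model.

All dates are ISO-8601 (``YYYY-MM-DD``).  Loaders collect row-level
diagnostics instead of aborting on the first malformed row, so a load
report always accounts for every input row.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, field_validator, model_validator

MIN_PLAUSIBLE_DATE = dt.date(1900, 1, 1)

PATIENT_COLUMNS = [
    "patient_id",
    "registration_date",
    "quality_start_date",
    "transfer_out_date",
    "death_date",
    "last_collection_date",
    "sex",
    "acceptable_quality",
    "duplicate_excluded",
]
EVENT_COLUMNS = ["patient_id", "event_date", "code"]


class Sex(str, enum.Enum):
    female = "female"
    male = "male"
    unknown = "unknown"


class Chronicity(str, enum.Enum):
    """Exposure model for a disease.

    ``lifelong``      — once presented, exposed until end of follow-up.
    ``non_lifelong``  — exposed for a fixed expected duration per episode;
                        point prevalence is reported.
    ``acute``         — as ``non_lifelong`` but period prevalence is reported.
    """

    lifelong = "lifelong"
    non_lifelong = "non_lifelong"
    acute = "acute"


class PatientRecord(BaseModel):
    """One registry row: a patient's administrative dates and quality flags."""

    patient_id: str
    registration_date: dt.date
    quality_start_date: Optional[dt.date] = None
    transfer_out_date: Optional[dt.date] = None
    death_date: Optional[dt.date] = None
    last_collection_date: dt.date
    sex: Sex = Sex.unknown
    acceptable_quality: bool = True
    duplicate_excluded: bool = False

    @model_validator(mode="after")
    def _check_date_order(self) -> "PatientRecord":
        if self.registration_date > self.last_collection_date:
            raise ValueError(
                "registration_date must not be after last_collection_date"
            )
        for name in ("transfer_out_date", "death_date"):
            value = getattr(self, name)
            if value is not None and value < self.registration_date:
                raise ValueError(f"{name} precedes registration_date")
        if (
            self.quality_start_date is not None
            and self.quality_start_date < MIN_PLAUSIBLE_DATE
        ):
            raise ValueError("quality_start_date before 1900-01-01")
        return self


class ClinicalEvent(BaseModel):
    """A dated, coded clinical record for one patient."""

    patient_id: str
    event_date: dt.date
    code: str
    flagged: bool = False  # outside any plausible date range, or unknown patient

    @field_validator("code")
    @classmethod
    def _non_empty_code(cls, v: str) -> str:
        if not v:
            raise ValueError("code must be non-empty")
        return v


class DiseaseDefinition(BaseModel):
    """Code list plus chronicity class and, for non-lifelong disease, the
    expected episode duration in days (also the recurrence look-back)."""

    name: str
    chronicity: Chronicity
    expected_duration_days: Optional[int] = None
    codes: frozenset[str]

    @model_validator(mode="after")
    def _duration_consistent(self) -> "DiseaseDefinition":
        if self.chronicity is Chronicity.lifelong:
            if self.expected_duration_days is not None:
                raise ValueError(
                    "expected_duration_days must be absent for lifelong disease"
                )
        else:
            if self.expected_duration_days is None or self.expected_duration_days < 1:
                raise ValueError(
                    "expected_duration_days >= 1 required for "
                    f"{self.chronicity.value} disease"
                )
        if not self.codes:
            raise ValueError("code list must be non-empty")
        return self


class ObservationWindow(BaseModel):
    """Calendar window over which annual estimates are produced."""

    start_date: dt.date = dt.date(2004, 1, 1)
    end_date: dt.date = dt.date(2020, 12, 31)

    @model_validator(mode="after")
    def _ordered(self) -> "ObservationWindow":
        if self.start_date > self.end_date:
            raise ValueError("start_date must be <= end_date")
        return self

    @property
    def years(self) -> range:
        return range(self.start_date.year, self.end_date.year + 1)


@dataclass
class RowDiagnostic:
    """A rejected or suspicious input row, addressable by row number."""

    row: int  # 1-based data row number (header excluded)
    field: str
    message: str


@dataclass
class LoadReport:
    """Accounting for one load: accepted + rejected == input rows."""

    n_rows: int = 0
    n_accepted: int = 0
    diagnostics: list[RowDiagnostic] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return self.n_rows - self.n_accepted


def _parse_date(raw: object, *, required: bool) -> Optional[dt.date]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        if required:
            raise ValueError("missing required date")
        return None
    return dt.date.fromisoformat(str(raw).strip())


def _parse_bool(raw: object) -> bool:
    s = str(raw).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f", ""}:
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def load_registry(
    patients_path: str | Path, events_path: str | Path
) -> tuple[list[PatientRecord], list[ClinicalEvent], LoadReport]:
    """Read the patient and event CSVs.

    Malformed rows are rejected and reported with their row number and the
    offending field; a missing required column raises immediately.  Events
    referring to an unknown patient, or dated outside the plausible range
    (before 1900, or after the registry's latest collection date), are
    retained but flagged rather than dropped.
    """
    patients_df = pd.read_csv(patients_path, dtype=str, keep_default_na=False)
    events_df = pd.read_csv(events_path, dtype=str, keep_default_na=False)

    for col in PATIENT_COLUMNS:
        if col not in patients_df.columns:
            raise ValueError(f"patients file missing required column {col!r}")
    for col in EVENT_COLUMNS:
        if col not in events_df.columns:
            raise ValueError(f"events file missing required column {col!r}")

    report = LoadReport(n_rows=len(patients_df) + len(events_df))
    patients: list[PatientRecord] = []
    for i, row in enumerate(patients_df.itertuples(index=False), start=1):
        try:
            patients.append(_patient_from_row(row))
            report.n_accepted += 1
        except ValueError as exc:
            report.diagnostics.append(
                RowDiagnostic(row=i, field=_blamed_field(exc, PATIENT_COLUMNS), message=str(exc))
            )

    known_ids = {p.patient_id for p in patients}
    max_collection = max(
        (p.last_collection_date for p in patients), default=dt.date.max
    )
    events: list[ClinicalEvent] = []
    for i, row in enumerate(events_df.itertuples(index=False), start=1):
        try:
            event_date = _parse_date(row.event_date, required=True)
            ev = ClinicalEvent(
                patient_id=row.patient_id, event_date=event_date, code=row.code
            )
            ev.flagged = (
                ev.patient_id not in known_ids
                or ev.event_date < MIN_PLAUSIBLE_DATE
                or ev.event_date > max_collection
            )
            events.append(ev)
            report.n_accepted += 1
        except ValueError as exc:
            report.diagnostics.append(
                RowDiagnostic(row=i, field=_blamed_field(exc, EVENT_COLUMNS), message=str(exc))
            )
    return patients, events, report


def _patient_from_row(row) -> PatientRecord:
    dates: dict[str, Optional[dt.date]] = {}
    for name, required in [
        ("registration_date", True),
        ("quality_start_date", False),
        ("transfer_out_date", False),
        ("death_date", False),
        ("last_collection_date", True),
    ]:
        try:
            dates[name] = _parse_date(getattr(row, name), required=required)
        except ValueError as exc:
            raise ValueError(f"{name}: {exc}") from exc
    try:
        sex = Sex(str(row.sex).strip().lower() or "unknown")
    except ValueError as exc:
        raise ValueError(f"sex: unrecognised value {row.sex!r}") from exc
    try:
        acceptable = _parse_bool(row.acceptable_quality)
        duplicate = _parse_bool(row.duplicate_excluded)
    except ValueError as exc:
        raise ValueError(f"flag: {exc}") from exc
    return PatientRecord(
        patient_id=row.patient_id,
        sex=sex,
        acceptable_quality=acceptable,
        duplicate_excluded=duplicate,
        **dates,
    )


def _blamed_field(exc: Exception, columns: list[str]) -> str:
    msg = str(exc)
    for col in columns:
        if col in msg:
            return col
    if "sex" in msg:
        return "sex"
    if "flag" in msg:
        return "flags"
    return "row"


def write_registry(
    patients: list[PatientRecord],
    events: list[ClinicalEvent],
    patients_path: str | Path,
    events_path: str | Path,
) -> None:
    """Write canonical CSVs; a load of the output reproduces the input."""

    def d(x: Optional[dt.date]) -> str:
        return x.isoformat() if x is not None else ""

    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "registration_date": d(p.registration_date),
                "quality_start_date": d(p.quality_start_date),
                "transfer_out_date": d(p.transfer_out_date),
                "death_date": d(p.death_date),
                "last_collection_date": d(p.last_collection_date),
                "sex": p.sex.value,
                "acceptable_quality": str(p.acceptable_quality).lower(),
                "duplicate_excluded": str(p.duplicate_excluded).lower(),
            }
            for p in patients
        ],
        columns=PATIENT_COLUMNS,
    ).to_csv(patients_path, index=False)
    pd.DataFrame(
        [
            {"patient_id": e.patient_id, "event_date": d(e.event_date), "code": e.code}
            for e in events
        ],
        columns=EVENT_COLUMNS,
    ).to_csv(events_path, index=False)


def load_disease_definition(config_path: str | Path) -> DiseaseDefinition:
    """Load one disease definition from a YAML or JSON document.

    The code list is given inline under ``codes`` or in a side file named by
    ``codes_file`` (one code per line, relative to the config); it is
    deduplicated on load.
    """
    path = Path(config_path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"disease definition {path} is not a mapping")
    if "codes_file" in raw and "codes" not in raw:
        codes_path = path.parent / raw.pop("codes_file")
        raw["codes"] = [
            line.strip() for line in codes_path.read_text().splitlines() if line.strip()
        ]
    raw["codes"] = frozenset(raw.get("codes", []))
    return DiseaseDefinition(**raw)
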