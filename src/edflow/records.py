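"""Per-visit ED records: the typed unit of ingestion.

A visit is one row of the input CSV: event times measured in hours since
registration (time zero), exactly one terminal outcome (departure, left
without being seen, or redirect), and registration-time covariates.  Acuity
(ESI, 1 = most urgent) may be revised once at triage, which is what makes it
a time-varying covariate downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Any, Iterable, Optional

import pandas as pd

GENDER_LEVELS = ("Male", "Female")
ETHNICITY_LEVELS = ("Not Hispanic", "Hispanic", "Other", "Unknown")
RACE_LEVELS = ("White", "Black", "Asian", "Other", "Unknown")
ESI_LEVELS = (1, 2, 3, 4, 5)
SEASON_LEVELS = ("Spring", "Summer", "Fall", "Winter")
TIME_OF_DAY_LEVELS = (
    "0:00-4:00",
    "4:00-8:00",
    "8:00-12:00",
    "12:00-16:00",
    "16:00-20:00",
    "20:00-24:00",
)

CATEGORY_LEVELS: dict[str, tuple] = {
    "gender": GENDER_LEVELS,
    "ethnicity": ETHNICITY_LEVELS,
    "race": RACE_LEVELS,
    "esi_initial": ESI_LEVELS,
    "esi_triage": ESI_LEVELS,
    "season": SEASON_LEVELS,
    "time_of_day": TIME_OF_DAY_LEVELS,
}

TIME_FIELDS = (
    "t_triage",
    "t_room",
    "t_contact",
    "t_disposition",
    "t_departure",
    "t_left",
    "t_redirect",
)

#: identity column map: CSV header -> record field
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "visit_id": "visit_id",
    "t_triage": "t_triage",
    "t_room": "t_room",
    "t_contact": "t_contact",
    "t_disposition": "t_disposition",
    "t_departure": "t_departure",
    "t_left": "t_left",
    "t_redirect": "t_redirect",
    "age": "age",
    "gender": "gender",
    "ethnicity": "ethnicity",
    "race": "race",
    "esi_initial": "esi_initial",
    "esi_triage": "esi_triage",
    "season": "season",
    "time_of_day": "time_of_day",
    "n_physicians": "n_physicians",
}


@dataclass
class EDVisitRecord:
    """One validated ED visit; all times in hours since registration."""

    visit_id: Any
    age: float
    gender: str
    ethnicity: str
    race: str
    esi_initial: int
    season: str
    time_of_day: str
    n_physicians: int
    esi_triage: Optional[int] = None
    t_triage: Optional[float] = None
    t_room: Optional[float] = None
    t_contact: Optional[float] = None
    t_disposition: Optional[float] = None
    t_departure: Optional[float] = None
    t_left: Optional[float] = None
    t_redirect: Optional[float] = None

    @property
    def terminal(self) -> str:
        """Which terminal outcome the visit realised: departure/left/redirect."""
        if self.t_departure is not None:
            return "departure"
        if self.t_left is not None:
            return "left"
        return "redirect"

    @property
    def registration_exit_time(self) -> float:
        """Time of the competing exit from Registration (room, left or redirect)."""
        if self.t_left is not None:
            return self.t_left
        if self.t_redirect is not None:
            return self.t_redirect
        assert self.t_room is not None
        return self.t_room

    @property
    def has_acuity_update(self) -> bool:
        return (
            self.esi_triage is not None
            and self.t_triage is not None
            and self.esi_triage != self.esi_initial
        )


def _clean(value: Any) -> Any:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return value


def records_to_frame(records: Iterable[EDVisitRecord]) -> pd.DataFrame:
    """One row per visit, columns named as the record fields."""
    cols = [f.name for f in fields(EDVisitRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


def frame_to_raw_rows(
    frame: pd.DataFrame, column_map: Optional[dict[str, str]] = None
) -> list[dict]:
    """Apply a CSV-header -> field column map and return raw per-visit dicts.

    No validation happens here; `validation.validate_records` owns type and
    consistency checking so that malformed rows become reported exclusions
    rather than crashes.
    """
    cmap = dict(column_map or {})
    if not cmap:
        cmap = {c: c for c in frame.columns if c in DEFAULT_COLUMN_MAP}
    missing = [src for src in cmap if src not in frame.columns]
    if missing:
        raise KeyError(f"input is missing mapped columns: {missing}")
    rows: list[dict] = []
    for _, row in frame.iterrows():
        rows.append({dst: _clean(row[src]) for src, dst in cmap.items()})
    return rows


def read_visits_csv(
    path, column_map: Optional[dict[str, str]] = None
) -> list[dict]:
    """Read a per-visit CSV (RFC-4180, header row) into raw row dicts."""
    frame = pd.read_csv(path)
    return frame_to_raw_rows(frame, column_map)
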