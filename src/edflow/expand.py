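"""Expansion of visit records into counting-process (start, stop, status) rows.

Each visit becomes one row per transition it was at risk for, on the shared
forward clock (hours since registration):

* Out of Registration the three exits (Left, Redirect, Exam Room) compete, so
  a visit contributes one row per exit over the identical span ``(0, exit]``,
  with status 1 only on the realised exit.
* The in-ED path Room -> Contact -> Disposition -> Departure is sequential:
  each row enters at its state-entry time (delayed entry / left truncation).
* An acuity revision at triage splits every Registration row at the triage
  time: ``[0, t_triage)`` carries the initial ESI with status 0 and
  ``[t_triage, exit]`` carries the revised ESI and the row's status.

This is the exact format the per-transition Cox partial likelihood consumes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import pandas as pd

from .records import EDVisitRecord
from .structure import TransitionStructure, ed_structure

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = (
    "age",
    "gender",
    "ethnicity",
    "race",
    "esi",
    "season",
    "time_of_day",
    "n_physicians",
)

LONG_COLUMNS = ("id", "from", "to", "trans", "Tstart", "Tstop", "status") + COVARIATE_COLUMNS


def _base_covariates(rec: EDVisitRecord) -> dict:
    return {
        "age": rec.age,
        "gender": rec.gender,
        "ethnicity": rec.ethnicity,
        "race": rec.race,
        "season": rec.season,
        "time_of_day": rec.time_of_day,
        "n_physicians": rec.n_physicians,
    }


def expand_record(
    rec: EDVisitRecord, structure: Optional[TransitionStructure] = None
) -> list[dict]:
    """Counting-process rows for one visit (see module docstring)."""
    structure = structure or ed_structure()
    exit_time = rec.registration_exit_time
    realised_to = {"left": 2, "redirect": 3, "departure": 4}[rec.terminal]

    update = rec.has_acuity_update
    if update and rec.t_triage >= exit_time:
        logger.warning(
            "visit %s: triage at %g not before exit %g; acuity update ignored",
            rec.visit_id, rec.t_triage, exit_time,
        )
        update = False
    esi_after = rec.esi_triage if update else rec.esi_initial

    base = _base_covariates(rec)
    rows: list[dict] = []

    def add(q: int, r: int, tstart: float, tstop: float, status: int, esi: int) -> None:
        rows.append({
            "id": rec.visit_id,
            "from": q,
            "to": r,
            "trans": structure.transition_id(q, r),
            "Tstart": tstart,
            "Tstop": tstop,
            "status": status,
            "esi": esi,
            **base,
        })

    for r in structure.successors(1):
        status = int(r == realised_to)
        if update:
            add(1, r, 0.0, rec.t_triage, 0, rec.esi_initial)
            add(1, r, rec.t_triage, exit_time, status, esi_after)
        else:
            add(1, r, 0.0, exit_time, status, esi_after)

    if rec.terminal == "departure":
        add(4, 5, rec.t_room, rec.t_contact, 1, esi_after)
        add(5, 6, rec.t_contact, rec.t_disposition, 1, esi_after)
        add(6, 7, rec.t_disposition, rec.t_departure, 1, esi_after)
    return rows


def expand_to_long(
    records: Iterable[EDVisitRecord],
    structure: Optional[TransitionStructure] = None,
) -> pd.DataFrame:
    """Expand validated visits into the long-format transition table.

    Row-count law: a departure-path visit with no acuity update yields 6 rows,
    a Left/Redirect visit 3; an acuity update adds 3 more (the split
    Registration rows).
    """
    structure = structure or ed_structure()
    all_rows: list[dict] = []
    for rec in records:
        all_rows.extend(expand_record(rec, structure))
    frame = pd.DataFrame(all_rows, columns=list(LONG_COLUMNS))
    return frame


def replay_path(
    long_rows: pd.DataFrame, structure: Optional[TransitionStructure] = None
) -> dict:
    """Reconstruct each visit's state sequence from its status-1 rows.

    Returns ``{visit_id: [(state, entry_time), ...]}`` starting from
    (1, 0.0).  Used by round-trip tests: the replayed path must equal the
    original record's observed sequence exactly.
    """
    structure = structure or ed_structure()
    paths: dict = {}
    for vid, grp in long_rows[long_rows["status"] == 1].groupby("id", sort=False):
        grp = grp.sort_values("Tstop")
        path = [(1, 0.0)]
        for _, row in grp.iterrows():
            path.append((int(row["to"]), float(row["Tstop"])))
        paths[vid] = path
    return paths
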