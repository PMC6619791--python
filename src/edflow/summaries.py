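"""Descriptive cohort summaries (demographics table, outcome split, waits)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .records import EDVisitRecord, records_to_frame


@dataclass
class DescriptiveSummary:
    total: int
    outcome_counts: dict[str, int]
    outcome_pct: dict[str, float]
    mean_waits_hours: dict[str, float]  # per realized transition
    frequency_table: pd.DataFrame  # variable / level / count / pct
    age_median_iqr: tuple[float, float, float]
    physicians_median_iqr: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "outcome_counts": self.outcome_counts,
            "outcome_pct": self.outcome_pct,
            "mean_waits_hours": self.mean_waits_hours,
            "age_median_iqr": list(self.age_median_iqr),
            "physicians_median_iqr": list(self.physicians_median_iqr),
            "frequency_table": self.frequency_table.to_dict(orient="records"),
        }


def _median_iqr(x: pd.Series) -> tuple[float, float, float]:
    q25, q50, q75 = np.percentile(x.astype(float), [25, 50, 75])  # linear interp
    return float(q50), float(q25), float(q75)


def summarize_dataset(records: Iterable[EDVisitRecord]) -> DescriptiveSummary:
    """Outcome counts, mean observed waits and a demographics frequency table.

    Mean waits are computed among the visits that realized each transition
    (e.g. registration->room only among visits that reached a room).
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    frame = records_to_frame(records)
    total = len(frame)

    terminals = pd.Series([r.terminal for r in records])
    counts = terminals.value_counts().to_dict()
    outcome_counts = {k: int(counts.get(k, 0)) for k in ("departure", "left", "redirect")}
    outcome_pct = {k: 100.0 * v / total for k, v in outcome_counts.items()}

    waits = {
        "registration_to_room": frame["t_room"],
        "room_to_contact": frame["t_contact"] - frame["t_room"],
        "contact_to_disposition": frame["t_disposition"] - frame["t_contact"],
        "disposition_to_departure": frame["t_departure"] - frame["t_disposition"],
    }
    mean_waits = {k: float(v.dropna().mean()) for k, v in waits.items()}

    rows = []
    for col in ("gender", "ethnicity", "race", "esi_initial", "season", "time_of_day"):
        vc = frame[col].value_counts()
        for level, count in vc.items():
            rows.append({
                "variable": col, "level": level, "count": int(count),
                "pct": round(100.0 * count / total, 1),
            })
    freq = pd.DataFrame(rows)

    return DescriptiveSummary(
        total=total,
        outcome_counts=outcome_counts,
        outcome_pct=outcome_pct,
        mean_waits_hours=mean_waits,
        frequency_table=freq,
        age_median_iqr=_median_iqr(frame["age"]),
        physicians_median_iqr=_median_iqr(frame["n_physicians"]),
    )
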