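"""Covariate coding for the per-transition Cox models.

Categorical covariates are indicator-coded against fixed reference levels
(Male, Not Hispanic, White, ESI 1, Spring, 0:00-4:00); age and the number of
ED physicians on staff enter linearly.  A level with zero observed events on
a given transition makes its contrast non-estimable (the partial likelihood
is monotone in that coefficient), so such levels are merged into the baseline
group — or into the level the merge map designates — with a logged notice.
The canonical instance: no ESI-1 patient ever leaves without being seen or is
redirected, so ESI levels 1 and 2 form the baseline group on those two
transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import pandas as pd

from .records import (
    ESI_LEVELS,
    ETHNICITY_LEVELS,
    GENDER_LEVELS,
    RACE_LEVELS,
    SEASON_LEVELS,
    TIME_OF_DAY_LEVELS,
)

logger = logging.getLogger(__name__)

CATEGORICAL_LEVELS: dict[str, tuple] = {
    "gender": GENDER_LEVELS,
    "ethnicity": ETHNICITY_LEVELS,
    "race": RACE_LEVELS,
    "esi": ESI_LEVELS,
    "season": SEASON_LEVELS,
    "time_of_day": TIME_OF_DAY_LEVELS,
}

DEFAULT_REFERENCES: dict[str, Any] = {
    "gender": "Male",
    "ethnicity": "Not Hispanic",
    "race": "White",
    "esi": 1,
    "season": "Spring",
    "time_of_day": "0:00-4:00",
}

CONTINUOUS_COLUMNS = ("age", "n_physicians")

# covariate ordering used in reported tables
COLUMN_ORDER = ("age", "gender", "ethnicity", "race", "esi", "season",
                "time_of_day", "n_physicians")


@dataclass
class CodingScheme:
    """Names every categorical level, its reference, and zero-event merges."""

    references: dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_REFERENCES))
    levels: dict[str, tuple] = field(default_factory=lambda: dict(CATEGORICAL_LEVELS))
    continuous: tuple = CONTINUOUS_COLUMNS
    #: where a zero-event level merges; fallback is the reference level
    merge_map: dict[str, dict[Any, Any]] = field(
        default_factory=lambda: {"esi": {1: 2}}
    )
    auto_merge_zero_events: bool = True
    columns: tuple = COLUMN_ORDER

    def __post_init__(self) -> None:
        for col, ref in self.references.items():
            if ref not in self.levels[col]:
                raise ValueError(f"reference {ref!r} not a level of {col!r}")


@dataclass
class Encoding:
    """Frozen result of applying a CodingScheme to one transition's rows.

    Knows how to encode both long-format rows and prediction profiles, so the
    design applied at fit time and at prediction time is guaranteed identical.
    """

    design_columns: list[str]
    continuous: list[str]
    #: categorical column -> {level: design column or None (baseline group)}
    level_maps: dict[str, dict[Any, Optional[str]]]
    merges: list[tuple[str, Any, Any]] = field(default_factory=list)

    def _encode_value(self, out: np.ndarray, col_idx: dict[str, int],
                      col: str, value: Any, rows: Any) -> None:
        mapping = self.level_maps[col]
        if value not in mapping:
            raise ValueError(f"unseen level {value!r} in column {col!r}")
        name = mapping[value]
        if name is not None:
            out[rows, col_idx[name]] = 1.0

    def encode_frame(self, frame: pd.DataFrame) -> np.ndarray:
        """Design matrix (n, p) for long-format rows."""
        n = len(frame)
        out = np.zeros((n, len(self.design_columns)))
        idx = {c: j for j, c in enumerate(self.design_columns)}
        for col in self.continuous:
            out[:, idx[col]] = frame[col].to_numpy(dtype=float)
        for col, mapping in self.level_maps.items():
            values = frame[col]
            unseen = set(values.unique()) - set(mapping)
            if unseen:
                raise ValueError(
                    f"unseen level {sorted(unseen, key=repr)[0]!r} in column {col!r}"
                )
            for level, name in mapping.items():
                if name is not None:
                    out[values.to_numpy() == level, idx[name]] = 1.0
        return out

    def encode_profile(self, profile: dict[str, Any]) -> np.ndarray:
        """Design vector (p,) for a covariate profile dict."""
        out = np.zeros(len(self.design_columns))
        idx = {c: j for j, c in enumerate(self.design_columns)}
        for col in self.continuous:
            if col not in profile:
                raise ValueError(f"profile missing covariate {col!r}")
            out[idx[col]] = float(profile[col])
        for col, mapping in self.level_maps.items():
            if col not in profile:
                raise ValueError(f"profile missing covariate {col!r}")
            value = profile[col]
            if value not in mapping:
                raise ValueError(f"unseen level {value!r} in column {col!r}")
            name = mapping[value]
            if name is not None:
                out[idx[name]] = 1.0
        return out


def build_encoding(
    rows: pd.DataFrame, scheme: Optional[CodingScheme] = None
) -> Encoding:
    """Decide the design for one transition's rows (including merges).

    Zero-event detection uses the rows' ``status`` column; if absent, no
    automatic merging is performed.
    """
    scheme = scheme or CodingScheme()
    has_status = "status" in rows.columns and scheme.auto_merge_zero_events

    design_columns: list[str] = []
    level_maps: dict[str, dict[Any, Optional[str]]] = {}
    merges: list[tuple[str, Any, Any]] = []
    continuous = [c for c in scheme.columns if c in scheme.continuous]

    for col in scheme.columns:
        if col in scheme.continuous:
            design_columns.append(col)
            continue
        levels = scheme.levels[col]
        ref = scheme.references[col]
        rep = {lv: lv for lv in levels}
        if has_status:
            events = rows.loc[rows["status"] == 1, col].value_counts().to_dict()
            for lv in levels:
                if events.get(lv, 0) == 0:
                    target = scheme.merge_map.get(col, {}).get(lv, ref)
                    if target != lv:
                        rep[lv] = target
                        merges.append((col, lv, target))
                        logger.info(
                            "column %r: level %r has zero events; merged into %r",
                            col, lv, target,
                        )
            # resolve merge chains; a cycle collapses into the baseline
            def _resolve(lv):
                seen = []
                while rep[lv] != lv and lv not in seen:
                    seen.append(lv)
                    lv = rep[lv]
                return ref if lv in seen else lv

            rep = {lv: _resolve(lv) for lv in levels}
        baseline_rep = rep[ref]
        mapping: dict[Any, Optional[str]] = {}
        for lv in levels:
            r = rep[lv]
            mapping[lv] = None if r == baseline_rep else f"{col}={r}"
        for lv in levels:  # preserve level order, no duplicates
            name = mapping[lv]
            if name is not None and name not in design_columns:
                design_columns.append(name)
        level_maps[col] = mapping

    return Encoding(
        design_columns=design_columns,
        continuous=continuous,
        level_maps=level_maps,
        merges=merges,
    )


def encode_covariates(
    rows: pd.DataFrame, scheme: Optional[CodingScheme] = None
) -> tuple[pd.DataFrame, Encoding]:
    """Attach numeric design vectors to one transition's counting-process rows.

    Returns the design as a DataFrame (aligned with ``rows``) plus the
    :class:`Encoding` needed to encode prediction profiles consistently.
    """
    encoding = build_encoding(rows, scheme)
    X = encoding.encode_frame(rows)
    design = pd.DataFrame(X, columns=encoding.design_columns, index=rows.index)
    return design, encoding
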