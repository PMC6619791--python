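"""Record validation and filtering.

The source data contain visits with inaccurate or invalid transition times
(e.g. a discharge stamped before first physician contact).  Because the exact
rule set used to clean the original cohort is not public, every rule here is
explicit, individually counted, and reported per excluded visit, so a run can
always account for the difference between input and retained counts.

Rules
-----
unparseable            a time/number field that cannot be coerced
unknown category       a categorical value outside the configured levels
missing covariate      complete-case requirement on model covariates
no terminal outcome    none of departure/left/redirect present
multiple terminal outcomes
incomplete departure path   departure present but room/contact/disposition absent
extraneous downstream times left/redirect visits carrying in-room timestamps
nonpositive time       an event stamped at or before registration (strict mode;
                       default policy epsilon-shifts exact ties instead)
non-monotone times     a later stage stamped strictly before an earlier one
tied times             zero-length stage (strict mode only; default shifts)

Ties: the default policy shifts the later of two equal timestamps forward by
``epsilon`` hours (default 1e-6) with a warning, because only reversed
orderings are unambiguously invalid; ``tie_policy="strict"`` excludes instead.
A triage time stamped after the exit from Registration cannot carry an acuity
update; the update is dropped with a warning and the visit retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

from .records import (
    CATEGORY_LEVELS,
    EDVisitRecord,
    ESI_LEVELS,
)

logger = logging.getLogger(__name__)


@dataclass
class ValidationConfig:
    tie_policy: str = "shift"  # "shift" | "strict"
    epsilon: float = 1e-6  # hours; tie-breaking shift
    require_complete_covariates: bool = True

    def __post_init__(self) -> None:
        if self.tie_policy not in ("shift", "strict"):
            raise ValueError("tie_policy must be 'shift' or 'strict'")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class ValidationReport:
    n_input: int = 0
    n_retained: int = 0
    n_excluded: int = 0
    rule_counts: dict[str, int] = field(default_factory=dict)
    exclusions: list[tuple[Any, list[str]]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add_exclusion(self, visit_id: Any, reasons: list[str]) -> None:
        self.exclusions.append((visit_id, reasons))
        self.n_excluded += 1
        for r in reasons:
            self.rule_counts[r] = self.rule_counts.get(r, 0) + 1

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "rule_counts": dict(self.rule_counts),
            "exclusions": [
                {"visit_id": vid, "reasons": reasons} for vid, reasons in self.exclusions
            ],
            "warnings": list(self.warnings),
        }


_COVARIATE_FIELDS = (
    "age",
    "gender",
    "ethnicity",
    "race",
    "esi_initial",
    "season",
    "time_of_day",
    "n_physicians",
)

# ordered in-ED path; ties are resolved left to right
_PATH_FIELDS = ("t_room", "t_contact", "t_disposition", "t_departure")


def _coerce_float(value: Any) -> Optional[float]:
    if value is None:
        return None
    return float(value)


def _coerce_esi(value: Any) -> Optional[int]:
    if value is None:
        return None
    iv = int(float(value))
    if iv != float(value) or iv not in ESI_LEVELS:
        raise ValueError(f"ESI level {value!r} not in 1..5")
    return iv


def _check_one(raw: dict, config: ValidationConfig, report: ValidationReport):
    """Return (record or None, list of reasons)."""
    reasons: list[str] = []
    vid = raw.get("visit_id")

    # -- type coercion -------------------------------------------------
    times: dict[str, Optional[float]] = {}
    for f in ("t_triage", "t_room", "t_contact", "t_disposition", "t_departure",
              "t_left", "t_redirect"):
        try:
            times[f] = _coerce_float(raw.get(f))
        except (TypeError, ValueError):
            reasons.append("unparseable")
            times[f] = None

    cov: dict[str, Any] = {}
    for f in ("age", "n_physicians"):
        try:
            v = raw.get(f)
            cov[f] = None if v is None else float(v)
            if cov[f] is not None and cov[f] < 0:
                reasons.append("unparseable")
        except (TypeError, ValueError):
            reasons.append("unparseable")
            cov[f] = None
    for f in ("gender", "ethnicity", "race", "season", "time_of_day"):
        v = raw.get(f)
        if v is not None and v not in CATEGORY_LEVELS[f]:
            reasons.append("unknown category")
            v = None
        cov[f] = v
    for f in ("esi_initial", "esi_triage"):
        try:
            cov[f] = _coerce_esi(raw.get(f))
        except (TypeError, ValueError):
            reasons.append("unknown category")
            cov[f] = None

    # -- completeness --------------------------------------------------
    if config.require_complete_covariates:
        missing = [f for f in _COVARIATE_FIELDS if cov.get(f) is None]
        if missing:
            reasons.append("missing covariate")

    terminals = [f for f in ("t_departure", "t_left", "t_redirect") if times[f] is not None]
    if len(terminals) == 0:
        reasons.append("no terminal outcome")
    elif len(terminals) > 1:
        reasons.append("multiple terminal outcomes")

    if times["t_departure"] is not None:
        if any(times[f] is None for f in ("t_room", "t_contact", "t_disposition")):
            reasons.append("incomplete departure path")
    elif len(terminals) == 1:
        if any(times[f] is not None for f in _PATH_FIELDS[:-1]):
            reasons.append("extraneous downstream times")

    if reasons:
        return None, sorted(set(reasons))

    # -- time ordering -------------------------------------------------
    if times["t_departure"] is not None:
        seq = [times[f] for f in _PATH_FIELDS]
    else:
        seq = [times[terminals[0]]]

    prev = 0.0
    fixed: list[float] = []
    for t in seq:
        if t < prev:
            reasons.append("non-monotone times")
            break
        if t == prev:
            if config.tie_policy == "strict":
                reasons.append("nonpositive time" if prev == 0.0 else "tied times")
                break
            t = prev + config.epsilon
            report.warnings.append(
                f"visit {vid}: tied timestamps shifted by epsilon={config.epsilon}"
            )
        fixed.append(t)
        prev = t
    if reasons:
        return None, sorted(set(reasons))

    if times["t_departure"] is not None:
        for f, t in zip(_PATH_FIELDS, fixed):
            times[f] = t
        exit_time = times["t_room"]
    else:
        times[terminals[0]] = fixed[0]
        exit_time = fixed[0]

    # -- triage plausibility (warn, don't exclude) ----------------------
    t_triage, esi_triage = times["t_triage"], cov["esi_triage"]
    if t_triage is not None and (t_triage <= 0 or t_triage > exit_time):
        report.warnings.append(
            f"visit {vid}: triage time {t_triage} outside (0, exit={exit_time:g}]; "
            "acuity update dropped"
        )
        t_triage, esi_triage = None, None

    record = EDVisitRecord(
        visit_id=vid,
        age=cov["age"],
        gender=cov["gender"],
        ethnicity=cov["ethnicity"],
        race=cov["race"],
        esi_initial=cov["esi_initial"],
        season=cov["season"],
        time_of_day=cov["time_of_day"],
        n_physicians=cov["n_physicians"],
        esi_triage=esi_triage,
        t_triage=t_triage,
        t_room=times["t_room"],
        t_contact=times["t_contact"],
        t_disposition=times["t_disposition"],
        t_departure=times["t_departure"],
        t_left=times["t_left"],
        t_redirect=times["t_redirect"],
    )
    return record, []


def validate_records(
    raw_rows: Iterable[dict], config: Optional[ValidationConfig] = None
) -> tuple[list[EDVisitRecord], ValidationReport]:
    """Validate raw per-visit rows; never crashes on a malformed record.

    Returns the retained :class:`EDVisitRecord` list and a
    :class:`ValidationReport` enumerating every exclusion with its rule(s).
    Raises ``ValueError`` on empty input.
    """
    rows = list(raw_rows)
    if not rows:
        raise ValueError("no records")
    config = config or ValidationConfig()
    report = ValidationReport(n_input=len(rows))
    retained: list[EDVisitRecord] = []
    for raw in rows:
        record, reasons = _check_one(raw, config, report)
        if record is None:
            report.add_exclusion(raw.get("visit_id"), reasons)
        else:
            retained.append(record)
    report.n_retained = len(retained)
    if report.n_excluded:
        logger.info(
            "validation: retained %d of %d visits (%d excluded)",
            report.n_retained, report.n_input, report.n_excluded,
        )
    return retained, report
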