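import numpy as np
import pandas as pd
import pytest

from edflow.expand import expand_record, expand_to_long, replay_path
from edflow.records import EDVisitRecord


def _record(**kwargs):
    base = dict(visit_id="v1", age=5.0, gender="Male", ethnicity="Not Hispanic",
                race="White", esi_initial=3, season="Winter",
                time_of_day="8:00-12:00", n_physicians=6)
    base.update(kwargs)
    return EDVisitRecord(**base)


def test_departure_path_hand_expansion():
    rec = _record(t_room=0.8, t_contact=1.2, t_disposition=2.0, t_departure=2.5)
    rows = pd.DataFrame(expand_record(rec))
    assert len(rows) == 6
    expected = [
        (1, 2, 0.0, 0.8, 0),
        (1, 3, 0.0, 0.8, 0),
        (1, 4, 0.0, 0.8, 1),
        (4, 5, 0.8, 1.2, 1),
        (5, 6, 1.2, 2.0, 1),
        (6, 7, 2.0, 2.5, 1),
    ]
    got = list(zip(rows["from"], rows["to"], rows["Tstart"], rows["Tstop"],
                   rows["status"]))
    assert got == expected


def test_left_visit_single_realized_competing_risk():
    rows = pd.DataFrame(expand_record(_record(t_left=0.5)))
    assert len(rows) == 3
    assert rows.loc[rows["status"] == 1, "to"].tolist() == [2]
    assert (rows["Tstart"] == 0.0).all() and (rows["Tstop"] == 0.5).all()


def test_acuity_update_splits_registration_rows():
    rec = _record(esi_initial=4, esi_triage=2, t_triage=0.25, t_room=0.8,
                  t_contact=1.2, t_disposition=2.0, t_departure=2.5)
    rows = pd.DataFrame(expand_record(rec))
    assert len(rows) == 9  # 6 state-1 rows (split) + 3 downstream
    state1 = rows[rows["from"] == 1]
    first = state1[state1["Tstart"] == 0.0]
    second = state1[state1["Tstart"] == 0.25]
    assert (first["Tstop"] == 0.25).all() and (first["esi"] == 4).all()
    assert (first["status"] == 0).all()
    assert (second["Tstop"] == 0.8).all() and (second["esi"] == 2).all()
    assert second.loc[second["to"] == 4, "status"].tolist() == [1]
    # downstream rows carry the revised acuity
    assert (rows[rows["from"] > 1]["esi"] == 2).all()


def test_triage_at_exit_ignores_update():
    rec = _record(t_left=0.5, esi_triage=1, t_triage=0.5)
    rows = pd.DataFrame(expand_record(rec))
    assert len(rows) == 3
    assert (rows["esi"] == 3).all()


def test_row_count_law(cohort):
    long = expand_to_long(cohort)
    counts = long.groupby("id").size()
    for rec in cohort:
        expected = 6 if rec.terminal == "departure" else 3
        if rec.has_acuity_update:
            expected += 3
        assert counts[rec.visit_id] == expected


def test_competing_rows_share_spans_and_single_event(cohort):
    long = expand_to_long(cohort)
    state1 = long[long["from"] == 1]
    spans = state1.groupby(["id", "Tstart"])["Tstop"].nunique()
    assert (spans == 1).all()
    per_trans = long[long["status"] == 1].groupby(["id", "trans"]).size()
    assert (per_trans == 1).all()


def test_round_trip_replay_reconstructs_paths(cohort):
    long = expand_to_long(cohort)
    paths = replay_path(long)
    for rec in cohort:
        path = paths[rec.visit_id]
        if rec.terminal == "departure":
            expected = [(1, 0.0), (4, rec.t_room), (5, rec.t_contact),
                        (6, rec.t_disposition), (7, rec.t_departure)]
        elif rec.terminal == "left":
            expected = [(1, 0.0), (2, rec.t_left)]
        else:
            expected = [(1, 0.0), (3, rec.t_redirect)]
        assert path == expected


def test_tstart_positive_only_after_acuity_split_or_delayed_entry(cohort):
    long = expand_to_long(cohort)
    state1 = long[long["from"] == 1]
    with_split = state1[state1["Tstart"] > 0]
    # split rows only occur for visits with an acuity revision
    updated = {r.visit_id for r in cohort if r.has_acuity_update}
    assert set(with_split["id"]) <= updated
    seq = long[long["from"] > 1]
    assert (seq["Tstart"] > 0).all()
    assert (long["Tstart"] < long["Tstop"]).all()
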