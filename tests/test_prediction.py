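import numpy as np
import pandas as pd
import pytest

from edflow.prediction import (
    CumulativeHazardSet,
    aalen_johansen,
    expected_sojourn,
    predict_cumulative_hazards,
)
from edflow.structure import TransitionStructure, ed_structure


def _two_state(inc_by_time: dict[float, float]) -> CumulativeHazardSet:
    st = TransitionStructure(states=(1, 2), transitions=((1, 2),),
                             labels={1: "a", 2: "b"})
    grid = np.array(sorted(inc_by_time))
    inc = {1: np.array([inc_by_time[t] for t in grid])}
    return CumulativeHazardSet(grid=grid, increments=inc, structure=st)


def test_empty_interval_gives_identity():
    ch = _two_state({1.0: 0.5})
    cur = aalen_johansen(ch, s=2.0)  # no events after s
    assert len(cur.grid) == 1
    np.testing.assert_array_equal(cur.P[0], np.eye(2))


def test_hand_product_integral_two_competing_exits():
    st = ed_structure()
    grid = np.array([1.0, 2.0])
    inc = {k: np.zeros(2) for k in range(1, 7)}
    inc[1][0] = 0.5  # 1->2 at t=1, increment 1/2
    inc[3][1] = 1.0  # 1->4 at t=2, increment 1/1
    cur = aalen_johansen(CumulativeHazardSet(grid, inc, st))
    P = cur.P[-1]
    assert P[0, 0] == pytest.approx(0.0)
    assert P[0, 1] == pytest.approx(0.5)
    assert P[0, 3] == pytest.approx(0.5)


def test_kaplan_meier_reduction():
    ch = _two_state({1.0: 1 / 3, 2.0: 1 / 2, 3.0: 1.0})
    cur = aalen_johansen(ch)
    idx = np.searchsorted(cur.grid, 2.5, side="right") - 1
    assert cur.P[idx][0, 0] == pytest.approx((1 - 1 / 3) * (1 - 1 / 2))


def test_row_sums_and_range(fitted_model, reference_profile):
    cur = fitted_model.predict_occupation(reference_profile)
    np.testing.assert_allclose(cur.P.sum(axis=2), 1.0, atol=1e-10)
    assert (cur.P >= -1e-12).all() and (cur.P <= 1 + 1e-12).all()


def test_chapman_kolmogorov_exact_on_grid(fitted_model, reference_profile):
    ch = fitted_model.predict_cumulative_hazard(reference_profile)
    full = aalen_johansen(ch, s=0.0, increment_policy="clip")
    u = float(full.grid[len(full.grid) // 2])
    t_idx = 3 * len(full.grid) // 4
    t = float(full.grid[t_idx])
    second = aalen_johansen(ch, s=u, increment_policy="clip")
    j = np.searchsorted(second.grid, t)
    u_idx = np.searchsorted(full.grid, u)
    np.testing.assert_allclose(
        full.P[u_idx] @ second.P[j], full.P[t_idx], atol=1e-12)


def test_terminal_states_monotone_and_stacked_curves(fitted_model, reference_profile):
    cur = fitted_model.predict_occupation(reference_profile)
    sidx = {s: i for i, s in enumerate(cur.structure.states)}
    for terminal in (2, 3, 7):
        occ = cur.occupation[:, sidx[terminal]]
        assert np.all(np.diff(occ) >= -1e-12)
    stacked = np.cumsum(cur.occupation, axis=1)
    assert np.all(np.diff(stacked, axis=1) >= -1e-12)


def test_reference_profile_recovers_baseline(fitted_model):
    ref = {"age": 0, "gender": "Male", "ethnicity": "Not Hispanic",
           "race": "White", "time_of_day": "0:00-4:00", "season": "Spring",
           "n_physicians": 0, "esi": 1}
    ch = fitted_model.predict_cumulative_hazard(ref)
    for k, fit in fitted_model.fits_.items():
        np.testing.assert_allclose(
            ch.cumulative(k)[-1], fit.baseline.values[-1], rtol=1e-10)


def test_constant_log_hr_scales_every_increment(fitted_model, reference_profile):
    """A profile whose linear predictor is ln 2 higher doubles each increment."""
    ch1 = fitted_model.predict_cumulative_hazard(reference_profile)
    fit = fitted_model.fits_[3]
    j = fit.coef_names.index("age")
    bumped = dict(reference_profile)
    bumped["age"] = reference_profile["age"] + np.log(2) / fit.beta[j]
    ch2 = fitted_model.predict_cumulative_hazard(bumped)
    np.testing.assert_allclose(ch2.increments[3], 2 * ch1.increments[3], rtol=1e-9)


def test_piecewise_profile_hand_summed(fitted_model):
    """Piecewise profile: increments before the switch use segment 1, after
    use segment 2; totals match the hand-scaled baseline sums."""
    base = {"age": 0, "gender": "Male", "ethnicity": "Not Hispanic",
            "race": "White", "time_of_day": "0:00-4:00", "season": "Spring",
            "n_physicians": 0, "esi": 1}
    seg2 = dict(base, esi=2)
    profile = [(0.0, base), (0.25, seg2)]
    ch = fitted_model.predict_cumulative_hazard(profile)
    fit = fitted_model.fits_[3]
    hr2 = np.exp(fit.beta[fit.coef_names.index("esi=2")])
    expect = np.where(fit.baseline_times < 0.25, 1.0, hr2) * fit.baseline_increments
    got = ch.increments[3][ch.increments[3] > 0]
    np.testing.assert_allclose(np.sort(got), np.sort(expect), rtol=1e-10)


def test_invalid_increment_errors_by_default():
    ch = _two_state({1.0: 1.2})
    with pytest.raises(ValueError, match="invalid hazard increment"):
        aalen_johansen(ch)
    cur = aalen_johansen(ch, increment_policy="clip")
    assert cur.P[-1][0, 0] == pytest.approx(0.0)


def test_missing_profile_covariate_names_it(fitted_model, reference_profile):
    prof = {k: v for k, v in reference_profile.items() if k != "race"}
    with pytest.raises(ValueError, match="race"):
        fitted_model.predict_cumulative_hazard(prof)


def test_sojourn_in_never_left_state_equals_tau():
    ch = _two_state({1.0: 0.0})  # zero increment: nothing ever happens
    cur = aalen_johansen(ch)
    soj = expected_sojourn(cur, tau=4.0)
    assert soj.loc[soj["state"] == 1, "sojourn_hours"].iloc[0] == pytest.approx(4.0)


def test_sojourn_sums_to_tau(fitted_model, reference_profile):
    cur = fitted_model.predict_occupation(reference_profile)
    tau = float(cur.grid[-1])
    soj = expected_sojourn(cur, tau=tau)
    assert soj["sojourn_hours"].sum() == pytest.approx(tau, abs=1e-8)
    np.testing.assert_allclose(soj["sojourn_minutes"], soj["sojourn_hours"] * 60)


def test_sojourn_constant_hazard_closed_form():
    """Single exit at constant rate lambda=2/h: mean time in state 1 is 1/2 h."""
    rng = np.random.default_rng(0)
    n = 200_000
    t = np.sort(rng.exponential(1 / 2.0, n))
    # nonparametric increments d/riskset on exact event times
    inc = 1.0 / np.arange(n, 0, -1)
    st = TransitionStructure(states=(1, 2), transitions=((1, 2),),
                             labels={1: "a", 2: "b"})
    ch = CumulativeHazardSet(grid=t, increments={1: inc}, structure=st)
    cur = aalen_johansen(ch)
    soj = expected_sojourn(cur, tau=float(t[-1]))
    assert soj["sojourn_hours"].iloc[0] == pytest.approx(0.5, rel=0.02)


def test_tau_validation(fitted_model, reference_profile):
    cur = fitted_model.predict_occupation(reference_profile)
    with pytest.raises(ValueError):
        expected_sojourn(cur, tau=0.0)
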