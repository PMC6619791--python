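import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from edflow.cox import (
    StepFunction,
    baseline_cumulative_hazard,
    cox_newton,
    fit_transition_cox,
    summarize_hazard_ratios,
)


def _fit_simple(df, **kw):
    cols = [c for c in df.columns if c not in ("Tstart", "Tstop", "status")]
    return fit_transition_cox(df, design=df[cols], transition_id=1, **kw)


def _three_subject_rows():
    # subjects (z=1, event t=1), (z=0, event t=2), (z=1, event t=3)
    return pd.DataFrame({
        "Tstart": 0.0, "Tstop": [1.0, 2.0, 3.0], "status": 1,
        "z": [1.0, 0.0, 1.0],
    })


def _brute_force_loglik(beta, z, order):
    """Explicit partial likelihood for untied single-event-per-time data."""
    ll = 0.0
    at_risk = list(range(len(z)))
    for i in order:
        ll += beta * z[i] - np.log(sum(np.exp(beta * z[j]) for j in at_risk))
        at_risk.remove(i)
    return ll


def test_three_subject_analytic_root_matches_grid_oracle():
    df = _three_subject_rows()
    fit = _fit_simple(df)
    # independent oracle: golden-section maximization of the written-out likelihood
    z, order = df["z"].tolist(), [0, 1, 2]
    oracle = optimize.minimize_scalar(
        lambda b: -_brute_force_loglik(b, z, order), bounds=(-5, 5), method="bounded",
        options={"xatol": 1e-10},
    ).x
    assert fit.beta[0] == pytest.approx(-np.log(2) / 2, abs=1e-6)
    assert fit.beta[0] == pytest.approx(oracle, abs=1e-6)
    assert fit.loglik >= fit.loglik0


def test_small_n_brute_force_property():
    rng = np.random.default_rng(3)
    for _ in range(5):
        n = 6
        z = rng.normal(size=n)
        t = np.sort(rng.exponential(size=n))  # distinct with prob 1
        df = pd.DataFrame({"Tstart": 0.0, "Tstop": t, "status": 1, "z": z})
        fit = _fit_simple(df)
        order = np.argsort(t).tolist()
        oracle = optimize.minimize_scalar(
            lambda b: -_brute_force_loglik(b, z.tolist(), order),
            bounds=(-8, 8), method="bounded", options={"xatol": 1e-10},
        ).x
        assert fit.beta[0] == pytest.approx(oracle, abs=1e-6)


def test_efron_equals_breslow_without_ties():
    rng = np.random.default_rng(1)
    n = 200
    z = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.4 * z))
    df = pd.DataFrame({"Tstart": 0.0, "Tstop": t, "status": 1, "z": z})
    fe = _fit_simple(df, ties="efron")
    fb = _fit_simple(df, ties="breslow")
    assert abs(fe.beta[0] - fb.beta[0]) < 1e-10
    assert fe.loglik == pytest.approx(fb.loglik, abs=1e-9)


def test_matches_established_implementation_on_identical_rows():
    """n=5000 two-group exponential rows, true log-HR = ln 2."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(99)
    n = 5000
    z = rng.integers(0, 2, n).astype(float)
    t0 = rng.uniform(0, 0.3, n)
    t = t0 + rng.exponential(np.exp(-np.log(2) * z))
    df = pd.DataFrame({"Tstart": t0, "Tstop": np.round(t, 2), "status": 1, "z": z})
    df = df[df["Tstop"] > df["Tstart"]]
    fit = _fit_simple(df)
    assert fit.beta[0] == pytest.approx(np.log(2), abs=0.1)

    ctv = lifelines.CoxTimeVaryingFitter()
    ll_df = df.rename(columns={"Tstart": "start", "Tstop": "stop", "status": "event"})
    ll_df["id"] = np.arange(len(ll_df))
    ctv.fit(ll_df, id_col="id", start_col="start", stop_col="stop", event_col="event")
    assert fit.beta[0] == pytest.approx(ctv.params_.iloc[0], abs=1e-6)
    assert fit.standard_errors[0] == pytest.approx(
        ctv.standard_errors_.iloc[0], rel=1e-5)


def test_delayed_entry_shift_invariance():
    rng = np.random.default_rng(5)
    n = 300
    z = rng.normal(size=n)
    t0 = rng.uniform(0, 1, n)
    t = t0 + rng.exponential(np.exp(-0.5 * z))
    df = pd.DataFrame({"Tstart": t0, "Tstop": t, "status": 1, "z": z})
    shifted = df.copy()
    shifted[["Tstart", "Tstop"]] += 7.5
    f1, f2 = _fit_simple(df), _fit_simple(shifted)
    assert f1.beta[0] == pytest.approx(f2.beta[0], abs=1e-9)


def test_error_cases():
    df = _three_subject_rows()
    with pytest.raises(ValueError, match="no events"):
        _fit_simple(df.assign(status=0))
    with pytest.raises(ValueError, match="non-identifiable.*'z'"):
        _fit_simple(df.assign(z=1.0))
    df2 = df.assign(z2=lambda d: 2 * d["z"])
    with pytest.raises(ValueError, match="non-identifiable"):
        _fit_simple(df2)


def test_hazard_ratio_table_arithmetic():
    fit = _fit_simple(_three_subject_rows())
    fit.beta = np.array([np.log(2)])
    fit.cov = np.array([[0.01]])
    table = summarize_hazard_ratios(fit)
    row = table.iloc[0]
    assert row["HR"] == pytest.approx(2.000, abs=1e-3)
    assert row["ci_low"] == pytest.approx(1.644, abs=1e-3)
    assert row["ci_high"] == pytest.approx(2.433, abs=1e-3)

    fit.beta = np.array([0.0])
    null_row = summarize_hazard_ratios(fit).iloc[0]
    assert null_row["HR"] == 1.0
    assert null_row["ci_low"] < 1.0 < null_row["ci_high"]


def test_baseline_reduces_to_nelson_aalen_at_beta_zero():
    # no covariates: events at t=1,2,3 among 3 subjects
    res = cox_newton(np.zeros((3, 0)), np.zeros(3), np.array([1.0, 2.0, 3.0]),
                     np.ones(3, dtype=int))
    L = StepFunction(res["baseline"][0], np.cumsum(res["baseline"][1]))
    assert L(2.5) == pytest.approx(1 / 3 + 1 / 2)
    assert L(0.5) == 0.0  # zero before the first event


def test_baseline_step_function_properties():
    rng = np.random.default_rng(8)
    n = 100
    z = rng.normal(size=n)
    df = pd.DataFrame({"Tstart": 0.0, "Tstop": rng.exponential(size=n),
                       "status": 1, "z": z})
    fit = _fit_simple(df)
    recomputed = baseline_cumulative_hazard(fit, df, design=df[["z"]])
    assert np.all(np.diff(recomputed.values) >= 0)
    np.testing.assert_allclose(recomputed.values, fit.baseline.values, rtol=1e-12)
    assert recomputed(df["Tstop"].min() / 2) == 0.0


def test_covariance_symmetric_psd(fitted_model):
    for fit in fitted_model.fits_.values():
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-12)
        eig = np.linalg.eigvalsh(fit.cov)
        assert eig.min() > -1e-10
        assert fit.loglik >= fit.loglik0


def test_wald_ci_coverage():
    """95% CI covers the true log-HR in 95% +/- 3% of simulated datasets."""
    rng = np.random.default_rng(2024)
    beta_true = 0.7
    covered = 0
    R = 500
    for _ in range(R):
        n = 150
        z = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(np.exp(-beta_true * z))
        df = pd.DataFrame({"Tstart": 0.0, "Tstop": t, "status": 1, "z": z})
        fit = _fit_simple(df)
        half = 1.959963984540054 * fit.standard_errors[0]
        covered += abs(fit.beta[0] - beta_true) <= half
    assert covered / R == pytest.approx(0.95, abs=0.03)
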