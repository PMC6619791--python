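import numpy as np
import pandas as pd
import pytest

from edflow.expand import expand_to_long
from edflow.oracle import constant_hazard_oracle, generator_matrix, transition_rates
from edflow.records import records_to_frame
from edflow.simulate import BaselineSpec, SimulationConfig, sample_cohort


def _no_effect_config(n=1000, seed=0, rates=(0.1, 0.02, 0.88, 2.0, 1.0, 1.0)):
    return SimulationConfig(
        n=n, seed=seed,
        baselines={k: BaselineSpec("constant", rate=r)
                   for k, r in zip(range(1, 7), rates)},
        coefficients={},
        p_acuity_update=0.0,
    )


def test_same_config_same_seed_identical_cohorts():
    cfg = SimulationConfig(n=500, seed=42)
    f1 = records_to_frame(sample_cohort(cfg))
    f2 = records_to_frame(sample_cohort(SimulationConfig(n=500, seed=42)))
    pd.testing.assert_frame_equal(f1, f2)
    f3 = records_to_frame(sample_cohort(SimulationConfig(n=500, seed=43)))
    assert not f1.equals(f3)


def test_competing_risk_exit_fractions():
    """lambda_14 / sum(lambda) of visits enter the exam room."""
    cfg = _no_effect_config(n=50_000, seed=7)
    recs = sample_cohort(cfg)
    frac_room = np.mean([r.terminal == "departure" for r in recs])
    assert frac_room == pytest.approx(0.88, abs=0.005)


def test_covariate_frequencies_match_config():
    recs = sample_cohort(SimulationConfig(n=50_000, seed=3))
    male = np.mean([r.gender == "Male" for r in recs])
    assert male == pytest.approx(0.515, abs=0.007)  # binomial 3-sigma bound


def test_records_satisfy_invariants(cohort):
    for r in cohort:
        terminals = [t for t in (r.t_departure, r.t_left, r.t_redirect)
                     if t is not None]
        assert len(terminals) == 1
        if r.t_departure is not None:
            assert 0 < r.t_room < r.t_contact < r.t_disposition < r.t_departure
        else:
            assert r.t_room is None and r.t_contact is None
        if r.t_triage is not None:
            assert 0 < r.t_triage <= r.registration_exit_time


def test_acuity_updates_round_trip_through_expansion():
    cfg = SimulationConfig(n=2000, seed=21, p_acuity_update=0.5)
    recs = sample_cohort(cfg)
    updated = [r for r in recs if r.has_acuity_update]
    assert updated  # the condition actually occurs
    long = expand_to_long(recs)
    counts = long.groupby("id").size()
    for r in updated:
        base = 6 if r.terminal == "departure" else 3
        assert counts[r.visit_id] == base + 3


def test_invalid_rates_rejected_before_sampling():
    with pytest.raises(ValueError):
        BaselineSpec("constant", rate=-1.0)
    with pytest.raises(ValueError):
        BaselineSpec("weibull", shape=0.0)
    cfg = SimulationConfig(n=10)
    cfg.category_probs["gender"] = {"Male": 0.9, "Female": 0.3}
    with pytest.raises(ValueError, match="sum"):
        sample_cohort(cfg)


def test_weibull_baseline_marginal_distribution():
    """With a single Weibull exit, times follow that Weibull exactly."""
    cfg = SimulationConfig(
        n=20_000, seed=9,
        baselines={1: BaselineSpec("constant", rate=1e-9),
                   2: BaselineSpec("constant", rate=1e-9),
                   3: BaselineSpec("weibull", shape=2.0, scale=1.5),
                   4: BaselineSpec("constant", rate=1.0),
                   5: BaselineSpec("constant", rate=1.0),
                   6: BaselineSpec("constant", rate=1.0)},
        coefficients={}, p_acuity_update=0.0,
    )
    rooms = np.array([r.t_room for r in sample_cohort(cfg)
                      if r.t_room is not None])
    # E[T] = scale * Gamma(1 + 1/shape)
    from scipy.special import gamma

    assert rooms.mean() == pytest.approx(1.5 * gamma(1.5), rel=0.02)


def test_oracle_identity_when_rates_zero():
    cfg = _no_effect_config(rates=(1e-300,) * 6)
    cfg.baselines = {k: BaselineSpec("constant", rate=1e-300) for k in range(1, 7)}
    P = constant_hazard_oracle(cfg, 3.0)
    np.testing.assert_allclose(P, np.eye(7), atol=1e-12)


def test_oracle_single_exit_closed_form():
    lam = 0.7
    cfg = _no_effect_config(rates=(lam, 1e-300, 1e-300, 1.0, 1.0, 1.0))
    for t in (0.5, 1.0, 2.0):
        P = constant_hazard_oracle(cfg, t)
        assert P[0, 0] == pytest.approx(np.exp(-lam * t), rel=1e-10)


def test_oracle_two_competing_exits_closed_form():
    # lambda_12 = lambda_14 = 1: P_12(1) = (1/2)(1 - e^-2)
    cfg = _no_effect_config(rates=(1.0, 1e-300, 1.0, 1e-300, 1e-300, 1e-300))
    P = constant_hazard_oracle(cfg, 1.0)
    assert P[0, 1] == pytest.approx(0.5 * (1 - np.exp(-2)), rel=1e-10)


def test_oracle_requires_constant_hazards():
    cfg = _no_effect_config()
    cfg.baselines[3] = BaselineSpec("weibull", shape=2.0, scale=1.0)
    with pytest.raises(ValueError, match="constant hazards"):
        transition_rates(cfg)


def test_generator_rows_sum_to_zero():
    rates = transition_rates(_no_effect_config())
    Q = generator_matrix(rates)
    np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-14)
    off = Q - np.diag(np.diag(Q))
    assert (off >= 0).all()
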