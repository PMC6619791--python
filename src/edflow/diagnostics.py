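"""Proportional-hazards diagnostics for fitted transition models.

Three complementary views:

* scaled Schoenfeld residuals at each event time (trend => time-varying
  effect), with a Grambsch-Therneau-type score test against a log-time
  transform as a cross-check;
* a likelihood-ratio test of the model augmented with covariate x log(time)
  interactions against the base model — the headline global PH test;
* log(-log S(t)) versus log t curves per level of a categorical covariate,
  from stratified baseline survival: under proportional hazards the curves
  are vertically parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxFit, StepFunction, _suffix_sums, cox_newton


@dataclass
class PHDiagnostics:
    transition_id: int
    schoenfeld: pd.DataFrame  # time + one scaled-residual column per covariate
    global_lr_stat: float
    global_lr_df: int
    global_lr_p: float
    score_stat: float
    score_df: int
    score_p: float
    lml_curves: Optional[dict] = field(default=None)  # level -> DataFrame


# ---------------------------------------------------------------------------
# Schoenfeld residuals


def schoenfeld_residuals(fit: CoxFit, rows: pd.DataFrame,
                         design: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Scaled Schoenfeld residuals, one row per event (Grambsch-Therneau
    scaling m * V * r); columns are the design columns plus ``time``."""
    X = _design_matrix(fit, rows, design)
    tstart = rows["Tstart"].to_numpy(dtype=float)
    tstop = rows["Tstop"].to_numpy(dtype=float)
    status = rows["status"].to_numpy(dtype=int)
    ev = status == 1
    ev_times = tstop[ev]
    order = np.argsort(ev_times, kind="stable")

    w = np.exp(X @ fit.beta)
    wX = w[:, None] * X
    times = ev_times[order]
    uniq = np.unique(times)
    S0 = _suffix_sums(tstop, w, uniq) - _suffix_sums(tstart, w, uniq)
    S1 = _suffix_sums(tstop, wX, uniq) - _suffix_sums(tstart, wX, uniq)
    xbar = S1 / S0[:, None]
    idx = np.searchsorted(uniq, times)
    resid = X[ev][order] - xbar[idx]
    scaled = fit.n_events * resid @ fit.cov
    out = pd.DataFrame(scaled, columns=fit.coef_names)
    out.insert(0, "time", times)
    return out


def _design_matrix(fit, rows, design):
    if design is not None:
        return design.to_numpy(dtype=float)
    if fit.encoding is not None:
        return fit.encoding.encode_frame(rows)
    return rows[fit.coef_names].to_numpy(dtype=float)


def schoenfeld_score_test(fit: CoxFit, rows: pd.DataFrame,
                          design: Optional[pd.DataFrame] = None) -> tuple[float, int, float]:
    """Score-type global PH test on the log-time transform (cross-check)."""
    X = _design_matrix(fit, rows, design)
    tstart = rows["Tstart"].to_numpy(dtype=float)
    tstop = rows["Tstop"].to_numpy(dtype=float)
    status = rows["status"].to_numpy(dtype=int)
    ev = status == 1
    times = np.sort(tstop[ev])

    w = np.exp(X @ fit.beta)
    wX = w[:, None] * X
    uniq = np.unique(times)
    S0 = _suffix_sums(tstop, w, uniq) - _suffix_sums(tstart, w, uniq)
    S1 = _suffix_sums(tstop, wX, uniq) - _suffix_sums(tstart, wX, uniq)
    xbar = S1 / S0[:, None]
    order = np.argsort(tstop[ev], kind="stable")
    idx = np.searchsorted(uniq, times)
    resid = X[ev][order] - xbar[idx]

    g = np.log(times)
    gc = g - g.mean()
    u = resid.T @ gc
    m = fit.n_events
    denom = float((gc ** 2).sum())
    stat = float(u @ (m * fit.cov) @ u / denom)
    df = X.shape[1]
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# LR test via covariate x log(time) interactions


def _tv_risk_layout(tstart, tstop, status):
    """Per-event-time risk-set indices; iteration-invariant, built once."""
    ev = status == 1
    uniq, counts = np.unique(tstop[ev], return_counts=True)
    layout = []
    for tau, d in zip(uniq, counts):
        at_risk = np.flatnonzero((tstart < tau) & (tstop >= tau))
        is_ev = ev[at_risk] & (tstop[at_risk] == tau)
        layout.append((float(np.log(tau)), int(d), at_risk, is_ev))
    return layout


def _tv_loglik_parts(theta, X, Xint, layout, ties):
    """Loglik, score and information for the time-interaction model.

    Parameters theta = (beta over X's columns, gamma over Xint's columns);
    the covariate vector at event time t is [x, x_int * log t], so weights
    depend on t and the fast suffix-sum path does not apply.
    """
    n, p = X.shape
    q = Xint.shape[1]
    beta, gamma = theta[:p], theta[p:]
    eta0 = X @ beta
    eta1 = Xint @ gamma
    ll = 0.0
    score = np.zeros(p + q)
    info = np.zeros((p + q, p + q))
    for g, d, at_risk, is_ev in layout:
        eta = eta0[at_risk] + g * eta1[at_risk]
        w = np.exp(eta)
        Z = np.hstack([X[at_risk], g * Xint[at_risk]])
        S0, S1 = w.sum(), w @ Z
        S2 = Z.T @ (w[:, None] * Z)
        ll += float(eta[is_ev].sum())
        if ties == "efron" and d > 1:
            wD = w[is_ev]
            ZD = Z[is_ev]
            D0, D1 = wD.sum(), wD @ ZD
            D2 = ZD.T @ (wD[:, None] * ZD)
            for l in range(d):
                f = l / d
                M0 = S0 - f * D0
                M1 = S1 - f * D1
                M2 = S2 - f * D2
                ll -= np.log(M0)
                r = M1 / M0
                score -= r
                info += M2 / M0 - np.outer(r, r)
        else:
            ll -= d * np.log(S0)
            r = S1 / S0
            score -= d * r
            info += d * (S2 / S0 - np.outer(r, r))
        score += Z[is_ev].sum(axis=0)
    return ll, score, info


def _fit_tv_interaction(X, Xint, tstart, tstop, status, ties,
                        tol=1e-7, max_iter=50):
    layout = _tv_risk_layout(tstart, tstop, status)
    theta = np.zeros(X.shape[1] + Xint.shape[1])
    ll, score, info = _tv_loglik_parts(theta, X, Xint, layout, ties)
    for _ in range(max_iter):
        if np.max(np.abs(score)) < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(info) @ score
        new = theta + step
        new_ll, new_score, new_info = _tv_loglik_parts(new, X, Xint, layout, ties)
        halves = 0
        while new_ll < ll - 1e-12 and halves < 12:
            step /= 2.0
            new = theta + step
            new_ll, new_score, new_info = _tv_loglik_parts(new, X, Xint, layout, ties)
            halves += 1
        stalled = abs(new_ll - ll) <= 1e-11 * (abs(ll) + 1.0)
        theta, ll, score, info = new, new_ll, new_score, new_info
        if stalled:
            break
    return theta, ll


def ph_lr_test(fit: CoxFit, rows: pd.DataFrame,
               design: Optional[pd.DataFrame] = None) -> tuple[float, int, float]:
    """Global LR test: base model vs base + all covariate x log(t) interactions."""
    X = _design_matrix(fit, rows, design)
    sd = X.std(axis=0)
    Z = X / sd
    tstart = rows["Tstart"].to_numpy(dtype=float)
    tstop = rows["Tstop"].to_numpy(dtype=float)
    status = rows["status"].to_numpy(dtype=int)
    _, ll_aug = _fit_tv_interaction(Z, Z, tstart, tstop, status, fit.ties)
    stat = 2.0 * (ll_aug - fit.loglik)
    stat = max(stat, 0.0)
    df = X.shape[1]
    return float(stat), df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# log(-log S) curves from stratified baselines


def log_minus_log_curves(fit: CoxFit, rows: pd.DataFrame,
                         group_covariate: str) -> dict:
    """Per-level log(-log S(t)) = log Lambda(t) curves vs log t.

    The model is refit with the grouping covariate removed from the design and
    used as a stratification factor, so each level gets its own baseline; the
    remaining coefficients are shared.  Raises if the covariate is continuous.
    """
    if fit.encoding is None:
        raise ValueError("log-minus-log curves need an encoded fit")
    if group_covariate in fit.encoding.continuous:
        raise ValueError("categorical required for log-minus-log")
    if group_covariate not in fit.encoding.level_maps:
        raise KeyError(f"unknown covariate {group_covariate!r}")

    drop = {name for name in fit.encoding.level_maps[group_covariate].values()
            if name is not None}
    keep = [c for c in fit.coef_names if c not in drop]
    X_full = fit.encoding.encode_frame(rows)
    cols = {c: j for j, c in enumerate(fit.coef_names)}
    X = X_full[:, [cols[c] for c in keep]]
    res = cox_newton(
        X,
        rows["Tstart"].to_numpy(dtype=float),
        rows["Tstop"].to_numpy(dtype=float),
        rows["status"].to_numpy(dtype=int),
        ties=fit.ties,
        strata=rows[group_covariate].to_numpy(),
        names=keep,
    )
    curves = {}
    for level, (times, dL) in res["baseline"].items():
        lam = np.cumsum(dL)
        ok = lam > 0
        curves[level] = pd.DataFrame({
            "time": times[ok],
            "log_time": np.log(times[ok]),
            "log_minus_log_S": np.log(lam[ok]),
        })
    return curves


def ph_diagnostics(fit: CoxFit, rows: pd.DataFrame,
                   design: Optional[pd.DataFrame] = None,
                   group_covariate: Optional[str] = None) -> PHDiagnostics:
    """Full diagnostic bundle for one fitted transition (see module docstring)."""
    resid = schoenfeld_residuals(fit, rows, design)
    lr_stat, lr_df, lr_p = ph_lr_test(fit, rows, design)
    sc_stat, sc_df, sc_p = schoenfeld_score_test(fit, rows, design)
    curves = None
    if group_covariate is not None:
        curves = log_minus_log_curves(fit, rows, group_covariate)
    return PHDiagnostics(
        transition_id=fit.transition_id,
        schoenfeld=resid,
        global_lr_stat=lr_stat, global_lr_df=lr_df, global_lr_p=lr_p,
        score_stat=sc_stat, score_df=sc_df, score_p=sc_p,
        lml_curves=curves,
    )
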