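"""Cox proportional-hazards estimation on counting-process rows.

Implements the partial likelihood for (start, stop, status] data with delayed
entry: the risk set at an event time t is every row with Tstart < t <= Tstop.
Ties are handled by the Efron approximation by default (Breslow available),
the score is maximized by Newton-Raphson with step-halving, and the baseline
cumulative hazard is the Breslow-type step-function estimator (with the Efron
correction when ties were handled by Efron).

Continuous covariates are rescaled to unit variance internally for
conditioning and back-transformed on output; the partial likelihood is
invariant to centering so no centering is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .encoding import CodingScheme, Encoding, encode_covariates


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message + f"; trace={trace}")
        self.trace = trace


class StepFunction:
    """Right-continuous step function, 0 before the first jump."""

    def __init__(self, times: np.ndarray, values: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be sorted")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        out = np.where(idx > 0, self.values[np.minimum(idx, len(self.values)) - 1], 0.0)
        return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# partial-likelihood sums


def _suffix_sums(keys: np.ndarray, contrib: np.ndarray, thresholds: np.ndarray):
    """sum of contrib over rows with keys >= each threshold (vectorized)."""
    order = np.argsort(keys, kind="stable")
    csum = np.cumsum(contrib[order], axis=0)
    total = csum[-1]
    idx = np.searchsorted(keys[order], thresholds, side="left")
    out = np.empty((len(thresholds),) + contrib.shape[1:])
    has_prefix = idx > 0
    out[...] = total
    out[has_prefix] = total - csum[idx[has_prefix] - 1]
    return out


def _event_layout(tstop: np.ndarray, status: np.ndarray):
    """Unique event times, multiplicities, and the Efron fraction expansion."""
    ev_t = tstop[status == 1]
    times, counts = np.unique(ev_t, return_counts=True)
    m = int(counts.sum())
    rep = np.repeat(np.arange(len(times)), counts)
    offset = np.repeat(np.cumsum(counts) - counts, counts)
    frac = (np.arange(m) - offset) / np.repeat(counts, counts)
    return times, counts, rep, frac


def _stratum_sums(beta, X, tstart, tstop, status, ties):
    """(loglik, score, information, baseline pieces) for one stratum."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    ev = status == 1
    if not ev.any():
        return 0.0, np.zeros(p), np.zeros((p, p)), (np.empty(0), np.empty(0))

    times, counts, rep, frac = _event_layout(tstop, status)
    if ties == "breslow":
        frac = np.zeros_like(frac)

    wX = w[:, None] * X
    wXX = wX[:, :, None] * X[:, None, :]

    S0 = _suffix_sums(tstop, w, times) - _suffix_sums(tstart, w, times)
    S1 = _suffix_sums(tstop, wX, times) - _suffix_sums(tstart, wX, times)
    S2 = _suffix_sums(tstop, wXX, times) - _suffix_sums(tstart, wXX, times)

    # tied-event sums, grouped by event time
    ev_idx = np.flatnonzero(ev)
    order = ev_idx[np.argsort(tstop[ev_idx], kind="stable")]
    bounds = np.concatenate(([0], np.cumsum(counts)))[:-1]
    D0 = np.add.reduceat(w[order], bounds)
    D1 = np.add.reduceat(wX[order], bounds)
    D2 = np.add.reduceat(wXX[order], bounds)

    M0 = S0[rep] - frac * D0[rep]
    if np.any(M0 <= 0):
        raise FloatingPointError("empty or degenerate risk set at an event time")
    M1 = S1[rep] - frac[:, None] * D1[rep]
    M2 = S2[rep] - frac[:, None, None] * D2[rep]

    ll = float(eta[ev].sum() - np.log(M0).sum())
    ratio = M1 / M0[:, None]
    score = X[ev].sum(axis=0) - ratio.sum(axis=0)
    info = (M2 / M0[:, None, None]).sum(axis=0) - np.einsum("ki,kj->ij", ratio, ratio)

    # baseline cumulative-hazard increments at beta (tie-consistent)
    dL = np.add.reduceat(1.0 / M0, bounds) if ties == "efron" else counts / S0
    return ll, score, info, (times, dL)


def _cox_sums(beta, X, tstart, tstop, status, ties, strata=None):
    p = X.shape[1]
    if strata is None:
        return _stratum_sums(beta, X, tstart, tstop, status, ties)
    ll, score, info = 0.0, np.zeros(p), np.zeros((p, p))
    baselines = {}
    for s in pd.unique(np.asarray(strata)):
        m = np.asarray(strata) == s
        l, g, h, b = _stratum_sums(beta, X[m], tstart[m], tstop[m], status[m], ties)
        ll += l
        score += g
        info += h
        baselines[s] = b
    return ll, score, info, baselines


def _check_design(X: np.ndarray, names: Sequence[str]):
    sd = X.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"non-identifiable design: column '{names[j]}' is constant")
    Z = (X - X.mean(axis=0)) / sd
    _, R = np.linalg.qr(Z)
    diag = np.abs(np.diag(R))
    bad = np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))
    if bad.size:
        raise ValueError(
            f"non-identifiable design: column '{names[bad[0]]}' is collinear"
        )
    return sd


def cox_newton(
    X: np.ndarray,
    tstart: np.ndarray,
    tstop: np.ndarray,
    status: np.ndarray,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
    strata=None,
    names: Optional[Sequence[str]] = None,
) -> dict:
    """Maximize the delayed-entry partial likelihood; the numeric core.

    Returns a dict with beta, covariance, log-likelihoods, iteration count and
    per-(stratum-)event-time baseline hazard increments evaluated at beta-hat.
    """
    X = np.asarray(X, dtype=float)
    tstart = np.asarray(tstart, dtype=float)
    tstop = np.asarray(tstop, dtype=float)
    status = np.asarray(status, dtype=int)
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if np.any(tstart >= tstop):
        raise ValueError("every row needs Tstart < Tstop")
    n_events = int(status.sum())
    if n_events == 0:
        raise ValueError("no events on transition")
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    if X.shape[1] == 0:  # pure baseline (e.g. stratified Nelson-Aalen)
        beta = np.zeros(0)
        ll0, _, _, baseline = _cox_sums(beta, X, tstart, tstop, status, ties, strata)
        return {
            "beta": beta, "cov": np.zeros((0, 0)), "loglik": ll0, "loglik0": ll0,
            "n_iter": 0, "n_events": n_events, "n_rows": len(X),
            "baseline": baseline, "names": names,
        }
    scale = _check_design(X, names)
    Z = X / scale

    beta = np.zeros(X.shape[1])
    ll0, _, _, _ = _cox_sums(beta, Z, tstart, tstop, status, ties, strata)
    ll, trace = ll0, []
    for it in range(1, max_iter + 1):
        _, score, info, _ = _cox_sums(beta, Z, tstart, tstop, status, ties, strata)
        if np.max(np.abs(score)) < tol:
            break
        step = np.linalg.solve(info, score)
        new_beta = beta + step
        new_ll, *_ = _cox_sums(new_beta, Z, tstart, tstop, status, ties, strata)
        halves = 0
        while new_ll < ll - 1e-12 and halves < 30:  # step-halving safeguard
            step /= 2.0
            new_beta = beta + step
            new_ll, *_ = _cox_sums(new_beta, Z, tstart, tstop, status, ties, strata)
            halves += 1
        converged_by_step = (
            np.max(np.abs(step)) < 1e-12
            or abs(new_ll - ll) <= 1e-13 * (abs(ll) + 1.0)
        )
        beta, ll = new_beta, new_ll
        trace.append({"iter": it, "loglik": ll, "max_score": float(np.max(np.abs(score)))})
        if converged_by_step:  # score at the float rounding floor
            break
    else:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations", trace
        )

    ll_hat, score, info, baseline = _cox_sums(beta, Z, tstart, tstop, status, ties, strata)
    cov_z = np.linalg.inv(info)
    cov = cov_z / np.outer(scale, scale)
    beta_x = beta / scale
    return {
        "beta": beta_x,
        "cov": 0.5 * (cov + cov.T),
        "loglik": ll_hat,
        "loglik0": ll0,
        "n_iter": it,
        "n_events": n_events,
        "n_rows": len(X),
        "baseline": baseline,  # (times, increments) or {stratum: ...}
        "names": names,
    }


# ---------------------------------------------------------------------------
# public per-transition surface


@dataclass
class CoxFit:
    """A fitted per-transition Cox model on the since-registration clock."""

    transition_id: int
    coef_names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik0: float
    n_rows: int
    n_events: int
    ties: str
    n_iter: int
    baseline: StepFunction  # cumulative hazard at the reference profile
    baseline_times: np.ndarray = field(repr=False, default=None)
    baseline_increments: np.ndarray = field(repr=False, default=None)
    encoding: Optional[Encoding] = field(repr=False, default=None)

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def fit_transition_cox(
    rows: pd.DataFrame,
    design: Optional[pd.DataFrame] = None,
    scheme: Optional[CodingScheme] = None,
    transition_id: Optional[int] = None,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Fit one transition's Cox model from its counting-process rows.

    ``rows`` must all share one transition id and carry Tstart/Tstop/status;
    covariates are encoded with ``scheme`` unless an explicit numeric
    ``design`` (aligned with ``rows``) is supplied.
    """
    if transition_id is None:
        trans = rows["trans"].unique() if "trans" in rows.columns else [0]
        if len(trans) != 1:
            raise ValueError("rows must all share one transition id")
        transition_id = int(trans[0])
    encoding = None
    if design is None:
        design, encoding = encode_covariates(rows, scheme)
    res = cox_newton(
        design.to_numpy(dtype=float),
        rows["Tstart"].to_numpy(dtype=float),
        rows["Tstop"].to_numpy(dtype=float),
        rows["status"].to_numpy(dtype=int),
        ties=ties, tol=tol, max_iter=max_iter,
        names=list(design.columns),
    )
    times, dL = res["baseline"]
    return CoxFit(
        transition_id=transition_id,
        coef_names=res["names"],
        beta=res["beta"],
        cov=res["cov"],
        loglik=res["loglik"],
        loglik0=res["loglik0"],
        n_rows=res["n_rows"],
        n_events=res["n_events"],
        ties=ties,
        n_iter=res["n_iter"],
        baseline=StepFunction(times, np.cumsum(dL)),
        baseline_times=times,
        baseline_increments=dL,
        encoding=encoding,
    )


def baseline_cumulative_hazard(fit: CoxFit, rows: pd.DataFrame,
                               design: Optional[pd.DataFrame] = None) -> StepFunction:
    """Breslow-type baseline cumulative hazard at beta-hat, recomputed from rows.

    With Efron ties the per-time increment is the Efron-corrected sum
    sum_l 1/(S0 - (l/d) D0); with no ties both reduce to d/S0, and with
    beta = 0 the estimator is exactly Nelson-Aalen.
    """
    if design is None:
        if fit.encoding is not None:
            X = fit.encoding.encode_frame(rows)
        else:
            X = rows[fit.coef_names].to_numpy(dtype=float)
    else:
        X = design.to_numpy(dtype=float)
    _, _, _, (times, dL) = _cox_sums(
        fit.beta,
        X,
        rows["Tstart"].to_numpy(dtype=float),
        rows["Tstop"].to_numpy(dtype=float),
        rows["status"].to_numpy(dtype=int),
        fit.ties,
    )
    return StepFunction(times, np.cumsum(dL))


def summarize_hazard_ratios(
    fit: CoxFit, level: float = 0.95, decimals: int = 3
) -> pd.DataFrame:
    """Hazard-ratio table: HR = exp(beta), Wald CI and two-sided p-values.

    Reference levels (and zero-event levels merged into the baseline) are
    listed as marked reference rows carrying no numbers, mirroring the usual
    published layout.
    """
    from scipy import stats

    z = stats.norm.ppf(0.5 + level / 2.0)
    se = fit.standard_errors
    rows = []
    if fit.encoding is not None:
        for col in fit.encoding.continuous:
            j = fit.coef_names.index(col)
            rows.append(_hr_row(col, col, fit.beta[j], se[j], z))
        for col, mapping in fit.encoding.level_maps.items():
            seen = set()
            for lv, name in mapping.items():
                if name is None:
                    rows.append({
                        "covariate": col, "level": str(lv), "reference": True,
                        "coef": np.nan, "HR": np.nan, "ci_low": np.nan,
                        "ci_high": np.nan, "p": np.nan,
                    })
                elif name not in seen:
                    seen.add(name)
                    j = fit.coef_names.index(name)
                    r = _hr_row(col, str(lv), fit.beta[j], se[j], z)
                    rows.append(r)
    else:
        for j, name in enumerate(fit.coef_names):
            rows.append(_hr_row(name, name, fit.beta[j], se[j], z))
    table = pd.DataFrame(rows)
    for c in ("HR", "ci_low", "ci_high", "p"):
        table[c] = table[c].round(decimals)
    return table


def _hr_row(covariate: str, level: str, b: float, se: float, z: float) -> dict:
    from scipy import stats

    return {
        "covariate": covariate,
        "level": level,
        "reference": False,
        "coef": b,
        "HR": float(np.exp(b)),
        "ci_low": float(np.exp(b - z * se)),
        "ci_high": float(np.exp(b + z * se)),
        "p": float(2 * stats.norm.sf(abs(b) / se)) if se > 0 else np.nan,
    }
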