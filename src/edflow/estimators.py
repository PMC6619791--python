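"""Estimator classes in the scikit-learn idiom.

:class:`TransitionCoxPH` is a single Cox proportional-hazards regression on
counting-process data (fit/predict, ``get_params``/``set_params``, fitted
attributes with trailing underscores), compatible with sklearn pipelines and
model selection.  :class:`MultistateCox` composes one :class:`TransitionCoxPH`
per transition of the ED flow graph and exposes the prediction surface
(conditional cumulative hazards, Aalen-Johansen occupation curves, expected
sojourn times).  The module-level functions elsewhere in the package are thin
wrappers over these.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .cox import CoxFit, StepFunction, cox_newton, summarize_hazard_ratios
from .diagnostics import PHDiagnostics, ph_diagnostics
from .encoding import CodingScheme, encode_covariates
from .prediction import (
    CumulativeHazardSet,
    OccupationCurves,
    aalen_johansen,
    expected_sojourn,
    predict_cumulative_hazards,
)
from .structure import TransitionStructure, ed_structure


def _as_survival_frame(y) -> pd.DataFrame:
    """Coerce y into a (Tstart, Tstop, status) frame.

    Accepts a DataFrame with those columns, a structured array with fields
    (tstart/start, tstop/stop/time, status/event), or an (n, 3) array.
    """
    if isinstance(y, pd.DataFrame):
        cols = {c.lower(): c for c in y.columns}
        try:
            return pd.DataFrame({
                "Tstart": y[cols.get("tstart", cols.get("start"))].to_numpy(float),
                "Tstop": y[cols.get("tstop", cols.get("stop", cols.get("time")))].to_numpy(float),
                "status": y[cols.get("status", cols.get("event"))].to_numpy(int),
            })
        except KeyError as exc:
            raise ValueError("y must carry Tstart/Tstop/status columns") from exc
    arr = np.asarray(y)
    if arr.dtype.names:
        names = {n.lower(): n for n in arr.dtype.names}
        return pd.DataFrame({
            "Tstart": arr[names.get("tstart", names.get("start"))].astype(float),
            "Tstop": arr[names.get("tstop", names.get("stop", names.get("time")))].astype(float),
            "status": arr[names.get("status", names.get("event"))].astype(int),
        })
    if arr.ndim == 2 and arr.shape[1] == 3:
        return pd.DataFrame(arr, columns=["Tstart", "Tstop", "status"])
    raise ValueError("y must be (Tstart, Tstop, status) data")


class TransitionCoxPH(BaseEstimator):
    """Cox proportional hazards on (start, stop, status] counting-process data.

    Parameters
    ----------
    ties : {'efron', 'breslow'}
        Partial-likelihood approximation for tied event times.
    tol : float
        Newton-Raphson gradient-norm convergence tolerance.
    max_iter : int
        Maximum Newton-Raphson iterations before a ConvergenceError.
    alpha : float
        1 - confidence level for hazard-ratio intervals.

    Attributes (after fit)
    ----------------------
    coef_, covariance_, baseline_cumulative_hazard_ (StepFunction),
    log_likelihood_, null_log_likelihood_, n_events_, feature_names_in_.
    """

    def __init__(self, ties: str = "efron", tol: float = 1e-8,
                 max_iter: int = 50, alpha: float = 0.05):
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter
        self.alpha = alpha

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(Xa.shape[1])]
        surv = _as_survival_frame(y)
        if len(surv) != len(Xa):
            raise ValueError("X and y length mismatch")
        res = cox_newton(
            Xa, surv["Tstart"].to_numpy(), surv["Tstop"].to_numpy(),
            surv["status"].to_numpy(), ties=self.ties, tol=self.tol,
            max_iter=self.max_iter, names=names,
        )
        self.coef_ = res["beta"]
        self.covariance_ = res["cov"]
        self.log_likelihood_ = res["loglik"]
        self.null_log_likelihood_ = res["loglik0"]
        self.n_iter_ = res["n_iter"]
        self.n_events_ = res["n_events"]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = Xa.shape[1]
        times, dL = res["baseline"]
        self.baseline_event_times_ = times
        self.baseline_increments_ = dL
        self.baseline_cumulative_hazard_ = StepFunction(times, np.cumsum(dL))
        return self

    def predict(self, X):
        """Linear predictor (log partial hazard) per row."""
        check_is_fitted(self, "coef_")
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return Xa @ self.coef_

    def predict_partial_hazard(self, X):
        return np.exp(self.predict(X))

    def predict_cumulative_hazard(self, X, times):
        """Lambda(t | z) = Lambda0(t) * exp(beta'z) on the requested times."""
        check_is_fitted(self, "coef_")
        base = self.baseline_cumulative_hazard_(np.asarray(times, float))
        return np.outer(self.predict_partial_hazard(X), base)

    def score(self, X, y):
        """Partial log-likelihood of (X, y) at the fitted coefficients."""
        check_is_fitted(self, "coef_")
        from .cox import _cox_sums

        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        surv = _as_survival_frame(y)
        ll, *_ = _cox_sums(self.coef_, Xa, surv["Tstart"].to_numpy(),
                           surv["Tstop"].to_numpy(), surv["status"].to_numpy(),
                           self.ties)
        return ll

    def as_cox_fit(self, transition_id: int = 0, encoding=None) -> CoxFit:
        """View the fitted state as the package's CoxFit record."""
        check_is_fitted(self, "coef_")
        return CoxFit(
            transition_id=transition_id,
            coef_names=list(self.feature_names_in_),
            beta=self.coef_,
            cov=self.covariance_,
            loglik=self.log_likelihood_,
            loglik0=self.null_log_likelihood_,
            n_rows=-1,
            n_events=self.n_events_,
            ties=self.ties,
            n_iter=self.n_iter_,
            baseline=self.baseline_cumulative_hazard_,
            baseline_times=self.baseline_event_times_,
            baseline_increments=self.baseline_increments_,
            encoding=encoding,
        )

    def hazard_ratios(self) -> pd.DataFrame:
        check_is_fitted(self, "coef_")
        return summarize_hazard_ratios(self.as_cox_fit(), level=1 - self.alpha)


class MultistateCox(BaseEstimator):
    """Per-transition Cox models + Aalen-Johansen prediction for ED flow.

    ``fit`` consumes the long-format counting-process table produced by
    ``expand_to_long`` (columns id/trans/Tstart/Tstop/status + covariates);
    each transition gets its own coefficient vector, zero-event level merges
    and Breslow/Efron baseline.  Prediction conditions on a covariate profile.
    """

    def __init__(self, ties: str = "efron", tol: float = 1e-8,
                 max_iter: int = 50, alpha: float = 0.05,
                 scheme: Optional[CodingScheme] = None,
                 structure: Optional[TransitionStructure] = None):
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter
        self.alpha = alpha
        self.scheme = scheme
        self.structure = structure

    def fit(self, X, y=None):
        from .cox import fit_transition_cox

        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be the long-format transition DataFrame")
        required = {"trans", "Tstart", "Tstop", "status"}
        if not required <= set(X.columns):
            raise ValueError(f"long table must carry columns {sorted(required)}")
        self.structure_ = self.structure or ed_structure()
        scheme = self.scheme or CodingScheme()
        self.fits_: dict[int, CoxFit] = {}
        self.rows_: dict[int, pd.DataFrame] = {}
        for k in sorted(X["trans"].unique()):
            rows = X[X["trans"] == k]
            self.fits_[int(k)] = fit_transition_cox(
                rows, scheme=scheme, transition_id=int(k),
                ties=self.ties, tol=self.tol, max_iter=self.max_iter,
            )
            self.rows_[int(k)] = rows
        return self

    def predict_cumulative_hazard(self, profile) -> CumulativeHazardSet:
        check_is_fitted(self, "fits_")
        return predict_cumulative_hazards(self.fits_, profile, self.structure_)

    def predict_occupation(self, profile, s: float = 0.0,
                           increment_policy: str = "clip") -> OccupationCurves:
        cumhaz = self.predict_cumulative_hazard(profile)
        return aalen_johansen(cumhaz, self.structure_, s=s,
                              increment_policy=increment_policy)

    def expected_sojourn(self, profile, tau: Optional[float] = None,
                         s: float = 0.0) -> pd.DataFrame:
        return expected_sojourn(self.predict_occupation(profile, s=s), tau=tau)

    def hazard_ratios(self) -> dict[int, pd.DataFrame]:
        check_is_fitted(self, "fits_")
        return {k: summarize_hazard_ratios(f, level=1 - self.alpha)
                for k, f in self.fits_.items()}

    def diagnostics(self, transition_id: int,
                    group_covariate: Optional[str] = None) -> PHDiagnostics:
        check_is_fitted(self, "fits_")
        return ph_diagnostics(self.fits_[transition_id],
                              self.rows_[transition_id],
                              group_covariate=group_covariate)
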