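"""Covariate-conditional prediction for the multistate model.

From six fitted transition models and a covariate profile this module builds
per-transition cumulative hazards Lambda_qr(t | Z), runs them through the
Aalen-Johansen product integral to get the transition probability matrix
P(s, t) and the state occupation probabilities e1' P(0, t), and integrates
occupation probabilities to expected sojourn times (the expected length of
stay in each state up to a horizon tau).

A profile may be piecewise in time — a list of (start_time, values) segments
partitioning [0, inf) — which is how a known covariate change (e.g. an acuity
revision) enters a prediction; for the standard per-ESI panels the profile is
constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cox import CoxFit
from .structure import TransitionStructure, ed_structure

logger = logging.getLogger(__name__)

Profile = Union[dict, Sequence[tuple[float, dict]]]


def _profile_segments(profile: Profile) -> list[tuple[float, dict]]:
    if isinstance(profile, dict):
        return [(0.0, profile)]
    segs = sorted(profile, key=lambda s: s[0])
    if not segs or segs[0][0] != 0.0:
        raise ValueError("piecewise profile segments must start at time 0")
    return list(segs)


@dataclass
class CumulativeHazardSet:
    """Per-transition conditional cumulative hazard increments on one grid.

    ``grid`` is the sorted union of every transition's event times;
    ``increments[k]`` holds d Lambda_qr(t | Z) for transition id k aligned
    with the grid (zero where that transition has no event).
    """

    grid: np.ndarray
    increments: dict[int, np.ndarray]
    structure: TransitionStructure

    def cumulative(self, transition_id: int) -> np.ndarray:
        return np.cumsum(self.increments[transition_id])


def predict_cumulative_hazards(
    fits: dict[int, CoxFit],
    profile: Profile,
    structure: Optional[TransitionStructure] = None,
) -> CumulativeHazardSet:
    """Conditional cumulative hazards: baseline increments scaled by
    exp(beta' z(u)), with z(u) read from the (possibly piecewise) profile at
    each event time u."""
    structure = structure or ed_structure()
    segments = _profile_segments(profile)
    grid = np.unique(np.concatenate([
        fits[k].baseline_times for k in fits if len(fits[k].baseline_times)
    ]))
    increments: dict[int, np.ndarray] = {}
    seg_starts = np.array([s for s, _ in segments])
    for k, fit in fits.items():
        if fit.encoding is None:
            raise ValueError("prediction requires fits with encodings attached")
        etas = np.array([
            float(fit.beta @ fit.encoding.encode_profile(vals))
            for _, vals in segments
        ])
        dL = np.zeros_like(grid)
        if len(fit.baseline_times):
            pos = np.searchsorted(grid, fit.baseline_times)
            seg_idx = np.searchsorted(seg_starts, fit.baseline_times, side="right") - 1
            dL[pos] = fit.baseline_increments * np.exp(etas[seg_idx])
        increments[k] = dL
    return CumulativeHazardSet(grid=grid, increments=increments, structure=structure)


@dataclass
class OccupationCurves:
    """P(s, t) matrices and state occupation probabilities on the event grid."""

    s: float
    grid: np.ndarray  # starts at s; right-continuous step representation
    P: np.ndarray  # (len(grid), n_states, n_states)
    occupation: np.ndarray  # (len(grid), n_states) = e_initial' P(s, t)
    structure: TransitionStructure

    def occupation_frame(self) -> pd.DataFrame:
        """Tidy (time, state, label, probability) table, plot-ready."""
        recs = []
        for i, t in enumerate(self.grid):
            for j, state in enumerate(self.structure.states):
                recs.append({
                    "time": t, "state": state,
                    "label": self.structure.labels.get(state, str(state)),
                    "probability": self.occupation[i, j],
                })
        return pd.DataFrame(recs)


def aalen_johansen(
    cumhaz: CumulativeHazardSet,
    structure: Optional[TransitionStructure] = None,
    s: float = 0.0,
    increment_policy: str = "error",
) -> OccupationCurves:
    """Product-integral estimator of P(s, t) over the event-time grid.

    P(s, t) = prod_{u in (s, t]} (I + dA(u)) with off-diagonal increments
    d Lambda_qr(u) and diagonals minus the row sums.  An off-diagonal
    increment above 1 is invalid: with the default policy it raises; with
    ``increment_policy="clip"`` it is clipped to 1 with a logged warning
    (conditional increments exceed 1 generically in the sparse risk-set tail
    when the profile's hazard ratio is above 1, where occupancy of the
    source state is already negligible).  A diagonal of I + dA below 0 is
    floored at zero with the off-diagonal entries rescaled to keep the row
    stochastic (each occurrence logged).
    """
    structure = structure or cumhaz.structure
    if s < 0:
        raise ValueError("start time s must be >= 0")
    if increment_policy not in ("error", "clip"):
        raise ValueError("increment_policy must be 'error' or 'clip'")
    ns = structure.n_states
    sidx = {state: i for i, state in enumerate(structure.states)}
    mask = cumhaz.grid > s
    times = cumhaz.grid[mask]

    P = np.eye(ns)
    grid = [s]
    Ps = [P.copy()]
    for pos, u in zip(np.flatnonzero(mask), times):
        F = np.eye(ns)
        for k, dL in cumhaz.increments.items():
            d = dL[pos]
            if d == 0.0:
                continue
            if d > 1.0:
                if increment_policy == "error":
                    raise ValueError(
                        f"invalid hazard increment {d:g} > 1 on transition {k} at t={u:g}"
                    )
                logger.warning(
                    "hazard increment %g > 1 on transition %d at t=%g clipped to 1",
                    d, k, u,
                )
                d = 1.0
            q, r = structure.from_to(k)
            F[sidx[q], sidx[r]] += d
            F[sidx[q], sidx[q]] -= d
        neg = np.diag(F) < 0
        if neg.any():
            for i in np.flatnonzero(neg):
                logger.warning(
                    "diagonal of I + dA floored at 0 (row %d, t=%g); "
                    "off-diagonals rescaled", i, u,
                )
                F[i, i] = 0.0
                rs = F[i].sum()
                F[i] /= rs
        P = P @ F
        grid.append(u)
        Ps.append(P.copy())

    grid = np.asarray(grid)
    Parr = np.asarray(Ps)
    init = sidx[structure.initial_states()[0]]
    occupation = Parr[:, init, :]
    return OccupationCurves(s=s, grid=grid, P=Parr, occupation=occupation,
                            structure=structure)


def expected_sojourn(
    curves: OccupationCurves, tau: Optional[float] = None
) -> pd.DataFrame:
    """Expected sojourn time per state over [s, tau]: integral of the
    occupation probability, exact for the piecewise-constant estimator.

    Defaults tau to the last grid time; beyond the grid the occupation vector
    is extrapolated as constant with a warning.  Returns a tidy table with
    hours and minutes; the sojourns sum to tau - s by construction.
    """
    if tau is None:
        tau = float(curves.grid[-1])
    if tau <= curves.s:
        raise ValueError("tau must exceed the start time")
    if tau > curves.grid[-1]:
        logger.warning(
            "tau=%g beyond last event time %g; extrapolating constant occupation",
            tau, curves.grid[-1],
        )
    knots = np.append(curves.grid, np.inf)
    sojourn = np.zeros(curves.occupation.shape[1])
    for i in range(len(curves.grid)):
        lo, hi = knots[i], min(knots[i + 1], tau)
        if hi <= lo:
            continue
        sojourn += curves.occupation[i] * (hi - lo)
    return pd.DataFrame({
        "state": list(curves.structure.states),
        "label": [curves.structure.labels.get(s_, str(s_))
                  for s_ in curves.structure.states],
        "sojourn_hours": sojourn,
        "sojourn_minutes": sojourn * 60.0,
    })


def occupation_table(curves: OccupationCurves, profile: Optional[dict] = None
                     ) -> pd.DataFrame:
    """Occupation curves as tidy CSV-ready rows, optionally tagged with the
    profile values (one column per covariate)."""
    frame = curves.occupation_frame()
    if profile:
        for key, value in profile.items():
            frame[key] = value
    return frame
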