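"""Closed-form oracle for constant-hazard cohorts.

When every baseline is a constant rate and covariate effects are folded in
for a fixed profile, the ED process is a time-homogeneous Markov chain on
the 7 states with generator matrix Q, so P(t) = expm(t Q) exactly.  The
simulation and Aalen-Johansen invariant tests compare against this.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.linalg import expm

from .simulate import SimulationConfig, _linear_predictor
from .structure import TransitionStructure, ed_structure


def transition_rates(
    config: SimulationConfig, profile: Optional[dict] = None
) -> dict[int, float]:
    """Per-transition constant rates, with the profile's effects folded in.

    ``profile`` maps covariate names to values (``esi`` is the held-fixed
    acuity level); omit it for a no-covariate-effect configuration.
    """
    rates: dict[int, float] = {}
    for k, spec in config.baselines.items():
        if spec.kind != "constant":
            raise ValueError("oracle requires constant hazards")
        mult = 1.0
        coefs = config.coefficients.get(k, {})
        if coefs:
            if profile is None:
                raise ValueError(
                    "a profile is required when covariate effects are present"
                )
            cov = {c: np.array([v], dtype=object) for c, v in profile.items()
                   if c != "esi"}
            esi = np.array([profile.get("esi", 1)], dtype=int)
            mult = float(np.exp(_linear_predictor(coefs, cov, esi)[0]))
        rates[k] = spec.rate * mult
    return rates


def generator_matrix(
    rates: dict[int, float], structure: Optional[TransitionStructure] = None
) -> np.ndarray:
    """Assemble the n_states x n_states generator Q; rows sum to zero."""
    structure = structure or ed_structure()
    sidx = {s: i for i, s in enumerate(structure.states)}
    Q = np.zeros((structure.n_states, structure.n_states))
    for k, rate in rates.items():
        q, r = structure.from_to(k)
        Q[sidx[q], sidx[r]] += rate
        Q[sidx[q], sidx[q]] -= rate
    return Q


def constant_hazard_oracle(
    config: SimulationConfig,
    t,
    profile: Optional[dict] = None,
    structure: Optional[TransitionStructure] = None,
) -> np.ndarray:
    """Exact P(t) = expm(t Q) for a constant-hazard configuration.

    ``t`` may be a scalar (returns one matrix) or an array (stacked matrices).
    """
    structure = structure or ed_structure()
    Q = generator_matrix(transition_rates(config, profile), structure)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.stack([expm(ti * Q) for ti in t_arr])
    return out[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out
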