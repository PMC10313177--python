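"""Stiff integration of the assembled model.

Wraps :func:`scipy.integrate.solve_ivp` with the model's per-species absolute
tolerances.  The default method is stiffness-switching LSODA (the compiled
right-hand side makes its internal finite-difference Jacobian cheap); BDF
with a cached Jacobian sparsity pattern is available as an alternative.
Trajectories are clipped at zero post hoc; excursions beyond ten times the
absolute tolerance are logged as warnings rather than terminating the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import rhs as _rhs_mod
from .mechanisms import diameter_to_cells
from .params import PatientParameters
from .state import (C_NCD4, C_NCD8, CENTRAL0, L_NCD4, L_NCD8, LN0, LN_BLOCK,
                    N_CLONES, N_LN, N_STATE, N_TUMORS, PER_NCD4, PER_NCD8,
                    PERIPHERAL0, T_CANCER, T_K, TUMOR0, TUMOR_BLOCK,
                    ModelState, default_atol, species_table)

logger = logging.getLogger(__name__)

RTOL = 1e-6
_ATOL = default_atol()


class SolverError(RuntimeError):
    """Raised when the stiff solver fails or the state goes non-finite."""


def _check_finite(y: np.ndarray, context: str) -> None:
    if not np.all(np.isfinite(y)):
        bad = int(np.argmin(np.isfinite(y)))
        comp, species = species_table()[bad]
        raise SolverError(
            f"non-finite value in {context}: {species} in {comp.value}")


def initial_state(patient: PatientParameters) -> ModelState:
    """Pre-seeding state: healthy immune pools, naive vasculature, no tumor."""
    kin = patient.kinetics
    y = np.zeros(N_STATE)
    for j in range(N_TUMORS):
        y[TUMOR0 + j * TUMOR_BLOCK + T_K] = kin.K_init
    y[CENTRAL0 + C_NCD8] = kin.N8_C0
    y[CENTRAL0 + C_NCD4] = kin.N4_C0
    y[PERIPHERAL0 + PER_NCD8] = kin.N8_P_max
    y[PERIPHERAL0 + PER_NCD4] = kin.N4_P_max
    for l in range(N_LN):
        y[LN0 + l * LN_BLOCK + L_NCD8] = kin.q_CL * kin.N8_C0 / kin.q_LC
        y[LN0 + l * LN_BLOCK + L_NCD4] = kin.q_CL * kin.N4_C0 / kin.q_LC
    return ModelState(y)


def seed_tumor(state: ModelState, patient: PatientParameters, j: int) -> None:
    """Introduce the seeding cancer-cell inoculum into tumor ``j`` in place."""
    off = TUMOR0 + j * TUMOR_BLOCK
    state.vec[off + T_CANCER: off + T_CANCER + N_CLONES] += (
        patient.n_seed_cells * patient.clone_fractions[j])


@dataclass
class Trajectory:
    times: np.ndarray           # (T,), day
    states: np.ndarray          # (T, N_STATE)
    stop_time: float | None = None   # event time, if an event fired

    def final(self) -> ModelState:
        return ModelState(self.states[-1].copy())


def integrate(patient: PatientParameters, y0: np.ndarray, t0: float,
              t1: float, t_eval: np.ndarray | None = None,
              events=None, max_step: float | None = None,
              method: str = "LSODA") -> Trajectory:
    """Integrate the full model from ``t0`` to ``t1``.

    ``events`` are scipy-style event callables of signature ``(t, y)``; a
    terminal event stops the integration early.
    """
    _check_finite(np.asarray(y0, dtype=float), "initial state")
    pscal, ptum = patient.pack()
    kernel = _rhs_mod.rhs

    def fun(t, y):
        return kernel(t, y, pscal, ptum)

    kwargs = {}
    if method == "BDF":
        kwargs["jac_sparsity"] = _rhs_mod.rhs_sparsity(pscal, ptum)
    sol = solve_ivp(
        fun, (t0, t1), np.asarray(y0, dtype=float), method=method,
        t_eval=t_eval, events=events, rtol=RTOL, atol=_ATOL,
        max_step=np.inf if max_step is None else max_step, **kwargs,
    )
    if sol.status == -1:
        raise SolverError(f"solver failed: {sol.message}")
    _check_finite(sol.y[:, -1], "final state")

    states = sol.y.T.copy()
    worst = states.min(axis=0)
    # excursions at the local-error scale (rtol * species magnitude) are
    # expected numerical noise; warn only beyond that
    tol = np.maximum(10.0 * _ATOL, 10.0 * RTOL * np.abs(states).max(axis=0))
    bad = worst < -tol
    if np.any(bad):
        idx = int(np.argmin(worst / _ATOL))
        comp, species = species_table()[idx]
        logger.warning("negative excursion clipped: %s in %s reached %.3g",
                       species, comp.value, worst[idx])
    np.clip(states, 0.0, None, out=states)

    stop = None
    if sol.status == 1 and events is not None:
        for te in sol.t_events:
            if len(te):
                stop = float(te[0])
    return Trajectory(times=sol.t.copy(), states=states, stop_time=stop)


def target_diameter_event(patient: PatientParameters,
                          metastatic_only: bool = True):
    """Terminal event: any (metastatic) lesion reaches the target diameter."""
    n_target = diameter_to_cells(patient.target_diameter_cm,
                                 patient.kinetics.v_cell_ml)
    start = 1 if metastatic_only else 0

    def event(t, y):
        best = -n_target
        for j in range(start, N_TUMORS):
            off = TUMOR0 + j * TUMOR_BLOCK
            tot = np.clip(y[off + T_CANCER: off + T_CANCER + N_CLONES],
                          0.0, None).sum()
            best = max(best, tot - n_target)
        return best

    event.terminal = True
    event.direction = 1.0
    return event
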