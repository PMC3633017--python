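"""Deterministic integration of the model equations.

Uses a stiff-capable adaptive solver (LSODA by default): the TGF-beta model
mixes per-day rates spanning roughly 1e-12 to 1e2, which makes the system
moderately stiff.  Solutions are sampled on the whole-day grid 0..horizon,
matching the daily sampling of the stochastic engine.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import ComparisonError, IntegrationError, ScenarioError
from .models import MODEL_SPECIES, ScenarioSpec, rhs_for
from .trajectory import Trajectory

__all__ = ["integrate", "sample_daily", "steady_state_value"]

#: Most negative value tolerated from the integrator before it is treated as
#: a genuine violation rather than roundoff undershoot.
_UNDERSHOOT_TOL = -1e-9


def integrate(
    scenario: ScenarioSpec,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    method: str = "LSODA",
) -> Trajectory:
    """Solve the scenario's ODEs and sample the solution at whole days.

    Tiny negative undershoot (above ``-1e-9``) is clamped to zero; anything
    more negative, or a non-finite state, raises :class:`IntegrationError`
    naming the time of failure.
    """
    species = MODEL_SPECIES[scenario.model_id]
    rhs = rhs_for(scenario.model_id)
    params = scenario.params
    y0 = np.array([scenario.initial_state[name] for name in species], dtype=float)
    days = np.arange(scenario.horizon_days + 1, dtype=float)

    def field(t: float, y: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(y)):
            raise IntegrationError(
                f"non-finite state (blow-up) in {scenario.label or scenario.model_id!r} at t={t:.6g} d"
            )
        # The solver may probe marginally negative states; evaluate the
        # vector field on the clamped state.
        state = dict(zip(species, np.maximum(y, 0.0)))
        with np.errstate(over="ignore", invalid="ignore"):
            deriv = rhs(state, params)
        return np.array([deriv[name] for name in species])

    sol = solve_ivp(
        field,
        (0.0, float(scenario.horizon_days)),
        y0,
        method=method,
        t_eval=days,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(
            f"integration of {scenario.label or scenario.model_id!r} failed near t={t_fail:.6g} d: {sol.message}"
        )
    if not np.all(np.isfinite(sol.y)):
        bad = np.argwhere(~np.isfinite(sol.y))
        t_fail = days[bad[0][1]]
        raise IntegrationError(
            f"non-finite state (blow-up) in {scenario.label or scenario.model_id!r} at t={t_fail:.6g} d"
        )
    if sol.y.min() < _UNDERSHOOT_TOL:
        idx = np.argwhere(sol.y < _UNDERSHOOT_TOL)[0]
        raise IntegrationError(
            f"negative abundance {sol.y[tuple(idx)]:.3g} for {species[idx[0]]!r} at t={days[idx[1]]:.6g} d"
        )
    y = sol.y.copy()
    y[:, 0] = y0  # the left endpoint is the initial state, exactly
    values = {name: np.maximum(y[i], 0.0) for i, name in enumerate(species)}
    return Trajectory(
        time_days=days,
        values=values,
        model_id=scenario.model_id,
        run_kind="ode",
        label=scenario.label,
    )


def sample_daily(traj: Trajectory, horizon_days: Optional[int] = None) -> Trajectory:
    """Resample a trajectory to the whole-day grid 0..horizon.

    A trajectory that is already daily is returned unchanged (idempotence).
    Finer grids are linearly interpolated; the grid must cover every
    requested day.
    """
    if horizon_days is None:
        horizon_days = int(round(traj.time_days[-1]))
    days = np.arange(horizon_days + 1, dtype=float)
    if traj.time_days[0] > 0.0 or traj.time_days[-1] < days[-1]:
        raise ComparisonError(
            f"trajectory grid [{traj.time_days[0]:g}, {traj.time_days[-1]:g}] does not cover 0..{horizon_days}"
        )
    if traj.time_days.size == days.size and np.allclose(traj.time_days, days):
        return traj
    values = {name: np.interp(days, traj.time_days, series) for name, series in traj.values.items()}
    return Trajectory(
        time_days=days,
        values=values,
        model_id=traj.model_id,
        run_kind=traj.run_kind,
        run_seed=traj.run_seed,
        label=traj.label,
    )


def steady_state_value(
    traj: Trajectory,
    species: str,
    window_days: int,
    rel_range: float = 0.01,
) -> Optional[float]:
    """Plateau estimate over the trailing window, or ``None`` if no plateau.

    The series is declared flat when the range over the final
    ``window_days`` is below ``rel_range`` relative to the window mean; the
    estimate is then that mean.
    """
    if species not in traj.values:
        raise ScenarioError(
            f"unknown species {species!r}; available: {', '.join(traj.species)}"
        )
    horizon = traj.time_days[-1]
    if not 0 < window_days < horizon:
        raise ScenarioError(f"window_days must lie in (0, {horizon:g})")
    mask = traj.time_days >= horizon - window_days
    window = traj.values[species][mask]
    centre = float(np.mean(window))
    spread = float(np.max(window) - np.min(window))
    scale = max(abs(centre), np.finfo(float).tiny)
    if spread / scale >= rel_range:
        return None
    return centre
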