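"""Hill-type muscle-tendon dynamics with rigid or elastic tendon.

Given a prescribed muscle-tendon length trajectory L^MT(t) and a constant
activation a, these solvers compute the fiber length L^M over the cycle:

* rigid tendon (applied when L_o/L_s > 2, i.e. no or very short external
  tendon): the tendon length is fixed at slack length and the fiber length
  follows directly from the constant-height pennation geometry;
* elastic tendon: fiber and tendon forces are kept in equilibrium,
  F^T = F^M cos(alpha).  The static solver finds the equilibrium fiber
  length at zero fiber velocity by a bracketed root search; the dynamic
  solver integrates dL^M/dt, recovering the fiber velocity by inverting
  the force-velocity curve from the equilibrium constraint, with
  fixed-step RK4 on the gait grid.

The pennation model is the constant-height convention,
L^M sin(alpha) = L_o sin(alpha_o).  Activation is floored at 0.05 to avoid
the numerical singularity of the model as activation approaches zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .curves import CurveSet
from .model import MuscleTendonUnit

__all__ = [
    "MuscleState",
    "FiberTrajectory",
    "pennation_angle",
    "rigid_tendon_fiber_length",
    "static_equilibrium_fiber_length",
    "simulate_fiber_trajectory",
    "ACTIVATION_FLOOR",
    "FIBER_LENGTH_FLOOR",
]

#: activation lower bound (avoids the singularity as a -> 0)
ACTIVATION_FLOOR = 0.05
#: fiber-length floor, as a fraction of the optimal fiber length
FIBER_LENGTH_FLOOR = 0.01
#: pennation clamp
_MAX_PENNATION = math.radians(84.0)
_SIN_MAX_PENNATION = math.sin(_MAX_PENNATION)
#: minimum RK4 substeps per gait-grid sample in the elastic-tendon integrator
_SUBSTEPS = 10
#: substep ceiling; beyond it the ODE is so stiff that the quasi-static
#: solution is the accurate limit and the solver falls back to it
_SUBSTEPS_MAX = 400


@dataclass
class MuscleState:
    """Instantaneous muscle-tendon solution at one sample."""

    L_M: float          # fiber length, m
    V_M: float          # fiber velocity, m/s
    alpha: float        # pennation angle, rad
    L_T: float          # tendon length, m
    eps_T: float        # tendon strain
    F_M: float          # fiber force, N
    F_T: float          # tendon force, N
    activation: float
    converged: bool = True
    flag: str = ""


@dataclass
class FiberTrajectory:
    """Fiber-length solution of one unit over the gait cycle."""

    muscle_unit: str
    activation: float
    gait_percent: np.ndarray
    states: list[MuscleState]
    tendon_mode: str  # "rigid" or "elastic"
    L_o: float
    clamp_events: int = 0

    @property
    def L_M(self) -> np.ndarray:
        return np.array([s.L_M for s in self.states])

    @property
    def L_M_normalized(self) -> np.ndarray:
        return self.L_M / self.L_o


def pennation_angle(L_M: float, L_o: float, alpha_o: float) -> float:
    """Pennation angle under the constant-height model, clamped at 84 deg."""
    if alpha_o == 0.0:
        return 0.0
    s = min(max(L_o * math.sin(alpha_o) / L_M, 0.0), _SIN_MAX_PENNATION)
    return math.asin(s)


def rigid_tendon_fiber_length(L_MT: float, unit: MuscleTendonUnit) -> float:
    """Fiber length for an inextensible tendon at slack length."""
    w = unit.L_o * math.sin(unit.alpha_o)  # constant muscle height
    proj = max(L_MT - unit.L_s, 0.0)
    return max(math.hypot(proj, w), FIBER_LENGTH_FLOOR * unit.L_o)


def _fiber_force_normalized(
    L_M: float, a: float, unit: MuscleTendonUnit, curves: CurveSet
) -> tuple[float, float]:
    """(isometric fiber force / F_o, pennation) at fiber length L_M."""
    l_norm = L_M / unit.L_o
    alpha = pennation_angle(L_M, unit.L_o, unit.alpha_o)
    f = a * curves.active_fl_scalar(l_norm) + curves.passive_fl_scalar(l_norm)
    return f, alpha


def _state_from_fiber_length(
    L_MT: float,
    L_M: float,
    a: float,
    unit: MuscleTendonUnit,
    curves: CurveSet,
    V_M: float = 0.0,
    f_V: float = 1.0,
    converged: bool = True,
    flag: str = "",
) -> MuscleState:
    alpha = pennation_angle(L_M, unit.L_o, unit.alpha_o)
    L_T = L_MT - L_M * math.cos(alpha)
    eps = (L_T - unit.L_s) / unit.L_s if unit.L_s > 0 else 0.0
    l_norm = L_M / unit.L_o
    F_M = unit.F_o * (
        a * curves.active_fl_scalar(l_norm) * f_V + curves.passive_fl_scalar(l_norm)
    )
    F_T = unit.F_o * curves.tendon_scalar(eps) if unit.L_s > 0 else F_M * math.cos(alpha)
    return MuscleState(
        L_M=L_M, V_M=V_M, alpha=alpha, L_T=L_T, eps_T=eps,
        F_M=F_M, F_T=F_T, activation=a, converged=converged, flag=flag,
    )


def static_equilibrium_fiber_length(
    L_MT: float, a: float, unit: MuscleTendonUnit, curves: CurveSet
) -> MuscleState:
    """Equilibrium fiber length at zero fiber velocity.

    Solves F_o [a f_L + f_P] cos(alpha) = F_o f_T(eps) for L_M by a
    bracketed root search.  For rigid-tendon units (L_o/L_s > 2) the
    result is the rigid-tendon fiber length regardless of activation.
    """
    a = min(max(a, ACTIVATION_FLOOR), 1.0)
    if unit.rigid_tendon:
        L_M = rigid_tendon_fiber_length(L_MT, unit)
        state = _state_from_fiber_length(L_MT, L_M, a, unit, curves)
        # rigid tendon: force balance holds by construction
        state.F_T = state.F_M * math.cos(state.alpha)
        return state

    w = unit.L_o * math.sin(unit.alpha_o)
    lo = FIBER_LENGTH_FLOOR * unit.L_o
    lo = max(lo, w * 1.0000001) if w > 0 else lo
    # upper bound: fiber projection cannot exceed the whole MTU length
    hi = math.hypot(max(L_MT - 1e-9, 1e-9), w)

    def residual(L_M: float) -> float:
        f_mus, alpha = _fiber_force_normalized(L_M, a, unit, curves)
        L_T = L_MT - L_M * math.cos(alpha)
        eps = (L_T - unit.L_s) / unit.L_s
        return f_mus * math.cos(alpha) - curves.tendon_scalar(eps)

    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo == 0.0:
        root = lo
    elif r_hi == 0.0:
        root = hi
    elif r_lo * r_hi > 0.0:
        # no sign change: report the better boundary, flagged
        root = lo if abs(r_lo) < abs(r_hi) else hi
        state = _state_from_fiber_length(
            L_MT, root, a, unit, curves, converged=False, flag="unbracketed"
        )
        return state
    else:
        root = brentq(residual, lo, hi, xtol=1e-14, rtol=1e-15, maxiter=200)
    return _state_from_fiber_length(L_MT, root, a, unit, curves)


def simulate_fiber_trajectory(
    unit: MuscleTendonUnit,
    curves: CurveSet,
    L_MT_series: np.ndarray,
    a: float,
    mode: str = "auto",
    cycle_duration: float = 1.0,
    gait_percent: np.ndarray | None = None,
) -> FiberTrajectory:
    """Fiber-length trajectory for a prescribed L^MT series and activation.

    Parameters
    ----------
    mode:
        ``auto`` selects ``rigid`` when L_o/L_s > 2, else ``elastic``;
        ``static`` applies the zero-velocity equilibrium solver
        samplewise (quasi-static solution).
    cycle_duration:
        Gait-cycle duration in seconds; only the elastic integrator uses
        it (through the force-velocity curve).
    """
    a = min(max(a, ACTIVATION_FLOOR), 1.0)
    L_MT_series = np.asarray(L_MT_series, dtype=float)
    n = L_MT_series.size
    if gait_percent is None:
        gait_percent = np.linspace(0.0, 100.0, n)

    if mode == "auto":
        mode = "rigid" if unit.rigid_tendon else "elastic"
    if mode not in ("rigid", "elastic", "static"):
        raise ValueError(f"unknown tendon mode '{mode}'")

    clamp_events = 0
    states: list[MuscleState] = []

    if mode == "rigid" or (mode != "static" and unit.rigid_tendon):
        for L_MT in L_MT_series:
            L_M = rigid_tendon_fiber_length(L_MT, unit)
            st = _state_from_fiber_length(L_MT, L_M, a, unit, curves)
            st.F_T = st.F_M * math.cos(st.alpha)
            states.append(st)
        return FiberTrajectory(
            muscle_unit=unit.name, activation=a, gait_percent=gait_percent,
            states=states, tendon_mode="rigid", L_o=unit.L_o,
        )

    if mode == "static":
        for L_MT in L_MT_series:
            states.append(static_equilibrium_fiber_length(L_MT, a, unit, curves))
        return FiberTrajectory(
            muscle_unit=unit.name, activation=a, gait_percent=gait_percent,
            states=states, tendon_mode="elastic", L_o=unit.L_o,
        )

    # --- elastic tendon: integrate dL_M/dt with RK4 -------------------------
    dt_sample = cycle_duration / (n - 1) if n > 1 else cycle_duration
    v_scale = unit.V_max * unit.L_o  # m/s at normalized velocity 1

    # Equilibrium-tracking rate estimate: the linearized ODE relaxes at
    # lambda ~ k_T * v_scale / (L_s * a * slope_fv); low activation and a
    # stiff tendon make the system stiff, so the substep count scales with
    # the estimate (safety factor 3).  In the extreme stiff limit the
    # relaxation time is negligible against the cycle and the quasi-static
    # solution is the accurate one, so the solver falls back to it.
    lam = curves.max_tendon_slope * v_scale / (unit.L_s * a * 5.0)
    n_sub = max(_SUBSTEPS, math.ceil(3.0 * lam * dt_sample))
    if n_sub > _SUBSTEPS_MAX:
        for L_MT in L_MT_series:
            states.append(static_equilibrium_fiber_length(L_MT, a, unit, curves))
        return FiberTrajectory(
            muscle_unit=unit.name, activation=a, gait_percent=gait_percent,
            states=states, tendon_mode="elastic", L_o=unit.L_o,
        )
    h = dt_sample / n_sub
    floor = FIBER_LENGTH_FLOOR * unit.L_o
    fv_lo, fv_hi = 0.0, 1.4 * (1.0 - 1e-6)
    # normalized-velocity cap: near the eccentric plateau the curve inverse
    # blows up; lengthening is limited to 1.5 V_max to keep the ODE benign
    v_cap = 1.5

    t_samples = np.arange(n) * dt_sample

    def L_MT_at(t: float) -> float:
        # linear interpolation between gait samples (scalar fast path)
        if t <= 0.0:
            return float(L_MT_series[0])
        i = min(int(t / dt_sample), n - 2)
        frac = t / dt_sample - i
        return float(L_MT_series[i] + frac * (L_MT_series[i + 1] - L_MT_series[i]))

    def dLdt(t: float, L_M: float) -> float:
        nonlocal clamp_events
        L_M = max(L_M, floor)
        alpha = pennation_angle(L_M, unit.L_o, unit.alpha_o)
        L_T = L_MT_at(t) - L_M * math.cos(alpha)
        eps = (L_T - unit.L_s) / unit.L_s
        f_T = curves.tendon_scalar(eps)
        l_norm = L_M / unit.L_o
        f_L = curves.active_fl_scalar(l_norm)
        f_P = curves.passive_fl_scalar(l_norm)
        f_V = (f_T / math.cos(alpha) - f_P) / (a * max(f_L, 1e-6))
        if f_V < fv_lo or f_V > fv_hi:
            clamp_events += 1
            f_V = min(max(f_V, fv_lo), fv_hi)
        v_norm = curves.force_velocity_inverse_scalar(f_V)
        if v_norm > v_cap:
            clamp_events += 1
            v_norm = v_cap
        return v_norm * v_scale

    st0 = static_equilibrium_fiber_length(L_MT_series[0], a, unit, curves)
    L_M = st0.L_M
    states.append(st0)
    for i in range(1, n):
        t = t_samples[i - 1]
        for _ in range(n_sub):
            k1 = dLdt(t, L_M)
            k2 = dLdt(t + h / 2, L_M + h / 2 * k1)
            k3 = dLdt(t + h / 2, L_M + h / 2 * k2)
            k4 = dLdt(t + h, L_M + h * k3)
            L_M = L_M + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            if L_M < floor:
                L_M = floor
                clamp_events += 1
            t += h
        if not math.isfinite(L_M):
            raise FloatingPointError(
                f"unit '{unit.name}': non-finite fiber length at sample {i}"
            )
        V_M = dLdt(t_samples[i], L_M)
        v_norm = V_M / v_scale
        f_V = curves.force_velocity_scalar(v_norm)
        states.append(
            _state_from_fiber_length(
                L_MT_series[i], L_M, a, unit, curves, V_M=V_M, f_V=f_V
            )
        )
    return FiberTrajectory(
        muscle_unit=unit.name, activation=a, gait_percent=gait_percent,
        states=states, tendon_mode="elastic", L_o=unit.L_o,
        clamp_events=clamp_events,
    )
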