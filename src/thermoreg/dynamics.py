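"""Time integration, quasi-static hysteresis ramps, separatrix and basins.

The bi-stable band makes the model history dependent: slowly warming the
air from a cold start keeps the body on the failure (non-homeostatic)
branch until that branch is annihilated at a fold, where the state jumps to
the homeostatic branch; cooling back down, the jump happens at a different,
lower verge. The ramp protocol here makes "slowly" precise by fully
relaxing to equilibrium between small ambient-temperature steps, so the
detected jump temperatures converge to the fold verges as the step shrinks.

Within the bi-stable band the saddle's stable manifold (the separatrix)
divides the phase plane into the two basins of attraction; it is traced by
integrating backwards in time from tiny offsets along the saddle's stable
eigenvector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .bifurcation import classify_area
from .equilibria import Equilibrium, find_equilibria, jacobian
from .model import State, ThermoParams, rhs_array

__all__ = [
    "Trajectory",
    "RampResult",
    "BasinPartition",
    "integrate",
    "ramp_protocol",
    "ramp_continuous",
    "separatrix",
    "basin_map",
]


@dataclass(frozen=True)
class Trajectory:
    """One integrated trajectory with its convergence diagnostics."""

    t: np.ndarray  # [min]
    states: np.ndarray  # shape (n, 2): columns T_S, T_C [K]
    params: ThermoParams
    converged: bool
    final_residual: float  # max |rhs| at the terminal state [K/min]

    @property
    def final_state(self) -> State:
        return State(T_S=float(self.states[-1, 0]), T_C=float(self.states[-1, 1]))


@dataclass(frozen=True)
class RampResult:
    """Outcome of a quasi-static ambient-temperature ramp."""

    direction: str  # increasing | decreasing
    T_A_schedule: np.ndarray
    T_C_curve: np.ndarray  # converged core temperature at each T_A
    jump_T_A: float | None  # first T_A after which the branch changed
    branch_before: str | None
    branch_after: str | None


@dataclass(frozen=True)
class BasinPartition:
    """Basin labels on a phase-plane grid and/or the separatrix polyline."""

    T_S_values: np.ndarray | None
    T_C_values: np.ndarray | None
    labels: np.ndarray | None  # 'homeostatic' / 'non_homeostatic' per cell
    separatrix: np.ndarray | None  # polyline, shape (m, 2): (T_S, T_C)


def integrate(
    initial: State,
    params: ThermoParams,
    shape,
    horizon: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    to_convergence: bool = False,
    residual_tol: float = 1e-9,
    method: str = "LSODA",
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the model forward from ``initial`` for up to ``horizon`` min.

    With ``to_convergence=True`` the solve stops early once the vector-field
    residual drops below ``residual_tol`` (K/min); failing to get there
    within the horizon is flagged via ``converged=False`` and the partial
    trajectory is returned rather than raised.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")

    def f(t, y):
        return rhs_array(y, params, shape)

    events = None
    if to_convergence:
        def settled(t, y):
            return float(np.max(np.abs(rhs_array(y, params, shape)))) - residual_tol
        settled.terminal = True
        settled.direction = -1
        events = settled

    sol = solve_ivp(
        f,
        (0.0, horizon),
        initial.as_array(),
        method=method,
        rtol=rtol,
        atol=atol,
        events=events,
        t_eval=t_eval,
        dense_output=False,
    )
    states = sol.y.T
    res = float(np.max(np.abs(rhs_array(states[-1], params, shape))))
    # status 1 = the settled event fired; the residual then sits at the
    # threshold up to root-finding error, so trust the event
    converged = (not to_convergence) or sol.status == 1 or res <= residual_tol
    return Trajectory(t=sol.t, states=states, params=params,
                      converged=converged, final_residual=res)


def _relax(state: State, params: ThermoParams, shape, residual_tol: float,
           horizon: float = 50_000.0) -> State:
    traj = integrate(state, params, shape, horizon,
                     to_convergence=True, residual_tol=residual_tol)
    return traj.final_state


def _branch_label(state: State, params: ThermoParams, shape) -> str:
    """Label of the stable equilibrium nearest (in core T) to a settled state."""
    stable = [e for e in find_equilibria(params, shape) if e.stable]
    best = min(stable, key=lambda e: abs(e.T_C_star - state.T_C))
    return best.label


def ramp_protocol(
    start_T_A: float,
    end_T_A: float,
    params: ThermoParams,
    shape,
    *,
    step: float = 0.1,
    initial: State | None = None,
    residual_tol: float = 1e-8,
    jump_threshold: float = 1.0,
) -> RampResult:
    """Quasi-static ambient-temperature ramp with branch-jump detection.

    At each ambient temperature the state is relaxed to equilibrium
    (residual < ``residual_tol`` K/min) before T_A moves by ``step``; the
    converged core temperatures trace the occupied stable branch. A change
    of more than ``jump_threshold`` (default 1 K — well below the >= 2 K
    branch separation at the folds, far above solver noise) between
    consecutive steps marks the fold-induced jump; the first one is
    reported. The default initial state sits at the set point, which lies
    in the homeostatic basin wherever that branch exists.
    """
    if start_T_A == end_T_A:
        raise ValueError("start and end ambient temperatures must differ")
    if step <= 0:
        raise ValueError("step must be > 0")
    direction = "increasing" if end_T_A > start_T_A else "decreasing"
    signed = step if end_T_A > start_T_A else -step
    n = int(round((end_T_A - start_T_A) / signed))
    schedule = start_T_A + signed * np.arange(n + 1)

    if initial is None:
        initial = State(T_S=shape.T_C_set, T_C=shape.T_C_set)

    state = initial
    curve = np.empty(len(schedule))
    jump_T_A: float | None = None
    for i, T_A in enumerate(schedule):
        p = params.with_(T_A=float(T_A))
        state = _relax(state, p, shape, residual_tol)
        curve[i] = state.T_C
        if i > 0 and jump_T_A is None and abs(curve[i] - curve[i - 1]) > jump_threshold:
            jump_T_A = float(T_A)

    branch_before = branch_after = None
    if jump_T_A is not None:
        i_jump = int(np.argmin(np.abs(schedule - jump_T_A)))
        p_before = params.with_(T_A=float(schedule[i_jump - 1]))
        p_after = params.with_(T_A=float(schedule[i_jump]))
        branch_before = _branch_label(
            State(T_S=float(curve[i_jump - 1]), T_C=float(curve[i_jump - 1])),
            p_before,
            shape,
        )
        branch_after = _branch_label(
            State(T_S=float(curve[i_jump]), T_C=float(curve[i_jump])), p_after, shape
        )
    return RampResult(
        direction=direction,
        T_A_schedule=schedule,
        T_C_curve=curve,
        jump_T_A=jump_T_A,
        branch_before=branch_before,
        branch_after=branch_after,
    )


def ramp_continuous(
    start_T_A: float,
    end_T_A: float,
    params: ThermoParams,
    shape,
    *,
    rate: float,
    initial: State | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> RampResult:
    """Continuous ramp: T_A moves at ``rate`` K/min while the state evolves.

    A realism-oriented alternative to the quasi-static protocol; for slow
    rates its jump temperature approaches the quasi-static one (delayed
    slightly by the finite relaxation time after the fold).
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if initial is None:
        initial = State(T_S=shape.T_C_set, T_C=shape.T_C_set)
    sign = 1.0 if end_T_A > start_T_A else -1.0
    duration = abs(end_T_A - start_T_A) / rate

    def f(t, y):
        p = params.with_(T_A=start_T_A + sign * rate * t)
        return rhs_array(y, p, shape)

    sol = solve_ivp(f, (0.0, duration), initial.as_array(),
                    method="LSODA", rtol=rtol, atol=atol, max_step=duration / 400)
    schedule = start_T_A + sign * rate * sol.t
    curve = sol.y[1]
    jump_T_A = None
    dT = np.abs(np.diff(curve))
    big = np.nonzero(dT > 1.0)[0]
    if big.size:
        jump_T_A = float(schedule[big[0] + 1])
    return RampResult(
        direction="increasing" if sign > 0 else "decreasing",
        T_A_schedule=schedule,
        T_C_curve=curve,
        jump_T_A=jump_T_A,
        branch_before=None,
        branch_after=None,
    )


def _find_saddle(params: ThermoParams, shape) -> Equilibrium:
    eqs = find_equilibria(params, shape)
    saddles = [e for e in eqs if not e.stable]
    if not saddles:
        area = classify_area(params, shape)
        raise ValueError(
            f"no saddle at these parameters (area {area}); the separatrix "
            "and basins are only defined in the bi-stable area 3"
        )
    return saddles[0]


def separatrix(
    params: ThermoParams,
    shape,
    *,
    eps: float = 1e-6,
    window: tuple[float, float] | None = None,
    max_time: float = 2000.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> BasinPartition:
    """Trace the saddle's stable manifold, the basin boundary.

    Starting ``eps`` Kelvin from the saddle along +/- the stable
    eigenvector, the manifold is grown by integrating the time-reversed
    vector field until the trajectory leaves the phase window (default
    set point +/- 30 K in both coordinates). The two halves are joined
    through the saddle into a single polyline ordered along the manifold.
    """
    saddle = _find_saddle(params, shape)
    if window is None:
        window = (shape.T_C_set - 30.0, shape.T_C_set + 30.0)
    lo, hi = window

    J = jacobian(saddle.T_C_star, params, shape)
    eigvals, eigvecs = np.linalg.eig(J)
    i_stable = int(np.argmin(eigvals.real))
    if eigvals.real[i_stable] >= 0:
        raise ValueError("degenerate saddle: no stable eigendirection")
    v_s = np.real(eigvecs[:, i_stable])
    v_s = v_s / np.linalg.norm(v_s)

    def f_back(t, y):
        return -rhs_array(y, params, shape)

    def leave(t, y):
        return float(min(y[0] - lo, hi - y[0], y[1] - lo, hi - y[1]))
    leave.terminal = True
    leave.direction = -1

    halves = []
    x0 = saddle.state.as_array()
    for sgn in (+1.0, -1.0):
        sol = solve_ivp(f_back, (0.0, max_time), x0 + sgn * eps * v_s,
                        method="LSODA", rtol=rtol, atol=atol, events=leave,
                        max_step=5.0)
        halves.append(sol.y.T)
    poly = np.vstack([halves[0][::-1], x0[None, :], halves[1]])
    return BasinPartition(T_S_values=None, T_C_values=None, labels=None,
                          separatrix=poly)


def basin_map(
    params: ThermoParams,
    shape,
    *,
    T_S_range: tuple[float, float],
    T_C_range: tuple[float, float],
    n: int = 20,
    residual_tol: float = 1e-8,
) -> BasinPartition:
    """Label each point of a phase-plane grid by the attractor it reaches.

    Every grid point is integrated to convergence and assigned to the
    nearest stable equilibrium. Only meaningful in the bi-stable area 3
    (rejected elsewhere); with one attractor the partition is trivial.
    """
    _find_saddle(params, shape)  # raises outside area 3
    stable = [e for e in find_equilibria(params, shape) if e.stable]
    TS = np.linspace(*T_S_range, n)
    TC = np.linspace(*T_C_range, n)
    labels = np.empty((n, n), dtype=object)
    for j, tc in enumerate(TC):
        for i, ts in enumerate(TS):
            final = _relax(State(T_S=float(ts), T_C=float(tc)), params, shape,
                           residual_tol)
            best = min(stable, key=lambda e: (e.T_S_star - final.T_S) ** 2
                       + (e.T_C_star - final.T_C) ** 2)
            labels[j, i] = best.label
    return BasinPartition(T_S_values=TS, T_C_values=TC, labels=labels,
                          separatrix=None)
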