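"""Equilibria of the skin/core model and their stability.

Setting the skin equation to zero gives T_S* as an explicit average of
ambient and core temperature; substituting into the core equation yields a
single scalar relation between ambient temperature and the core temperature
at equilibrium,

    T_A = T_C* - C * f_S(T_C*),      C = (k1+k2) / (k1*k3 + k4*V_O2*(k1+k2)),

which parameterizes the whole equilibrium branch explicitly by T_C*. All
root finding here exploits that: global bracketing on a fine grid plus
bisection is complete and cheap, so no generic nonlinear solver is needed.

Stability of a fixed point reduces (det J > 0, trace J < 0) to the single
condition f_S'(T_C*) < k1*k3/(k1+k2) + k4*V_O2. Note that C times that
right-hand side is exactly 1, so the condition boundary coincides with the
stationary points of the branch map T_A(T_C*) — the folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import State, ThermoParams, rhs

__all__ = [
    "Equilibrium",
    "StabilityReport",
    "branch_coefficient",
    "ambient_for_core",
    "skin_for_core",
    "jacobian",
    "find_equilibria",
    "stability_report",
    "label_equilibrium",
    "homeostatic_sensitivity",
]

#: residual below which a point counts as an equilibrium [K/min]
RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the model with its local linearization."""

    T_C_star: float
    T_S_star: float
    eigenvalues: tuple[complex, complex]
    stable: bool
    label: str  # homeostatic | saddle | non_homeostatic

    @property
    def state(self) -> State:
        return State(T_S=self.T_S_star, T_C=self.T_C_star)


@dataclass(frozen=True)
class StabilityReport:
    """Jacobian diagnostics and the scalar stability condition at a fixed point.

    ``condition5_lhs`` is f_S'(T_C*); ``condition5_rhs`` is
    k1*k3/(k1+k2) + k4*V_O2. lhs < rhs is equivalent to det J > 0 together
    with trace J < 0 for this model.
    """

    jacobian: np.ndarray
    det: float
    trace: float
    condition5_lhs: float
    condition5_rhs: float

    @property
    def stable(self) -> bool:
        return self.condition5_lhs < self.condition5_rhs


def branch_coefficient(params: ThermoParams) -> float:
    """C = (k1+k2)/(k1*k3 + k4*V_O2*(k1+k2)) relating f_S to the T_A offset."""
    denom = params.k1 * params.k3 + params.k4 * params.V_O2 * (params.k1 + params.k2)
    if denom <= 0:
        raise ValueError("branch coefficient denominator must be positive")
    return (params.k1 + params.k2) / denom


def stability_threshold(params: ThermoParams) -> float:
    """Right-hand side of the stability condition: k1*k3/(k1+k2) + k4*V_O2."""
    return params.k1 * params.k3 / (params.k1 + params.k2) + params.k4 * params.V_O2


def ambient_for_core(T_C_star, params: ThermoParams, shape) -> float:
    """Ambient temperature at which T_C_star is an equilibrium core temperature."""
    C = branch_coefficient(params)
    return np.asarray(T_C_star, dtype=float) - C * np.asarray(shape.value(T_C_star))


def skin_for_core(T_C_star: float, params: ThermoParams) -> float:
    """Equilibrium skin temperature: flow-weighted mean of T_A and T_C*."""
    return (params.k1 * params.T_A + params.k2 * T_C_star) / (params.k1 + params.k2)


def jacobian(T_C_star: float, params: ThermoParams, shape) -> np.ndarray:
    """Jacobian of the vector field at a point with core temperature T_C_star."""
    fsp = float(np.asarray(shape.derivative(T_C_star)))
    return np.array(
        [
            [-(params.k1 + params.k2), params.k2],
            [params.k3, -params.k3 + fsp - params.k4 * params.V_O2],
        ]
    )


def _classify(T_C_star: float, params: ThermoParams, shape) -> Equilibrium:
    J = jacobian(T_C_star, params, shape)
    eigs = np.linalg.eigvals(J)
    stable = bool(np.all(eigs.real < 0))
    T_S_star = skin_for_core(T_C_star, params)
    eq = Equilibrium(
        T_C_star=float(T_C_star),
        T_S_star=float(T_S_star),
        eigenvalues=(complex(eigs[0]), complex(eigs[1])),
        stable=stable,
        label="",
    )
    return Equilibrium(
        T_C_star=eq.T_C_star,
        T_S_star=eq.T_S_star,
        eigenvalues=eq.eigenvalues,
        stable=eq.stable,
        label=label_equilibrium(eq, params, shape),
    )


def find_equilibria(
    params: ThermoParams,
    shape,
    *,
    grid_step: float = 0.01,
    xtol: float = 1e-10,
) -> list[Equilibrium]:
    """All equilibria at the given ambient temperature, sorted by core T.

    The scan window [T_C_set - W, T_C_set + W] with
    W = max(25 K, |T_A - T_C_set| + 10 K) covers every root: outside the
    saturating band the branch relation degenerates to T_C* = T_A. The grid
    step of 0.01 K is far below the minimal root separation at physiological
    parameters, so bracketing plus bisection is exhaustive.
    """
    set_pt = shape.T_C_set
    W = max(25.0, abs(params.T_A - set_pt) + 10.0)
    grid = np.arange(set_pt - W, set_pt + W + grid_step, grid_step)
    g = np.asarray(ambient_for_core(grid, params, shape)) - params.T_A

    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = g[i], g[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(
                brentq(
                    lambda t: float(ambient_for_core(t, params, shape)) - params.T_A,
                    grid[i],
                    grid[i + 1],
                    xtol=xtol,
                )
            )
    if g[-1] == 0.0:
        roots.append(float(grid[-1]))

    # dedupe tangential near-duplicates (possible exactly at a fold)
    roots.sort()
    unique: list[float] = []
    for r in roots:
        if not unique or r - unique[-1] > 10 * grid_step * 1e-3:
            unique.append(r)
    return [_classify(r, params, shape) for r in unique]


def stability_report(eq: Equilibrium, params: ThermoParams, shape) -> StabilityReport:
    """Jacobian, determinant/trace, and the scalar stability condition at ``eq``.

    Rejects points whose vector-field residual exceeds the equilibrium
    tolerance — the report is only meaningful at an actual fixed point.
    """
    res = rhs(eq.state, params, shape)
    if max(abs(res[0]), abs(res[1])) > 1e3 * RESIDUAL_TOL:
        raise ValueError(
            f"point (T_S={eq.T_S_star}, T_C={eq.T_C_star}) is not an equilibrium "
            f"(residual {max(abs(res[0]), abs(res[1])):.3g} K/min)"
        )
    J = jacobian(eq.T_C_star, params, shape)
    return StabilityReport(
        jacobian=J,
        det=float(np.linalg.det(J)),
        trace=float(np.trace(J)),
        condition5_lhs=float(np.asarray(shape.derivative(eq.T_C_star))),
        condition5_rhs=stability_threshold(params),
    )


def label_equilibrium(eq: Equilibrium, params: ThermoParams, shape) -> str:
    """Classify a fixed point as homeostatic, saddle, or non-homeostatic.

    Unstable points are saddles (the only unstable type this planar model
    admits). A stable point is homeostatic when its core temperature is at
    least as close to the set point as to the ambient temperature — a
    convention making "close to the set point" quantitative; ties resolve
    to homeostatic.
    """
    if not eq.stable:
        return "saddle"
    d_set = abs(eq.T_C_star - shape.T_C_set)
    d_amb = abs(eq.T_C_star - params.T_A)
    return "homeostatic" if d_set <= d_amb else "non_homeostatic"


def homeostatic_sensitivity(eq: Equilibrium, params: ThermoParams, shape) -> float:
    """Sensitivity dT_C*/dT_A of the equilibrium core temperature.

    By implicit differentiation of the branch relation,
    dT_C*/dT_A = 1 / (1 - C * f_S'(T_C*)). At the homeostatic equilibrium
    this shrinks toward zero as the regulatory peak p grows — steeper
    regulation pins the core harder — but never reaches zero for finite p.
    At a fold the denominator vanishes and the sensitivity diverges.
    """
    if not eq.stable:
        raise ValueError("sensitivity is defined on stable equilibria")
    C = branch_coefficient(params)
    denom = 1.0 - C * float(np.asarray(shape.derivative(eq.T_C_star)))
    if abs(denom) < 1e-14:
        return math.inf
    return 1.0 / denom
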