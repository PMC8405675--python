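"""Two-compartment skin/core model of human thermoregulation.

The body is reduced to two temperature states: skin ``T_S`` exchanges heat
with the ambient air (rate ``k1``) and with the core (rate ``k2``); the core
exchanges heat with the skin (rate ``k3``), loses heat to the air through
breathing (rate ``k4*V_O2``), and is actively driven back toward a set point
``T_C_set`` by a saturating regulatory term ``f_S(T_C)``:

    dT_S/dt = k1*(T_A - T_S) + k2*(T_C - T_S)
    dT_C/dt = k3*(T_S - T_C) + f_S(T_C) + k4*V_O2*(T_A - T_C)

The default saturating function is a Gaussian-kernel odd bump

    f_S(T_C) = p * (T_C_set - T_C) * exp(-v * (T_C_set - T_C)**2)

which is positive below the set point, negative above it, and decays to zero
far from it — regulation has finite reach, which is what makes a second,
"failure" equilibrium near ambient temperature possible.

All temperatures are absolute Kelvin; time is in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "State",
    "ThermoParams",
    "SaturationShape",
    "CustomSaturation",
    "ReducedParams",
    "saturation_value",
    "saturation_derivative",
    "saturation_area",
    "rhs",
    "reduce_params",
    "dimensionalize",
    "reduced_rhs",
]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def _require_positive(name: str, value: float) -> float:
    value = _require_finite(name, value)
    if value <= 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")
    return value


@dataclass(frozen=True)
class State:
    """Instantaneous skin and core temperature, in Kelvin."""

    T_S: float
    T_C: float

    def __post_init__(self) -> None:
        _require_positive("T_S", self.T_S)
        _require_positive("T_C", self.T_C)

    def as_array(self) -> np.ndarray:
        return np.array([self.T_S, self.T_C], dtype=float)


@dataclass(frozen=True)
class ThermoParams:
    """Physical parameters of the heat-exchange equations.

    Defaults are the model's reference values: equal skin/core exchange
    rates of 0.2 min^-1, a breathing coefficient k4 = 0.06 l^-1 at an
    oxygen uptake of 0.3 l/min, in 300 K air.
    """

    k1: float = 0.2  # skin <-> air [1/min]
    k2: float = 0.2  # skin <- core [1/min]
    k3: float = 0.2  # core <- skin [1/min]
    k4: float = 0.06  # breathing heat loss per litre of O2 [1/l]
    T_A: float = 300.0  # ambient air temperature [K]
    V_O2: float = 0.3  # oxygen consumption [l/min]

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4"):
            _require_positive(name, getattr(self, name))
        _require_positive("T_A", self.T_A)
        v = _require_finite("V_O2", self.V_O2)
        if v < 0:
            raise ValueError(f"V_O2 must be >= 0, got {v!r}")

    def with_(self, **kwargs: float) -> "ThermoParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SaturationShape:
    """Gaussian-kernel saturating function f_S and its derived geometry.

    ``p`` scales the peak regulatory rate, ``v`` is the reciprocal of the
    shape's variability (larger v = narrower regulation band), and
    ``support_eps`` is the relative level (of p) below which |f_S| counts
    as "approximately zero" when locating the effective support
    [theta1, theta2].
    """

    p: float = 2.0  # peak scale [1/min]
    v: float = 0.5  # reciprocal variability [1/K^2]
    T_C_set: float = 310.15  # core set point [K]
    support_eps: float = 1e-9  # relative |f_S| cut for theta1/theta2

    def __post_init__(self) -> None:
        _require_positive("p", self.p)
        _require_positive("v", self.v)
        _require_positive("T_C_set", self.T_C_set)
        _require_positive("support_eps", self.support_eps)

    @property
    def T_C_max(self) -> float:
        """Core temperature at the unique maximum of f_S (below set point)."""
        return self.T_C_set - 1.0 / math.sqrt(2.0 * self.v)

    @property
    def T_C_min(self) -> float:
        """Core temperature at the unique minimum of f_S (above set point)."""
        return self.T_C_set + 1.0 / math.sqrt(2.0 * self.v)

    def _support_halfwidth(self) -> float:
        # solve |u| * exp(-v u^2) = support_eps on the decaying branch
        eps = self.support_eps
        u0 = 1.0 / math.sqrt(2.0 * self.v)
        hi = u0
        f = lambda u: u * math.exp(-self.v * u * u) - eps
        while f(hi) > 0:
            hi *= 2.0
        return brentq(f, u0, hi, xtol=1e-12)

    @property
    def theta1(self) -> float:
        """Lower bound of the effective support of f_S."""
        return self.T_C_set - self._support_halfwidth()

    @property
    def theta2(self) -> float:
        """Upper bound of the effective support of f_S."""
        return self.T_C_set + self._support_halfwidth()

    # uniform evaluation protocol shared with CustomSaturation
    def value(self, T_C):
        u = self.T_C_set - np.asarray(T_C, dtype=float)
        return self.p * u * np.exp(-self.v * u * u)

    def derivative(self, T_C):
        u = self.T_C_set - np.asarray(T_C, dtype=float)
        return -self.p * np.exp(-self.v * u * u) * (1.0 - 2.0 * self.v * u * u)

    def area(self) -> float:
        return self.p / self.v

    def with_(self, **kwargs: float) -> "SaturationShape":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CustomSaturation:
    """Extension point: an arbitrary saturating function.

    Any pair of callables (value, derivative of value w.r.t. T_C) that
    satisfies the qualitative requirements — smooth, zero at the set point,
    positive below / negative above it, decaying beyond [theta1, theta2],
    single max/min — can stand in for the Gaussian-kernel shape. No symmetry
    is assumed; the area has no closed form and is always computed by
    quadrature over [theta1, theta2].
    """

    value_fn: Callable[[float], float]
    derivative_fn: Callable[[float], float]
    T_C_set: float
    theta1: float
    theta2: float

    def value(self, T_C):
        return np.vectorize(self.value_fn, otypes=[float])(T_C)[()]

    def derivative(self, T_C):
        return np.vectorize(self.derivative_fn, otypes=[float])(T_C)[()]

    def area(self) -> float:
        return saturation_area(self, method="quadrature")


@dataclass(frozen=True)
class ReducedParams:
    """Dimensionless parameterization after rescaling time by tau = k1*t.

    Exactly seven free parameters remain: a = k2/k1, b = k3/k1, c = p/k1,
    d = k4*V_O2/k1, plus v, T_A and T_C_set. k1 is retained only as the
    time-scale factor mapping tau back to minutes; it is not a free
    parameter of the reduced vector field.
    """

    a: float
    b: float
    c: float
    d: float
    v: float
    T_A: float
    T_C_set: float
    k1: float = field(compare=False)

    N_FREE_PARAMETERS = 7

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return ("a", "b", "c", "d", "v", "T_A", "T_C_set")


def saturation_value(T_C, shape: SaturationShape):
    """Regulatory heating/cooling rate f_S(T_C) in K/min.

    Positive when the core is below the set point (heating), negative above
    it (cooling), and vanishing at the set point and far from it.
    """
    T_C = np.asarray(T_C, dtype=float)
    if not np.all(np.isfinite(T_C)):
        raise ValueError("T_C must be finite")
    return shape.value(T_C)[()]


def saturation_derivative(T_C, shape: SaturationShape):
    """d f_S / d T_C in 1/min; zero exactly at T_C_max and T_C_min."""
    T_C = np.asarray(T_C, dtype=float)
    if not np.all(np.isfinite(T_C)):
        raise ValueError("T_C must be finite")
    return shape.derivative(T_C)[()]


def saturation_area(shape, method: str = "closed_form", rel_tol: float = 1e-10) -> float:
    """Area E_S = integral of |f_S| over core temperature, in K^2/min.

    For the Gaussian-kernel shape the improper integral over the real line
    is exactly p/v. ``method="quadrature"`` integrates |f_S| over the
    effective support [theta1, theta2] instead; the Gaussian tail beyond the
    support is negligible at the default support_eps.
    """
    if method == "closed_form":
        if not hasattr(shape, "area") or isinstance(shape, CustomSaturation):
            raise ValueError("closed form only available for SaturationShape")
        return shape.area()
    if method != "quadrature":
        raise ValueError(f"unknown method {method!r}")
    lo, hi = shape.theta1, shape.theta2
    # |f_S| has a kink at the set point; integrate each half separately
    total = 0.0
    for a, b in ((lo, shape.T_C_set), (shape.T_C_set, hi)):
        val, _ = quad(lambda t: abs(float(np.asarray(shape.value(t)))), a, b,
                      epsrel=rel_tol, limit=200)
        total += val
    return total


def rhs(state: State, params: ThermoParams, shape) -> tuple[float, float]:
    """Time derivatives (dT_S/dt, dT_C/dt) of the two-compartment model."""
    dTS = params.k1 * (params.T_A - state.T_S) + params.k2 * (state.T_C - state.T_S)
    dTC = (
        params.k3 * (state.T_S - state.T_C)
        + float(np.asarray(shape.value(state.T_C)))
        + params.k4 * params.V_O2 * (params.T_A - state.T_C)
    )
    return (dTS, dTC)


def rhs_array(y: np.ndarray, params: ThermoParams, shape) -> np.ndarray:
    """Vectorized right-hand side on a raw [T_S, T_C] array (solver plumbing)."""
    TS, TC = y[0], y[1]
    dTS = params.k1 * (params.T_A - TS) + params.k2 * (TC - TS)
    dTC = (
        params.k3 * (TS - TC)
        + np.asarray(shape.value(TC), dtype=float)
        + params.k4 * params.V_O2 * (params.T_A - TC)
    )
    return np.array([dTS, dTC])


def reduce_params(params: ThermoParams, shape: SaturationShape) -> ReducedParams:
    """Rescale time by tau = k1*t, collapsing nine parameters to seven.

    The ratios a=k2/k1, b=k3/k1, c=p/k1 and d=k4*V_O2/k1 fully determine the
    reduced vector field; k4 and V_O2 enter only through their product, so
    they are not individually recoverable from the reduced form.
    """
    if params.k1 <= 0:
        raise ValueError("k1 must be > 0 to rescale time")
    return ReducedParams(
        a=params.k2 / params.k1,
        b=params.k3 / params.k1,
        c=shape.p / params.k1,
        d=params.k4 * params.V_O2 / params.k1,
        v=shape.v,
        T_A=params.T_A,
        T_C_set=shape.T_C_set,
        k1=params.k1,
    )


def dimensionalize(reduced: ReducedParams) -> tuple[ThermoParams, SaturationShape]:
    """Inverse of :func:`reduce_params` up to the k4*V_O2 ambiguity.

    V_O2 is fixed to 1 l/min so that k4 carries the whole product d*k1;
    k2, k3, p and the product k4*V_O2 are recovered exactly.
    """
    k1 = reduced.k1
    params = ThermoParams(
        k1=k1,
        k2=reduced.a * k1,
        k3=reduced.b * k1,
        k4=reduced.d * k1 if reduced.d > 0 else 1e-30,
        T_A=reduced.T_A,
        V_O2=1.0 if reduced.d > 0 else 0.0,
    )
    shape = SaturationShape(p=reduced.c * k1, v=reduced.v, T_C_set=reduced.T_C_set)
    return params, shape


def reduced_rhs(y: np.ndarray, reduced: ReducedParams) -> np.ndarray:
    """Right-hand side of the dimensionless system in rescaled time tau."""
    TS, TC = y[0], y[1]
    u = reduced.T_C_set - TC
    dTS = (reduced.T_A - TS) + reduced.a * (TC - TS)
    dTC = (
        reduced.b * (TS - TC)
        + reduced.c * u * np.exp(-reduced.v * u * u)
        + reduced.d * (reduced.T_A - TC)
    )
    return np.array([dTS, dTC])
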