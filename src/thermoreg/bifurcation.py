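"""Fold (saddle-node) bifurcations and parameter-space region mapping.

Because the equilibrium branch is explicit — T_A(T_C*) = T_C* - C*f_S(T_C*)
— folds are simply the stationary points of that map, and since
C * (k1*k3/(k1+k2) + k4*V_O2) = 1 identically, they coincide with the core
temperatures where f_S' equals the stability threshold. For the
Gaussian-kernel shape, f_S' (an even function of u = T_C_set - T_C) rises
from -p at u=0, crosses zero at u^2 = 1/(2v), peaks at 2p*exp(-3/2) at
u^2 = 3/(2v) and decays to zero, so each side of the set point carries at
most two fold core temperatures: an *inner* one (between the zero of f_S'
and its peak) and an *outer* one (beyond the peak). Mapping them through
the branch relation gives the four allostatic verges of ambient
temperature — the jump points of the hysteresis loop.

Parameter space splits into three areas by which stable equilibria exist:
only the homeostatic one (area 1), only the non-homeostatic one (area 2),
or both (area 3, the bi-stable band). Sweeping T_A upward at bi-stable
defaults the areas appear in the order 2, 3, 1, 3, 2, with the four verge
temperatures as borders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .equilibria import (
    ambient_for_core,
    find_equilibria,
    stability_threshold,
)
from .model import SaturationShape, ThermoParams

__all__ = [
    "FoldPoint",
    "FoldSet",
    "RegionMap",
    "fold_points",
    "classify_area",
    "scan_vo2",
    "scan_shape",
    "region_map",
]

#: border names in the paper-table order, keyed by (side, position)
BORDER_OF = {
    ("cold", "inner"): "2-3",
    ("cold", "outer"): "3-1",
    ("hot", "outer"): "1-3",
    ("hot", "inner"): "3-2",
}

#: which branch the fold creates/destroys as T_A increases through the verge
ROLE_OF = {
    "2-3": "creates_homeostatic",
    "3-1": "destroys_non_homeostatic",
    "1-3": "creates_non_homeostatic",
    "3-2": "destroys_homeostatic",
}

BORDER_ORDER = ("2-3", "3-1", "1-3", "3-2")


@dataclass(frozen=True)
class FoldPoint:
    """One saddle-node point: fold core temperature and its verge in T_A."""

    T_C: float
    T_A: float
    side: str  # cold (below set point) | hot (above)
    position: str  # inner (closer to set point) | outer
    border: str  # which area border this verge forms, e.g. "3-1"
    role: str  # branch created/destroyed for increasing T_A


@dataclass(frozen=True)
class FoldSet:
    """The up-to-four folds of one parameter set."""

    points: tuple[FoldPoint, ...]

    @property
    def is_empty(self) -> bool:
        return len(self.points) == 0

    @property
    def fold_core_temps(self) -> tuple[float, ...]:
        return tuple(sorted(pt.T_C for pt in self.points))

    @property
    def fold_ambient_temps(self) -> tuple[float, ...]:
        return tuple(pt.T_A for pt in sorted(self.points, key=lambda p: p.T_C))

    def verges_by_border(self) -> dict[str, float]:
        return {pt.border: pt.T_A for pt in self.points}


@dataclass(frozen=True)
class RegionMap:
    """Grid classification of a two-parameter section into areas 1/2/3."""

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    labels: np.ndarray  # shape (len(axis2), len(axis1)), values in {1,2,3}
    borders: dict[str, list[tuple[float, float]]]  # border -> (axis1, axis2) pts


def _fsprime_of_u(u: float, shape: SaturationShape) -> float:
    return -shape.p * math.exp(-shape.v * u * u) * (1.0 - 2.0 * shape.v * u * u)


def fold_points(params: ThermoParams, shape: SaturationShape, *, xtol: float = 1e-10) -> FoldSet:
    """Locate all saddle-node points and their ambient-temperature verges.

    Solves f_S'(T_C) = k1*k3/(k1+k2) + k4*V_O2 on the two monotone segments
    of f_S' per side (delimited analytically by u^2 = 1/(2v) and 3/(2v)),
    then maps each root through the branch relation. If the peak of f_S'
    does not exceed the threshold, no fold exists anywhere: the system is
    mono-stable for every ambient temperature.
    """
    R = stability_threshold(params)
    peak = 2.0 * shape.p * math.exp(-1.5)
    if peak <= R:
        return FoldSet(points=())

    u_zero = 1.0 / math.sqrt(2.0 * shape.v)  # f_S' = 0
    u_peak = math.sqrt(3.0 / (2.0 * shape.v))  # f_S' maximal
    h = lambda u: _fsprime_of_u(u, shape) - R

    u_inner = brentq(h, u_zero, u_peak, xtol=xtol)
    hi = 2.0 * u_peak
    while h(hi) > 0:
        hi *= 2.0
    u_outer = brentq(h, u_peak, hi, xtol=xtol)

    pts = []
    for side, sign in (("cold", +1.0), ("hot", -1.0)):
        for position, u in (("inner", u_inner), ("outer", u_outer)):
            T_C = shape.T_C_set - sign * u
            T_A = float(ambient_for_core(T_C, params, shape))
            border = BORDER_OF[(side, position)]
            pts.append(
                FoldPoint(T_C=T_C, T_A=T_A, side=side, position=position,
                          border=border, role=ROLE_OF[border])
            )
    return FoldSet(points=tuple(pts))


def classify_area(params: ThermoParams, shape) -> int:
    """Area label of a parameter point: 1, 2, or 3.

    Area 1: only the homeostatic stable equilibrium exists. Area 2: only
    the non-homeostatic one. Area 3: both (three equilibria, outer two
    stable). The measure-zero case of exactly two equilibria (parameters
    sitting on a fold) resolves to the adjacent bi-stable area 3.
    """
    eqs = find_equilibria(params, shape)
    stable = [e for e in eqs if e.stable]
    if len(eqs) >= 2:
        return 3
    return 1 if stable[0].label == "homeostatic" else 2


def _round_to_grid(x: float, grid: float) -> float:
    return round(x / grid) * grid


def _verge_row(params: ThermoParams, shape: SaturationShape, rounding: float | None) -> dict:
    fs = fold_points(params, shape)
    row: dict[str, float | bool] = {"bistable": not fs.is_empty}
    verges = fs.verges_by_border()
    for border in BORDER_ORDER:
        key = f"area_{border.replace('-', '_')}"
        raw = verges.get(border, math.nan)
        row[key + "_raw"] = raw
        if rounding:
            row[key] = _round_to_grid(raw, rounding) if math.isfinite(raw) else math.nan
    return row


def scan_vo2(
    params: ThermoParams,
    shape: SaturationShape,
    vo2_values,
    rounding: float = 0.5,
) -> pd.DataFrame:
    """Verge table across oxygen-consumption values.

    One row per V_O2 with the four border ambient temperatures (areas 2-3,
    3-1, 1-3, 3-2), rounded to the reporting grid (default 0.5 K) alongside
    the raw high-precision values. Rows whose parameters admit no fold are
    flagged bistable=False with NaN verges.
    """
    rows = []
    for vo2 in vo2_values:
        row = {"V_O2": float(vo2)}
        row.update(_verge_row(params.with_(V_O2=float(vo2)), shape, rounding))
        rows.append(row)
    return pd.DataFrame(rows)


def scan_shape(
    params: ThermoParams,
    E_S: float,
    v_values,
    rounding: float = 0.5,
    T_C_set: float | None = None,
) -> pd.DataFrame:
    """Verge table across saturation shapes of equal regulatory area.

    Holds the area below the saturation curve fixed at E_S and sweeps the
    reciprocal-variability v, deriving the peak as p = E_S * v from the
    closed-form area. Narrower, taller shapes (larger v) widen the
    bi-stable band.
    """
    if E_S <= 0:
        raise ValueError("E_S must be > 0")
    set_pt = 310.15 if T_C_set is None else T_C_set
    rows = []
    for v in v_values:
        v = float(v)
        shape = SaturationShape(p=E_S * v, v=v, T_C_set=set_pt)
        row = {"v": v, "p": shape.p}
        row.update(_verge_row(params, shape, rounding))
        rows.append(row)
    return pd.DataFrame(rows)


_PARAM_AXES = {"T_A", "V_O2", "k1", "k2", "k3", "k4"}
_SHAPE_AXES = {"p", "v"}


def _with_axis(params: ThermoParams, shape: SaturationShape, name: str, value: float):
    if name in _PARAM_AXES:
        return params.with_(**{name: value}), shape
    if name in _SHAPE_AXES:
        return params, shape.with_(**{name: value})
    raise ValueError(f"unknown axis parameter {name!r}")


def region_map(
    params: ThermoParams,
    shape: SaturationShape,
    axis1: tuple[str, float, float, float],
    axis2: tuple[str, float, float, float],
) -> RegionMap:
    """Classify a two-parameter section into areas 1/2/3 and trace borders.

    Each axis is (parameter name, start, stop, step) over any of T_A, V_O2,
    k1..k4, p, v. When axis1 is T_A, the border curves are the exact fold
    verges recomputed per axis2 value; otherwise borders are extracted as
    grid-edge midpoints between differently labeled cells.
    """
    name1, lo1, hi1, step1 = axis1
    name2, lo2, hi2, step2 = axis2
    if not (hi1 > lo1 and hi2 > lo2 and step1 > 0 and step2 > 0):
        raise ValueError("axis ranges must be increasing with positive step")
    vals1 = np.arange(lo1, hi1 + 0.5 * step1, step1)
    vals2 = np.arange(lo2, hi2 + 0.5 * step2, step2)

    labels = np.zeros((len(vals2), len(vals1)), dtype=int)
    for j, v2 in enumerate(vals2):
        p2, s2 = _with_axis(params, shape, name2, float(v2))
        for i, v1 in enumerate(vals1):
            p1, s1 = _with_axis(p2, s2, name1, float(v1))
            labels[j, i] = classify_area(p1, s1)

    borders: dict[str, list[tuple[float, float]]] = {b: [] for b in BORDER_ORDER}
    if name1 == "T_A":
        for v2 in vals2:
            p2, s2 = _with_axis(params, shape, name2, float(v2))
            for pt in fold_points(p2, s2).points:
                if lo1 <= pt.T_A <= hi1:
                    borders[pt.border].append((pt.T_A, float(v2)))
    else:
        for j in range(len(vals2)):
            for i in range(len(vals1) - 1):
                a, b = labels[j, i], labels[j, i + 1]
                if a != b:
                    key = f"{a}-{b}"
                    borders.setdefault(key, []).append(
                        (0.5 * (vals1[i] + vals1[i + 1]), float(vals2[j]))
                    )
    return RegionMap(
        axis1_name=name1,
        axis1_values=vals1,
        axis2_name=name2,
        axis2_values=vals2,
        labels=labels,
        borders=borders,
    )
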