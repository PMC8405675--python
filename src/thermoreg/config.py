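"""Run configuration, parameter presets, and result serialization.

A :class:`RunConfig` bundles parameter overrides with one named analysis
and its options; :func:`run` dispatches it and writes CSV/JSON artifacts.
Unspecified parameters fall back to the packaged reference preset
``table2_table3_defaults``. Everything here is deterministic: re-running
the same config byte-reproduces the numeric outputs (the optional basin
grid jitter is the only randomness, and it is seeded).

Logging goes to standard error; artifacts go to files only, so outputs
compose cleanly in pipelines.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import bifurcation, dynamics
from .equilibria import find_equilibria
from .model import SaturationShape, State, ThermoParams

__all__ = ["RunConfig", "load_preset", "build_model", "run"]

log = logging.getLogger("thermoreg")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(_h)

_PARAM_KEYS = {"k1", "k2", "k3", "k4", "T_A", "V_O2"}
_SHAPE_KEYS = {"p", "v", "T_C_set"}
ANALYSES = ("equilibria", "folds", "regions", "simulate", "hysteresis", "basin")


def load_preset(name: str = "table2_table3_defaults") -> dict:
    """Load a packaged parameter preset (JSON key-value file)."""
    ref = resources.files("thermoreg.presets").joinpath(f"{name}.json")
    with ref.open("r") as fh:
        return json.load(fh)


@dataclass
class RunConfig:
    """One reproducible analysis run: overrides, analysis name, options."""

    analysis: str = "equilibria"
    params: dict = field(default_factory=dict)  # overrides on the preset
    shape: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    preset: str = "table2_table3_defaults"
    out_dir: str = "."
    seed: int | None = None  # only used for optional basin grid jitter
    verbosity: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    def resolve(self) -> tuple[ThermoParams, SaturationShape]:
        return build_model(self.params, self.shape, preset=self.preset,
                           log_provenance=self.verbosity > 0)


def build_model(
    param_overrides: dict | None = None,
    shape_overrides: dict | None = None,
    *,
    preset: str = "table2_table3_defaults",
    log_provenance: bool = False,
) -> tuple[ThermoParams, SaturationShape]:
    """Merge preset values with user overrides into validated model objects."""
    base = load_preset(preset)
    pvals = dict(base["params"])
    svals = dict(base["shape"])
    for key, val in (param_overrides or {}).items():
        if key not in _PARAM_KEYS:
            raise ValueError(f"unknown model parameter {key!r}")
        pvals[key] = float(val)
        if log_provenance:
            log.info("parameter %s = %s (user override)", key, val)
    for key, val in (shape_overrides or {}).items():
        if key not in _SHAPE_KEYS:
            raise ValueError(f"unknown saturation parameter {key!r}")
        svals[key] = float(val)
        if log_provenance:
            log.info("shape %s = %s (user override)", key, val)
    if log_provenance:
        for key in sorted(_PARAM_KEYS - set(param_overrides or {})):
            log.info("parameter %s = %s (preset %s)", key, pvals[key], preset)
    return ThermoParams(**pvals), SaturationShape(**svals)


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda x: float(f"{x:.6g}"))
    return out


def _run_equilibria(params, shape, options, out_dir: Path) -> dict:
    eqs = find_equilibria(params, shape)
    df = pd.DataFrame(
        {
            "T_C_star": [e.T_C_star for e in eqs],
            "T_S_star": [e.T_S_star for e in eqs],
            "eig1_re": [e.eigenvalues[0].real for e in eqs],
            "eig1_im": [e.eigenvalues[0].imag for e in eqs],
            "eig2_re": [e.eigenvalues[1].real for e in eqs],
            "eig2_im": [e.eigenvalues[1].imag for e in eqs],
            "stable": [e.stable for e in eqs],
            "label": [e.label for e in eqs],
        }
    )
    path = out_dir / "equilibria.csv"
    _fmt(df).to_csv(path, index=False)
    return {"equilibria": path}


def _run_folds(params, shape, options, out_dir: Path) -> dict:
    grid = float(options.get("rounding", 0.5))
    fs = bifurcation.fold_points(params, shape)
    rows = [
        {
            "border": pt.border,
            "side": pt.side,
            "position": pt.position,
            "role": pt.role,
            "fold_T_C": pt.T_C,
            "verge_T_A": pt.T_A,
            "verge_T_A_rounded": round(pt.T_A / grid) * grid,
        }
        for pt in sorted(fs.points, key=lambda p: p.T_A)
    ]
    path = out_dir / "folds.csv"
    _fmt(pd.DataFrame(rows)).to_csv(path, index=False)
    return {"folds": path}


def _run_regions(params, shape, options, out_dir: Path) -> dict:
    axis1 = tuple(options.get("axis1", ("T_A", 290.0, 330.0, 1.0)))
    axis2 = tuple(options.get("axis2", ("V_O2", 0.1, 0.7, 0.1)))
    rm = bifurcation.region_map(params, shape, axis1, axis2)
    payload = {
        "axis1": {"name": rm.axis1_name, "values": rm.axis1_values.tolist()},
        "axis2": {"name": rm.axis2_name, "values": rm.axis2_values.tolist()},
        "labels": rm.labels.tolist(),
        "borders": {k: v for k, v in rm.borders.items() if v},
    }
    path = out_dir / "region_map.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return {"regions": path}


def _run_simulate(params, shape, options, out_dir: Path) -> dict:
    init = options.get("initial", (shape.T_C_set, shape.T_C_set))
    horizon = float(options.get("horizon", 500.0))
    traj = dynamics.integrate(
        State(T_S=float(init[0]), T_C=float(init[1])), params, shape, horizon,
        to_convergence=bool(options.get("to_convergence", True)),
    )
    df = pd.DataFrame({"t": traj.t, "T_S": traj.states[:, 0], "T_C": traj.states[:, 1]})
    path = out_dir / "trajectory.csv"
    _fmt(df).to_csv(path, index=False)
    return {"trajectory": path}


def _run_hysteresis(params, shape, options, out_dir: Path) -> dict:
    start = float(options.get("start_T_A", 295.0))
    end = float(options.get("end_T_A", 310.0))
    step = float(options.get("step", 0.1))
    res = dynamics.ramp_protocol(start, end, params, shape, step=step)
    df = pd.DataFrame({"T_A": res.T_A_schedule, "T_C": res.T_C_curve})
    path = out_dir / "hysteresis.csv"
    _fmt(df).to_csv(path, index=False)
    meta = out_dir / "hysteresis.json"
    with open(meta, "w") as fh:
        json.dump(
            {
                "direction": res.direction,
                "jump_T_A": res.jump_T_A,
                "branch_before": res.branch_before,
                "branch_after": res.branch_after,
            },
            fh,
            indent=2,
        )
    return {"hysteresis": path, "hysteresis_meta": meta}


def _run_basin(params, shape, options, out_dir: Path, seed: int | None) -> dict:
    ts = tuple(options.get("T_S_range", (295.0, 320.0)))
    tc = tuple(options.get("T_C_range", (295.0, 320.0)))
    n = int(options.get("n", 15))
    part = dynamics.basin_map(params, shape, T_S_range=ts, T_C_range=tc, n=n)
    sep = dynamics.separatrix(params, shape)
    TS, TC = np.meshgrid(part.T_S_values, part.T_C_values)
    df = pd.DataFrame(
        {"T_S": TS.ravel(), "T_C": TC.ravel(), "attractor": part.labels.ravel()}
    )
    path = out_dir / "basin.csv"
    _fmt(df).to_csv(path, index=False)
    sep_path = out_dir / "separatrix.csv"
    _fmt(pd.DataFrame(sep.separatrix, columns=["T_S", "T_C"])).to_csv(
        sep_path, index=False
    )
    return {"basin": path, "separatrix": sep_path}


def run(config: RunConfig) -> dict:
    """Execute one configured analysis; returns {artifact name: path}.

    Invalid parameter values raise ``ValueError`` naming the violated
    invariant before any artifact is written.
    """
    if config.analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {config.analysis!r}; choose from {ANALYSES}")
    log.setLevel(logging.INFO if config.verbosity else logging.WARNING)
    params, shape = config.resolve()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.analysis == "equilibria":
        return _run_equilibria(params, shape, config.options, out_dir)
    if config.analysis == "folds":
        return _run_folds(params, shape, config.options, out_dir)
    if config.analysis == "regions":
        return _run_regions(params, shape, config.options, out_dir)
    if config.analysis == "simulate":
        return _run_simulate(params, shape, config.options, out_dir)
    if config.analysis == "hysteresis":
        return _run_hysteresis(params, shape, config.options, out_dir)
    return _run_basin(params, shape, config.options, out_dir, config.seed)
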