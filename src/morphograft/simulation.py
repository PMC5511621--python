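"""Scenario orchestration: graft runs, parameter sweeps, and area tracking.

A scenario builds the slice mesh and post-grafting initial state, advances
the coupled system with the adaptive engine, and tracks the displaced
tracer polygon whose shoelace area (relative to its reference area)
measures graft contraction over time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mgio
from .fem_engine import NumericalFailure, StepController, advance
from .geometry import (
    Mesh,
    StateFields,
    TracerSet,
    build_mesh,
    initial_state,
    place_tracers,
    shoelace_area,
)
from .params import ModelParameters, default_parameters
from .refine import refine_recoarsen

logger = logging.getLogger("morphograft")

__all__ = ["ScenarioConfig", "SimulationResult", "relative_area", "run_scenario", "sweep"]

#: display epochs of a full-year run; scaled proportionally for shorter runs
DEFAULT_EPOCH_DAYS = (7.0, 14.0, 29.0, 56.0, 180.0, 365.0)


@dataclass
class ScenarioConfig:
    """Everything needed to reproduce a scenario run deterministically."""

    params: ModelParameters = None
    half_width: float = 10.0
    target_edge: float = 1.0
    t_end: float = 365.0
    epochs: tuple = None            # None -> DEFAULT_EPOCH_DAYS scaled by t_end/365
    dt_init: float = 1e-2
    tol: float = 1e-3
    dt_min: float = 1e-9
    dt_max: float = 1.0
    quasi_static: bool = False
    n_tracers_per_side: int = 2
    refine_every: int = 0           # 0 disables adaptive refinement
    refine_threshold: float = 0.5
    max_refine_level: int = 2
    unwounded: bool = False         # control: no graft, homogeneous equilibrium
    output_dir: str | None = None
    snapshot_epochs: bool = False

    def __post_init__(self):
        if self.params is None:
            self.params = default_parameters()
        if self.epochs is None:
            scale = self.t_end / 365.0
            self.epochs = tuple(
                round(d * scale, 6) for d in DEFAULT_EPOCH_DAYS if d * scale <= self.t_end
            )
            if not self.epochs or self.epochs[-1] < self.t_end:
                self.epochs = self.epochs + (self.t_end,)


@dataclass
class SimulationResult:
    """Scalar time series plus state snapshots at the requested epochs."""

    time: np.ndarray
    relative_area: np.ndarray
    field_min: dict
    field_max: dict
    strain_max: np.ndarray          # max nodal Frobenius norm over time
    strain_l2: np.ndarray           # area-weighted L2 norm of the strain
    epochs: tuple
    snapshots: dict                 # epoch -> (Mesh, StateFields)
    final_mesh: Mesh = None
    final_state: StateFields = None
    config: ScenarioConfig = None

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.time, "relative_area": self.relative_area,
                "strain_max": self.strain_max, "strain_l2": self.strain_l2}
        for k in ("N", "M", "c", "rho"):
            data[f"{k}_min"] = self.field_min[k]
            data[f"{k}_max"] = self.field_max[k]
        return pd.DataFrame(data)

    @property
    def final_relative_area(self) -> float:
        return float(self.relative_area[-1])

    @property
    def min_relative_area(self) -> float:
        return float(np.min(self.relative_area))

    @property
    def time_of_min_area(self) -> float:
        return float(self.time[int(np.argmin(self.relative_area))])


def _barycentric_interpolate(mesh: Mesh, values: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Interpolate nodal values at reference-coordinate points (P1)."""
    tri = mesh.triangles
    a = mesh.ref_coords[tri[:, 0]]
    b = mesh.ref_coords[tri[:, 1]]
    c = mesh.ref_coords[tri[:, 2]]
    det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    out = np.empty((len(points),) + values.shape[1:])
    for k, p in enumerate(points):
        w1 = ((b[:, 0] - a[:, 0]) * (p[1] - a[:, 1]) - (p[0] - a[:, 0]) * (b[:, 1] - a[:, 1])) / det
        w0 = ((p[0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (p[1] - a[:, 1])) / det
        wa = 1.0 - w0 - w1
        inside = (wa >= -1e-10) & (w0 >= -1e-10) & (w1 >= -1e-10)
        e = int(np.argmax(inside))
        if not inside[e]:
            raise ValueError(f"tracer point {p} outside the reference mesh")
        wts = np.array([wa[e], w0[e], w1[e]])
        out[k] = np.tensordot(wts, values[tri[e]], axes=(0, 0))
    return out


def relative_area(tracers: TracerSet, mesh: Mesh, state: StateFields) -> float:
    """Area of the displaced tracer polygon over its reference area.

    Tracers are material points: their displacement is the P1 interpolant
    of the nodal displacement field at their reference coordinates.
    """
    disp = _barycentric_interpolate(mesh, state.u, tracers.ref_points)
    moved = tracers.ref_points + disp
    return shoelace_area(moved) / tracers.reference_area


def _record(result_rows, t, mesh, state, tracers):
    areas = mesh.element_areas()
    fro = state.strain_frobenius()
    ml = np.zeros(mesh.n_nodes)
    np.add.at(ml, mesh.triangles, (areas / 3.0)[:, None])
    row = {
        "time": t,
        "relative_area": relative_area(tracers, mesh, state),
        "strain_max": float(np.max(fro)),
        "strain_l2": float(np.sqrt(np.sum(ml * fro**2))),
    }
    for k in ("N", "M", "c", "rho"):
        row[f"{k}_min"] = float(np.min(getattr(state, k)))
        row[f"{k}_max"] = float(np.max(getattr(state, k)))
    result_rows.append(row)


def run_scenario(config: ScenarioConfig | None = None, **overrides) -> SimulationResult:
    """Run one full scenario; deterministic given a config.

    Pipeline: build mesh -> initial state -> adaptive time loop (with
    optional refine/recoarsen cycles) -> epoch snapshots and scalar series.
    """
    if config is None:
        config = ScenarioConfig(**overrides)
    params = config.params
    mesh = build_mesh(config.half_width, config.target_edge, symmetric=True)
    if config.unwounded:
        state = initial_state(mesh, params.replace(c_w=params.c_bar, I_w=1.0, s1=0.0))
        state.graft_marker[:] = 1.0
    else:
        state = initial_state(mesh, params)
    tracers = place_tracers(params, config.n_tracers_per_side)

    ctrl = StepController(
        dt=config.dt_init, tol=config.tol, dt_min=config.dt_min, dt_max=config.dt_max
    )
    rows: list[dict] = []
    _record(rows, 0.0, mesh, state, tracers)
    snapshots: dict = {}
    pending_epochs = list(config.epochs)
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    last_mesh, last_state = mesh, state
    try:
        while ctrl.time < config.t_end - 1e-9:
            target = pending_epochs[0] if pending_epochs else config.t_end
            ctrl.dt = min(ctrl.dt, max(target - ctrl.time, config.dt_min))
            mesh, state, ctrl, ok = advance(
                ctrl, mesh, state, params, quasi_static=config.quasi_static
            )
            if not ok:
                logger.debug("step rejected: dt -> %.3e (err %.3e)", ctrl.dt, ctrl.last_error)
                continue
            last_mesh, last_state = mesh, state
            _record(rows, ctrl.time, mesh, state, tracers)
            if (
                config.refine_every
                and ctrl.n_accepted % config.refine_every == 0
            ):
                mesh, state = refine_recoarsen(
                    mesh, state, config.refine_threshold, max_level=config.max_refine_level
                )
            while pending_epochs and ctrl.time >= pending_epochs[0] - 1e-9:
                ep = pending_epochs.pop(0)
                snapshots[ep] = (mesh.copy(), state.copy())
                if outdir and config.snapshot_epochs:
                    mgio.write_vtk(outdir / f"snapshot_t{ep:g}.vtk", mesh, state)
            logger.debug(
                "t=%.3f dt=%.3e err=%.2e nodes=%d", ctrl.time, ctrl.dt, ctrl.last_error,
                mesh.n_nodes,
            )
    except NumericalFailure:
        if outdir:
            mgio.save_checkpoint(outdir / "last_checkpoint.h5", last_mesh, last_state, ctrl.time)
        raise

    frame = pd.DataFrame(rows)
    result = SimulationResult(
        time=frame["time"].to_numpy(),
        relative_area=frame["relative_area"].to_numpy(),
        field_min={k: frame[f"{k}_min"].to_numpy() for k in ("N", "M", "c", "rho")},
        field_max={k: frame[f"{k}_max"].to_numpy() for k in ("N", "M", "c", "rho")},
        strain_max=frame["strain_max"].to_numpy(),
        strain_l2=frame["strain_l2"].to_numpy(),
        epochs=config.epochs,
        snapshots=snapshots,
        final_mesh=mesh,
        final_state=state,
        config=config,
    )
    if outdir:
        mgio.write_timeseries(outdir / "timeseries.csv", result.to_frame())
    return result


def sweep(
    zeta_values=None,
    a_c_III_values=None,
    configs: list[ScenarioConfig] | None = None,
    base_config: ScenarioConfig | None = None,
) -> pd.DataFrame:
    """Run a family of scenarios differing only in (zeta, a_c_III).

    Either pass explicit ``configs`` (>= 2) or value lists which are
    combined with the base config; numerics settings are identical across
    rows. Returns one row per run with the final relative area and the time
    of minimum area.
    """
    if configs is None:
        if base_config is None:
            base_config = ScenarioConfig()
        zs = list(zeta_values) if zeta_values is not None else [base_config.params.zeta]
        acs = (
            list(a_c_III_values)
            if a_c_III_values is not None
            else [base_config.params.a_c_III]
        )
        configs = []
        for z in zs:
            for ac in acs:
                p = base_config.params.replace(zeta=z, a_c_III=ac)
                cfg = ScenarioConfig(
                    **{**base_config.__dict__, "params": p, "epochs": base_config.epochs}
                )
                configs.append(cfg)
    if len(configs) < 2:
        raise ValueError("a sweep needs at least 2 configurations")
    rows = []
    for cfg in configs:
        res = run_scenario(cfg)
        rows.append(
            {
                "zeta": cfg.params.zeta,
                "a_c_III": cfg.params.a_c_III,
                "final_relative_area": res.final_relative_area,
                "min_relative_area": res.min_relative_area,
                "time_of_min_area": res.time_of_min_area,
            }
        )
    return pd.DataFrame(rows)
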