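"""Independent reference computations for validating the FEM engine.

The slice assumptions admit a spatially homogeneous reduction: with all
gradients and velocities zero, the constituents follow the plain reaction
ODEs and a scalar effective strain e obeys de/dt = -zeta k e with
k = (N + eta_II M) c / (1 + a_c_III c). This module integrates that
reduction with a generic stiff solver (an entirely separate numerical path
from the FEM engine) and compares the two on uniform fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import kinetics
from .fem_engine import StepController, advance
from .geometry import build_mesh, StateFields

__all__ = ["HomogeneousState", "integrate_homogeneous", "compare_fem_to_ode"]


@dataclass
class HomogeneousState:
    """Scalar constituents plus one scalar effective strain."""

    N: float
    M: float = 0.0
    c: float = 0.0
    rho: float = 0.0
    e: float = 0.0


@dataclass
class HomogeneousTrajectory:
    t: np.ndarray
    N: np.ndarray
    M: np.ndarray
    c: np.ndarray
    rho: np.ndarray
    e: np.ndarray
    sol: object  # dense-output interpolant

    def __call__(self, t):
        return self.sol(t)


def integrate_homogeneous(
    init: HomogeneousState,
    params,
    t_end: float,
    rtol: float = 1e-10,
    atol_scale: float = 1e-12,
    frozen_kinetics: bool = False,
    n_out: int = 200,
) -> HomogeneousTrajectory:
    """High-accuracy stiff integration of the homogeneous reduction.

    ``frozen_kinetics`` holds N, M, c, rho at their initial values so only
    the strain decays (its exact solution is e0 exp(-zeta k t)).
    """
    y0 = np.array([init.N, init.M, init.c, init.rho, init.e], dtype=float)
    if np.any(y0[:4] < 0):
        raise ValueError("initial constituents must be non-negative")

    def rhs(_t, y):
        N, M, c, rho, e = y
        p = kinetics.ConstituentPoint(N=max(N, 0), M=max(M, 0), c=max(c, 0), rho=max(rho, 0))
        k = (p.N + params.eta_II * p.M) * p.c / (1.0 + params.a_c_III * p.c)
        de = -params.zeta * k * e
        if frozen_kinetics:
            return [0.0, 0.0, 0.0, 0.0, de]
        return [
            kinetics.reaction_fibroblasts(p, params),
            kinetics.reaction_myofibroblasts(p, params),
            kinetics.reaction_signal(p, params),
            kinetics.reaction_collagen(p, params),
            de,
        ]

    scales = np.array(
        [max(init.N, params.N_bar, 1.0), max(init.M, params.N_bar, 1.0),
         max(init.c, params.c_w, 1e-10), max(init.rho, params.rho_bar, 1e-3),
         max(abs(init.e), 1.0)]
    )
    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method="LSODA", rtol=rtol,
        atol=atol_scale * scales, t_eval=t_eval, dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"homogeneous integration failed: {sol.message}")
    # clip solver round-off (far below atol) so stored constituents honor the
    # non-negativity invariant; the dense-output interpolant stays raw
    y = np.maximum(sol.y[:4], 0.0)
    return HomogeneousTrajectory(
        t=sol.t, N=y[0], M=y[1], c=y[2], rho=y[3], e=sol.y[4], sol=sol.sol,
    )


def compare_fem_to_ode(
    params,
    t_end: float,
    init: HomogeneousState | None = None,
    n_cells: int = 6,
    tol: float = 5e-6,
    dt_max: float = 0.25,
    floors: dict | None = None,
) -> float:
    """Max relative deviation between the FEM engine and the ODE reduction.

    The FEM run starts from spatially uniform fields with natural (no-flux,
    no-Dirichlet) boundary handling, under which uniform fields stay
    uniform and evolve by the reaction kinetics alone; the ODE oracle uses
    an independent stiff integrator. Returns max over time and fields of
    |FEM - ODE| / (|ODE| + floor).
    """
    if init is None:
        init = HomogeneousState(
            N=0.5 * params.N_bar, M=0.0, c=params.c_w, rho=params.rho_bar, e=0.0
        )
    if floors is None:
        floors = {
            "N": 1e-3 * params.N_bar, "M": 1e-3 * params.N_bar,
            "c": 1e-3 * max(params.c_w, 1e-30), "rho": 1e-3 * params.rho_bar,
        }
    traj = integrate_homogeneous(init, params, t_end)

    mesh = build_mesh(half_width=1.0, target_edge=2.0 / n_cells)
    n = mesh.n_nodes
    state = StateFields(
        N=np.full(n, init.N), M=np.full(n, init.M), c=np.full(n, init.c),
        rho=np.full(n, init.rho), u=np.zeros((n, 2)), v=np.zeros((n, 2)),
        eps22=np.zeros(n), eps23=np.zeros(n), eps33=np.zeros(n),
    )
    ctrl = StepController(dt=1e-3, tol=tol, dt_max=dt_max)
    worst = 0.0
    while ctrl.time < t_end - 1e-12:
        ctrl.dt = min(ctrl.dt, t_end - ctrl.time)
        mesh, state, ctrl, ok = advance(ctrl, mesh, state, params, use_dirichlet=False)
        if not ok:
            continue
        ref = traj(ctrl.time)  # [N, M, c, rho, e]
        for k, (name, vals) in enumerate(
            (("N", state.N), ("M", state.M), ("c", state.c), ("rho", state.rho))
        ):
            dev = np.max(np.abs(vals - ref[k])) / (abs(ref[k]) + floors[name])
            worst = max(worst, float(dev))
    return worst
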