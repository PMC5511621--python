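"""Moving-grid P1 finite-element engine for the coupled contraction model.

The grid is purely Lagrangian: nodes move with the material velocity, so
the discrete advective term vanishes and the dilution term z div(v) is
captured exactly by the change of the mass matrices between the old and the
moved configuration (Reynolds transport on the moving test functions).

One time step applies, in order: a semi-implicit momentum solve (implicit
viscosity, explicit elastic and traction forces), the strain evolution and
mesh motion, and a positivity-preserving transport update per constituent
(semi-implicit low order + Galerkin high order + Zalesak FCT, with Patankar
source splitting). Nonlinear coefficients are Picard-lagged at the start of
the step; an adaptive controller accepts or rejects steps by step-doubling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from . import kinetics, mechanics
from .fct import apply_fct, artificial_diffusion, extract_edges
from .geometry import Mesh, StateFields
from .mechanics import PlaneTensor, VelocityGradient

__all__ = [
    "ElementGeometry",
    "DiscreteOperatorSet",
    "StepController",
    "NumericalFailure",
    "InvertedElementError",
    "precompute_geometry",
    "assemble_transport",
    "solve_momentum",
    "update_strain",
    "transport_step",
    "step_once",
    "advance",
]


class NumericalFailure(RuntimeError):
    """A step could not be completed (NaN, singular system, ...)."""


class InvertedElementError(NumericalFailure):
    """An element turned inside out (non-positive area)."""

    def __init__(self, element_ids):
        self.element_ids = np.atleast_1d(element_ids)
        super().__init__(f"inverted element(s): {self.element_ids.tolist()}")


# --------------------------------------------------------------------------
# element geometry and basic operators
# --------------------------------------------------------------------------

@dataclass
class ElementGeometry:
    """Per-element P1 data on a given coordinate set."""

    coords: np.ndarray      # (n, 2)
    triangles: np.ndarray   # (m, 3)
    area: np.ndarray        # (m,)
    grads: np.ndarray       # (m, 3, 2) basis-function gradients


def precompute_geometry(coords: np.ndarray, triangles: np.ndarray) -> ElementGeometry:
    a = coords[triangles[:, 0]]
    b = coords[triangles[:, 1]]
    c = coords[triangles[:, 2]]
    det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    area = 0.5 * det
    bad = np.flatnonzero(area <= 0)
    if bad.size:
        raise InvertedElementError(bad)
    grads = np.empty((len(triangles), 3, 2))
    grads[:, 0, 0] = b[:, 1] - c[:, 1]
    grads[:, 0, 1] = c[:, 0] - b[:, 0]
    grads[:, 1, 0] = c[:, 1] - a[:, 1]
    grads[:, 1, 1] = a[:, 0] - c[:, 0]
    grads[:, 2, 0] = a[:, 1] - b[:, 1]
    grads[:, 2, 1] = b[:, 0] - a[:, 0]
    grads /= det[:, None, None]
    return ElementGeometry(coords, triangles, area, grads)


def lumped_mass(geo: ElementGeometry) -> np.ndarray:
    ml = np.zeros(len(geo.coords))
    np.add.at(ml, geo.triangles, (geo.area / 3.0)[:, None])
    return ml


def consistent_mass(geo: ElementGeometry) -> sparse.csr_matrix:
    m = len(geo.triangles)
    local = np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]]) / 12.0
    vals = geo.area[:, None, None] * local
    rows = np.repeat(geo.triangles, 3, axis=1).reshape(m, 3, 3)
    cols = np.tile(geo.triangles, (1, 3)).reshape(m, 3, 3)
    n = len(geo.coords)
    return sparse.coo_matrix(
        (vals.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n)
    ).tocsr()


def stiffness(geo: ElementGeometry, coeff: np.ndarray | float) -> sparse.csr_matrix:
    """Diffusion stiffness S_ij = sum_e k_e A_e (grad phi_i . grad phi_j)."""
    m = len(geo.triangles)
    k = np.broadcast_to(np.asarray(coeff, dtype=float), (m,))
    gg = np.einsum("eid,ejd->eij", geo.grads, geo.grads)
    vals = (k * geo.area)[:, None, None] * gg
    rows = np.repeat(geo.triangles, 3, axis=1).reshape(m, 3, 3)
    cols = np.tile(geo.triangles, (1, 3)).reshape(m, 3, 3)
    n = len(geo.coords)
    return sparse.coo_matrix(
        (vals.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n)
    ).tocsr()


def chemotaxis_matrix(
    geo: ElementGeometry, chi: float, grad_c: np.ndarray
) -> sparse.csr_matrix:
    """Discrete chemotactic transport: C_ij = chi sum_e (A_e/3)(grad c_e . grad phi_i).

    Contribution of the flux term chi z grad(c) integrated against grad phi_i;
    within an element the entry is independent of j.
    """
    m = len(geo.triangles)
    gb = np.einsum("ed,eid->ei", grad_c, geo.grads)  # (m, 3)
    vals = chi * (geo.area / 3.0)[:, None, None] * gb[:, :, None] * np.ones((1, 1, 3))
    rows = np.repeat(geo.triangles, 3, axis=1).reshape(m, 3, 3)
    cols = np.tile(geo.triangles, (1, 3)).reshape(m, 3, 3)
    n = len(geo.coords)
    return sparse.coo_matrix(
        (vals.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n)
    ).tocsr()


def element_gradient(geo: ElementGeometry, nodal: np.ndarray) -> np.ndarray:
    """Piecewise-constant gradient (m, 2) of a nodal P1 field."""
    return np.einsum("ei,eid->ed", nodal[geo.triangles], geo.grads)


def nodal_projection(geo: ElementGeometry, elem_vals: np.ndarray) -> np.ndarray:
    """Lumped L2 projection of piecewise-constant element values to nodes."""
    ml = lumped_mass(geo)
    out = np.zeros((len(geo.coords),) + np.shape(elem_vals)[1:])
    w = (geo.area / 3.0).reshape((-1,) + (1,) * (elem_vals.ndim - 1))
    for k in range(3):
        np.add.at(out, geo.triangles[:, k], w * elem_vals)
    return out / ml.reshape((-1,) + (1,) * (elem_vals.ndim - 1))


def element_mean(geo: ElementGeometry, nodal: np.ndarray) -> np.ndarray:
    return nodal[geo.triangles].mean(axis=1)


# --------------------------------------------------------------------------
# operator bundle (contract surface for the discretization)
# --------------------------------------------------------------------------

@dataclass
class DiscreteOperatorSet:
    """Assembled operators of the transport system on the current coordinates."""

    lumped: np.ndarray
    consistent: sparse.csr_matrix
    transport: dict          # constituent -> csr operator K (None for rho)
    production: dict         # constituent -> nodal production vector (>= 0)
    loss_rate: dict          # constituent -> nodal loss rate (>= 0)
    dirichlet_nodes: np.ndarray
    dirichlet_values: dict   # constituent -> scalar boundary value (rho absent)


def _transport_operators(geo: ElementGeometry, state: StateFields, params) -> dict:
    """K per constituent: Galerkin flux operators (advection-free Lagrangian)."""
    F_e = element_mean(geo, state.N + state.M)
    S_cells = stiffness(geo, params.D_F * F_e, )
    grad_c = element_gradient(geo, state.c)
    C = chemotaxis_matrix(geo, params.chi_F, grad_c)
    K_cells = (-S_cells + C).tocsr()
    K_c = (-stiffness(geo, params.D_c)).tocsr()
    return {"N": K_cells, "M": K_cells, "c": K_c, "rho": None}


def assemble_transport(
    mesh: Mesh, state: StateFields, params, geo: ElementGeometry | None = None
) -> DiscreteOperatorSet:
    """Linear FE discretization of the constituent conservation laws.

    Assembled on the CURRENT (moved) coordinates; the mesh velocity equals
    the material velocity, so no discrete advection term appears and the
    dilution term is carried by the time-varying mass matrices. Collagen is
    flux-free (no stiffness block). Boundary rows are Dirichlet for N, M, c.
    """
    if geo is None:
        geo = precompute_geometry(mesh.cur_coords, mesh.triangles)
    point = kinetics.ConstituentPoint(N=state.N, M=state.M, c=state.c, rho=state.rho)
    split = kinetics.reaction_terms_split(point, params)
    return DiscreteOperatorSet(
        lumped=lumped_mass(geo),
        consistent=consistent_mass(geo),
        transport=_transport_operators(geo, state, params),
        production={k: split[k][0] for k in split},
        loss_rate={k: np.broadcast_to(split[k][1], state.N.shape).copy() for k in split},
        dirichlet_nodes=np.flatnonzero(mesh.boundary_mask),
        dirichlet_values={"N": params.N_bar, "M": params.M_bar, "c": params.c_bar},
    )


# --------------------------------------------------------------------------
# momentum and strain
# --------------------------------------------------------------------------

def _vector_block(geo: ElementGeometry, mu1, mu2) -> sparse.csr_matrix:
    """Vector-P1 operator of mu1 sym(grad v) + mu2 div(v) I (per-element moduli)."""
    m = len(geo.triangles)
    mu1 = np.broadcast_to(np.asarray(mu1, dtype=float), (m,))
    mu2 = np.broadcast_to(np.asarray(mu2, dtype=float), (m,))
    g = geo.grads  # (m, 3, 2)
    gg = np.einsum("eid,ejd->eij", g, g)
    K = np.empty((m, 3, 2, 3, 2))
    for a in range(2):
        for b in range(2):
            term = 0.5 * mu1[:, None, None] * (
                (a == b) * gg + np.einsum("ei,ej->eij", g[:, :, b], g[:, :, a])
            )
            term = term + mu2[:, None, None] * np.einsum("ei,ej->eij", g[:, :, a], g[:, :, b])
            K[:, :, a, :, b] = geo.area[:, None, None] * term
    dof = (2 * geo.triangles[:, :, None] + np.arange(2)[None, None, :]).reshape(m, 6)
    rows = np.repeat(dof, 6, axis=1).reshape(m, 6, 6)
    cols = np.tile(dof, (1, 6)).reshape(m, 6, 6)
    n2 = 2 * len(geo.coords)
    return sparse.coo_matrix(
        (K.reshape(m, 6, 6).ravel(), (rows.ravel(), cols.ravel())), shape=(n2, n2)
    ).tocsr()


def _stress_force(geo: ElementGeometry, state: StateFields, params) -> np.ndarray:
    """Nodal force vector of the elastic stress and myofibroblast traction.

    Weak form of div(sigma_el) + div(psi): -int (sigma_el + psi I) : grad phi.
    """
    e22 = element_mean(geo, state.eps22)
    e23 = element_mean(geo, state.eps23)
    e33 = element_mean(geo, state.eps33)
    rho_e = element_mean(geo, state.rho)
    M_e = element_mean(geo, state.M)
    k_el = mechanics.youngs_modulus(rho_e, params) / (1.0 + params.nu)
    lam = params.nu / (1.0 - 2.0 * params.nu)
    tr = e22 + e33
    s22 = k_el * (e22 + lam * tr)
    s23 = k_el * e23
    s33 = k_el * (e33 + lam * tr)
    psi = mechanics.traction_stress(M_e, rho_e, params).t22
    s22 = s22 + psi
    s33 = s33 + psi
    # f[2i+a] = -A * sum_l sigma[a,l] b_i[l]
    n = len(geo.coords)
    f = np.zeros((n, 2))
    fa = -geo.area[:, None] * (s22[:, None] * geo.grads[:, :, 0] + s23[:, None] * geo.grads[:, :, 1])
    fb = -geo.area[:, None] * (s23[:, None] * geo.grads[:, :, 0] + s33[:, None] * geo.grads[:, :, 1])
    np.add.at(f[:, 0], geo.triangles, fa)
    np.add.at(f[:, 1], geo.triangles, fb)
    return f.ravel()


def solve_momentum(
    mesh: Mesh, state: StateFields, params, dt: float, quasi_static: bool = False,
    geo: ElementGeometry | None = None,
) -> np.ndarray:
    """Semi-implicit velocity update on the current coordinates.

    The viscous stress and the first-order elastic stress increment
    (sigma_el at eps^n + dt sym(grad v^{n+1})) are implicit in v^{n+1};
    the current elastic stress, the traction and the advective dilution
    term are explicit. The implicit elastic increment renders the fast
    visco-elastic relaxation mode unconditionally stable. Boundary
    velocity is constrained to zero exactly (splinted far field).
    """
    if geo is None:
        geo = precompute_geometry(mesh.cur_coords, mesh.triangles)
    n = mesh.n_nodes
    rho_e = element_mean(geo, state.rho)
    k_el = mechanics.youngs_modulus(rho_e, params) / (1.0 + params.nu)
    lam = params.nu / (1.0 - 2.0 * params.nu)
    K = _vector_block(
        geo, params.mu_1 + dt * k_el, params.mu_2 + dt * k_el * lam
    )
    f = _stress_force(geo, state, params)
    ml = lumped_mass(geo)
    ml2 = np.repeat(ml, 2)
    v_old = state.v.ravel()
    if quasi_static:
        A = K
        b = f
    else:
        div_e = np.einsum("eid,eid->e", state.v[geo.triangles], geo.grads)
        div_v = nodal_projection(geo, div_e)
        adv = params.rho_t * ml2 * v_old * np.repeat(div_v, 2)
        A = sparse.diags(params.rho_t * ml2 / dt) + K
        b = params.rho_t * ml2 * v_old / dt + f - adv
    # Dirichlet: v = 0 on the box boundary
    fixed = np.repeat(mesh.boundary_mask, 2)
    A = _constrain(A, fixed)
    b = np.where(fixed, 0.0, b)
    v_new = spsolve(A, b)
    if not np.all(np.isfinite(v_new)):
        raise NumericalFailure("momentum solve produced non-finite velocity")
    return v_new.reshape(n, 2)


def velocity_gradient_nodes(
    mesh: Mesh, v: np.ndarray, geo: ElementGeometry | None = None
) -> VelocityGradient:
    """Nodal in-plane velocity gradient by lumped projection."""
    if geo is None:
        geo = precompute_geometry(mesh.cur_coords, mesh.triangles)
    L_e = np.einsum("eia,eib->eab", v[geo.triangles], geo.grads)  # (m, 2, 2)
    L_n = nodal_projection(geo, L_e)
    return VelocityGradient(
        l22=L_n[:, 0, 0], l23=L_n[:, 0, 1], l32=L_n[:, 1, 0], l33=L_n[:, 1, 1]
    )


def update_strain(
    mesh: Mesh, state: StateFields, params, dt: float,
    geo: ElementGeometry | None = None,
) -> None:
    """Advance strain, displacement, and the moving grid in place.

    Strain uses the same explicit stage as the transport update; the mesh
    current coordinates are reference + displacement after every step.
    """
    L = velocity_gradient_nodes(mesh, state.v, geo)
    eps = PlaneTensor(state.eps22, state.eps23, state.eps33)
    point = kinetics.ConstituentPoint(N=state.N, M=state.M, c=state.c, rho=state.rho)
    G = mechanics.growth_tensor(eps, point, params)
    rate = mechanics.strain_rate(eps, L, G)
    state.eps22 = state.eps22 + dt * rate.t22
    state.eps23 = state.eps23 + dt * rate.t23
    state.eps33 = state.eps33 + dt * rate.t33
    state.u = state.u + dt * state.v
    mesh.cur_coords = mesh.ref_coords + state.u


# --------------------------------------------------------------------------
# FCT transport step
# --------------------------------------------------------------------------

def transport_step(
    geo_old: ElementGeometry,
    geo_new: ElementGeometry,
    ops: DiscreteOperatorSet,
    state_fields: dict,
    dt: float,
    use_dirichlet: bool = True,
) -> dict:
    """One positivity-preserving transport update for all constituents.

    The old/new geometry pair carries the Lagrangian dilution; ``ops`` holds
    the operators assembled on the new coordinates with Picard-lagged
    coefficients.
    """
    ML0 = lumped_mass(geo_old)
    MC0 = consistent_mass(geo_old)
    ML1 = ops.lumped
    MC1 = ops.consistent
    fixed = np.zeros(len(ML1), dtype=bool)
    if use_dirichlet:
        fixed[ops.dirichlet_nodes] = True

    # shared per-operator data (N and M use the same transport operator)
    cache: dict[int, tuple] = {}

    def _op_data(K):
        key = id(K)
        if key not in cache:
            D = artificial_diffusion(K)
            Lmat = (K + D).tocsr()
            edges = extract_edges(MC1, D)
            i, j = edges[:, 0], edges[:, 1]
            mc0 = np.asarray(MC0[i, j]).ravel()
            mc1 = np.asarray(MC1[i, j]).ravel()
            dd = np.asarray(D[i, j]).ravel()
            cache[key] = (D, Lmat, edges, mc0, mc1, dd)
        return cache[key]

    out = {}
    for name in ("N", "M", "c", "rho"):
        z0 = state_fields[name]
        P = np.broadcast_to(ops.production[name], z0.shape)
        lam = np.broadcast_to(ops.loss_rate[name], z0.shape)
        K = ops.transport[name]
        if K is None:
            # flux-free constituent: diagonal update (dilution + reactions)
            z = (ML0 * z0 + dt * ML1 * P) / (ML1 * (1.0 + dt * lam))
            out[name] = z
            continue

        D, Lmat, edges, mc0, mc1, dd = _op_data(K)
        A_lo = sparse.diags(ML1 * (1.0 + dt * lam)) - dt * Lmat
        b_lo = ML0 * z0 + dt * ML1 * P
        A_hi = (MC1 + sparse.diags(dt * ML1 * lam) - dt * K).tocsr()
        b_hi = MC0 @ z0 + dt * ML1 * P

        if use_dirichlet and name in ops.dirichlet_values:
            bc = ops.dirichlet_values[name]
            A_lo = _constrain(A_lo, fixed)
            A_hi = _constrain(A_hi, fixed)
            b_lo = np.where(fixed, bc, b_lo)
            b_hi = np.where(fixed, bc, b_hi)

        z_L = spsolve(A_lo.tocsr(), b_lo)
        z_H = spsolve(A_hi, b_hi)
        if not (np.all(np.isfinite(z_L)) and np.all(np.isfinite(z_H))):
            raise NumericalFailure(f"transport solve for {name} produced non-finite values")
        z_L = np.maximum(z_L, 0.0)

        i, j = edges[:, 0], edges[:, 1]
        fluxes = (
            -mc0 * (z0[i] - z0[j])
            + (mc1 + dt * dd) * (z_H[i] - z_H[j])
        )
        z = apply_fct(
            z_L, z_H, ML1, edges, fluxes, prelimit=True,
            locked=fixed if use_dirichlet else None,
        )
        out[name] = np.maximum(z, 0.0)
    return out


def _constrain(A: sparse.spmatrix, fixed: np.ndarray) -> sparse.csr_matrix:
    """Replace the rows of ``fixed`` dofs by identity rows."""
    free = sparse.diags((~fixed).astype(float))
    pin = sparse.diags(fixed.astype(float))
    return (free @ A + pin).tocsr()


# --------------------------------------------------------------------------
# full step and adaptive controller
# --------------------------------------------------------------------------

@dataclass
class StepController:
    """Adaptive step-size controller (step-doubling local error estimate)."""

    dt: float = 1e-2
    tol: float = 1e-3
    dt_min: float = 1e-8
    dt_max: float = 1.0
    growth: float = 1.5
    safety: float = 0.9
    n_accepted: int = 0
    n_rejected: int = 0
    time: float = 0.0
    last_dt: float = 0.0
    last_error: float = field(default=0.0)

    def __post_init__(self):
        self.dt = float(np.clip(self.dt, self.dt_min, self.dt_max))


def step_once(
    mesh: Mesh,
    state: StateFields,
    params,
    dt: float,
    quasi_static: bool = False,
    use_dirichlet: bool = True,
) -> tuple[Mesh, StateFields]:
    """One split step: momentum -> strain/mesh motion -> FCT transport."""
    mesh = mesh.copy()
    state = state.copy()
    geo_old = precompute_geometry(mesh.cur_coords, mesh.triangles)
    state.v = solve_momentum(mesh, state, params, dt, quasi_static=quasi_static, geo=geo_old)
    update_strain(mesh, state, params, dt, geo=geo_old)
    geo_new = precompute_geometry(mesh.cur_coords, mesh.triangles)
    ops = assemble_transport(mesh, state, params, geo=geo_new)
    fields = {k: getattr(state, k) for k in StateFields.CONSTITUENTS}
    new_fields = transport_step(geo_old, geo_new, ops, fields, dt, use_dirichlet)
    for k, v in new_fields.items():
        setattr(state, k, v)
    return mesh, state


_FIELD_FLOORS = {"N": 1.0, "M": 1.0, "c": 1e-12, "rho": 1e-3}


def _step_error(params, s1: StateFields, s2: StateFields) -> float:
    """Max relative discrepancy between a full step and two half steps."""
    err = 0.0
    for k in StateFields.CONSTITUENTS:
        a, b = getattr(s1, k), getattr(s2, k)
        scale = max(np.max(np.abs(b)), _FIELD_FLOORS[k])
        err = max(err, float(np.max(np.abs(a - b))) / scale)
    # velocity is a slaved (quasi-stationary) variable: its accuracy shows up
    # in u and eps, which are controlled below
    escale = max(float(np.max(s2.strain_frobenius())), 1e-3)
    for k in ("eps22", "eps23", "eps33"):
        err = max(err, float(np.max(np.abs(getattr(s1, k) - getattr(s2, k)))) / escale)
    err = max(err, float(np.max(np.abs(s1.u - s2.u))) / max(float(np.max(np.abs(s2.u))), 1e-6))
    return err


def advance(
    controller: StepController,
    mesh: Mesh,
    state: StateFields,
    params,
    quasi_static: bool = False,
    use_dirichlet: bool = True,
):
    """Attempt one adaptive step; returns (mesh', state', controller, accepted).

    The local error is estimated by comparing one dt step against two dt/2
    steps; the more accurate half-step result is kept on acceptance. Error
    exactly at tolerance is accepted. Rejected steps halve dt; underflow of
    dt below its lower bound raises.
    """
    dt = controller.dt
    try:
        mesh_f, state_f = step_once(mesh, state, params, dt, quasi_static, use_dirichlet)
        mesh_h, state_h = step_once(mesh, state, params, dt / 2, quasi_static, use_dirichlet)
        mesh_h, state_h = step_once(mesh_h, state_h, params, dt / 2, quasi_static, use_dirichlet)
        err = _step_error(params, state_f, state_h)
        if not np.isfinite(err):
            raise NumericalFailure("non-finite error estimate")
    except NumericalFailure:
        err = np.inf

    if err <= controller.tol:
        controller.n_accepted += 1
        controller.last_error = err
        controller.last_dt = dt
        controller.time += dt
        factor = controller.growth
        if err > 0:
            factor = min(controller.growth, controller.safety * (controller.tol / err) ** 0.5)
        controller.dt = float(np.clip(dt * max(factor, 0.3), controller.dt_min, controller.dt_max))
        return mesh_h, state_h, controller, True
    controller.n_rejected += 1
    controller.last_error = err
    if dt <= controller.dt_min * (1 + 1e-12):
        raise NumericalFailure(
            f"time step underflow: dt = {dt:.3e} rejected with error {err:.3e}"
        )
    controller.dt = max(dt / 2, controller.dt_min)
    return mesh, state, controller, False
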