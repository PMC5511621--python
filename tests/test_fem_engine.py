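"""Discrete operators, momentum/strain updates, and transport invariants."""

import numpy as np
import pytest

import morphograft as mg
from morphograft.fem_engine import (
    assemble_transport,
    consistent_mass,
    lumped_mass,
    precompute_geometry,
    solve_momentum,
    step_once,
    transport_step,
    update_strain,
    velocity_gradient_nodes,
    InvertedElementError,
    NumericalFailure,
    StepController,
    advance,
)
from morphograft.geometry import StateFields


def inert(params, fluxes=True):
    """Parameter set with all reaction rates zeroed (transport only);
    ``fluxes=False`` also switches off every dispersal coefficient."""
    p = params.replace(
        r_F=0.0, k_F=0.0, delta_N=0.0, delta_M=0.0, k_c=0.0, delta_c=0.0,
        k_rho=0.0, delta_rho=0.0, xi=0.0, zeta=0.0,
    )
    if not fluxes:
        p = p.replace(D_F=0.0, chi_F=0.0, D_c=0.0)
    return p


def uniform_state(mesh, N=1.0, M=0.0, c=0.0, rho=0.0):
    n = mesh.n_nodes
    return StateFields(
        N=np.full(n, float(N)), M=np.full(n, float(M)), c=np.full(n, float(c)),
        rho=np.full(n, float(rho)), u=np.zeros((n, 2)), v=np.zeros((n, 2)),
        eps22=np.zeros(n), eps23=np.zeros(n), eps33=np.zeros(n),
    )


class TestBasicOperators:
    def test_single_triangle_lumped_mass(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])  # area 1
        tris = np.array([[0, 1, 2]])
        geo = precompute_geometry(coords, tris)
        assert geo.area[0] == pytest.approx(1.0)
        np.testing.assert_allclose(lumped_mass(geo), 1.0 / 3.0)

    def test_consistent_mass_row_sums_match_lumped(self, coarse_mesh):
        geo = precompute_geometry(coarse_mesh.cur_coords, coarse_mesh.triangles)
        mc = consistent_mass(geo)
        np.testing.assert_allclose(
            np.asarray(mc.sum(axis=1)).ravel(), lumped_mass(geo), rtol=1e-12
        )

    def test_inverted_element_reports_id(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0], [0.5, -1.0]])
        tris = np.array([[0, 1, 2], [0, 1, 3]])  # second is clockwise
        with pytest.raises(InvertedElementError) as err:
            precompute_geometry(coords, tris)
        assert 1 in err.value.element_ids

    def test_constant_field_zero_transport_residual(self, coarse_mesh, params):
        state = uniform_state(coarse_mesh, N=params.N_bar, c=3e-9, rho=params.rho_bar)
        ops = assemble_transport(coarse_mesh, state, params)
        for name in ("N", "M", "c"):
            K = ops.transport[name]
            residual = K @ np.full(coarse_mesh.n_nodes, 7.0)
            np.testing.assert_allclose(residual, 0.0, atol=1e-10)

    def test_collagen_has_no_stiffness_block(self, coarse_mesh, params):
        state = uniform_state(coarse_mesh, N=1.0)
        ops = assemble_transport(coarse_mesh, state, params)
        assert ops.transport["rho"] is None


class TestMomentum:
    def test_no_forcing_stays_at_rest(self, coarse_mesh, params):
        state = uniform_state(coarse_mesh, N=params.N_bar, rho=params.rho_bar)
        v = solve_momentum(coarse_mesh, state, params, dt=0.1)
        np.testing.assert_allclose(v, 0.0, atol=1e-14)

    def test_uniform_traction_forces_only_patch_rim(self, params):
        """The discrete divergence of a constant stress vanishes inside the patch."""
        from morphograft.fem_engine import _stress_force

        mesh = mg.build_mesh(10.0, 2.0)
        geo = precompute_geometry(mesh.cur_coords, mesh.triangles)
        n = mesh.n_nodes
        state = uniform_state(mesh, rho=params.R_const)
        inside = np.max(np.abs(mesh.ref_coords), axis=1) < 4.0 - 1e-9
        state.M = np.where(inside, 100.0, 0.0)
        f = _stress_force(geo, state, params).reshape(n, 2)
        # nodes whose entire element star carries the same uniform psi
        elem_psi = state.M[mesh.triangles].mean(axis=1)
        deep, rim = [], []
        for i in range(n):
            stars = np.any(mesh.triangles == i, axis=1)
            vals = elem_psi[stars]
            (deep if np.allclose(vals, vals[0]) else rim).append(i)
        np.testing.assert_allclose(f[deep], 0.0, atol=1e-10)
        assert np.max(np.abs(f[rim])) > 1e-3

    def test_boundary_velocity_exactly_zero(self, params):
        mesh = mg.build_mesh(10.0, 2.0)
        state = mg.initial_state(mesh, params)
        # traction localized in the graft pulls the tissue inward
        state.M = 200.0 * (1.0 - state.graft_marker)
        v = solve_momentum(mesh, state, params, dt=0.1)
        np.testing.assert_array_equal(v[mesh.boundary_mask], 0.0)
        assert np.max(np.abs(v)) > 0.0

    def test_quasi_static_agrees_with_inertial(self, params):
        """Once the (hours-scale) inertial transient has relaxed, both modes agree."""
        mesh = mg.build_mesh(10.0, 2.0)
        state = mg.initial_state(mesh, params)
        state.M = 200.0 * (1.0 - state.graft_marker)
        v2 = solve_momentum(mesh, state, params, dt=0.5, quasi_static=True)
        for _ in range(30):  # iterate the inertial update on a frozen state
            state.v = solve_momentum(mesh, state, params, dt=0.5)
        scale = np.max(np.abs(v2))
        assert scale > 0
        assert np.max(np.abs(state.v - v2)) / scale < 1e-3


class TestStrainUpdate:
    def test_frozen_without_velocity_or_growth(self, coarse_mesh, params):
        state = uniform_state(coarse_mesh, N=params.N_bar, rho=params.rho_bar)
        state.eps22[:] = 0.05
        mesh = coarse_mesh.copy()
        update_strain(mesh, state, params, dt=0.5)
        np.testing.assert_allclose(state.eps22, 0.05, atol=1e-15)
        np.testing.assert_allclose(state.eps23, 0.0, atol=1e-15)

    def test_homogeneous_stretch_grows_trace(self, params):
        """L = d I over one step: tr(eps) grows by ~ 2 d dt (1 - tr(eps))."""
        mesh = mg.build_mesh(10.0, 2.0)
        state = uniform_state(mesh, N=params.N_bar, rho=params.rho_bar)
        d, dt = 0.01, 0.1
        state.v = d * mesh.cur_coords.copy()
        update_strain(mesh, state, params, dt)
        interior = ~mesh.boundary_mask
        tr = state.eps22 + state.eps33
        np.testing.assert_allclose(tr[interior], 2 * d * dt, rtol=1e-9)

    def test_mesh_follows_displacement(self, params):
        mesh = mg.build_mesh(10.0, 2.5)
        state = uniform_state(mesh, N=params.N_bar, rho=params.rho_bar)
        state.v = np.full((mesh.n_nodes, 2), [0.3, -0.1])
        update_strain(mesh, state, params, dt=0.5)
        np.testing.assert_allclose(mesh.cur_coords, mesh.ref_coords + state.u, atol=1e-14)
        np.testing.assert_allclose(
            state.u, np.broadcast_to([0.15, -0.05], state.u.shape), atol=1e-14
        )


class TestTransport:
    def test_rigid_translation_transports_exactly(self, params):
        """Lagrangian moving grid: translating the mesh leaves nodal values fixed."""
        p = inert(params, fluxes=False)
        mesh = mg.build_mesh(10.0, 2.0)
        state = mg.initial_state(mesh, p)
        geo_old = precompute_geometry(mesh.cur_coords, mesh.triangles)
        moved = mesh.copy()
        moved.cur_coords = mesh.cur_coords + np.array([0.7, -0.3])
        geo_new = precompute_geometry(moved.cur_coords, moved.triangles)
        ops = assemble_transport(moved, state, p, geo=geo_new)
        fields = {k: getattr(state, k) for k in StateFields.CONSTITUENTS}
        out = transport_step(geo_old, geo_new, ops, fields, dt=0.5, use_dirichlet=False)
        for k in StateFields.CONSTITUENTS:
            np.testing.assert_allclose(out[k], fields[k], rtol=1e-10, atol=1e-10 * params.c_w)

    def test_mass_conserved_over_many_steps(self, params):
        """Zero reactions, no-flux boundary: each constituent's integral is constant."""
        p = inert(params)
        mesh = mg.build_mesh(10.0, 2.0)
        state = mg.initial_state(mesh, p)
        geo = precompute_geometry(mesh.cur_coords, mesh.triangles)
        ml = lumped_mass(geo)
        start = {k: float(ml @ getattr(state, k)) for k in StateFields.CONSTITUENTS}
        fields = {k: getattr(state, k) for k in StateFields.CONSTITUENTS}
        ops = assemble_transport(mesh, state, p, geo=geo)
        for _ in range(100):
            fields = transport_step(geo, geo, ops, fields, dt=0.25, use_dirichlet=False)
        for k in StateFields.CONSTITUENTS:
            total = float(ml @ fields[k])
            if start[k] == 0.0:
                assert total == 0.0
            else:
                assert total == pytest.approx(start[k], rel=1e-8)

    def test_positivity_with_sharp_front(self, params):
        """FCT keeps the signal non-negative next to a steep initial front."""
        mesh = mg.build_mesh(10.0, 1.25)
        state = mg.initial_state(mesh, params)
        m, s = mesh.copy(), state.copy()
        for _ in range(20):
            m, s = step_once(m, s, params, dt=0.2)
            for k in StateFields.CONSTITUENTS:
                assert np.min(getattr(s, k)) >= 0.0


class TestAdvance:
    def test_equilibrium_accepts_and_grows_dt(self, params):
        mesh = mg.build_mesh(10.0, 2.5)
        state = uniform_state(
            mesh, N=params.N_bar, M=params.M_bar, c=params.c_bar, rho=params.rho_bar
        )
        ctrl = StepController(dt=0.05, tol=1e-3, dt_max=1.0)
        dts = []
        m, s = mesh, state
        for _ in range(8):
            m, s, ctrl, ok = advance(ctrl, m, s, params)
            assert ok
            dts.append(ctrl.dt)
            assert ctrl.last_error <= 1e-8
        assert dts[-1] == pytest.approx(1.0)  # grown to the cap

    @pytest.mark.filterwarnings("ignore:Matrix is exactly singular")
    def test_nan_field_rejects_and_halves(self, params):
        mesh = mg.build_mesh(10.0, 2.5)
        state = mg.initial_state(mesh, params)
        state.c[5] = np.nan
        ctrl = StepController(dt=0.2, tol=1e-3, dt_min=0.05)
        _, _, ctrl, ok = advance(ctrl, mesh, state, params)
        assert not ok
        assert ctrl.dt == pytest.approx(0.1)

    @pytest.mark.filterwarnings("ignore:Matrix is exactly singular")
    def test_dt_underflow_raises(self, params):
        mesh = mg.build_mesh(10.0, 2.5)
        state = mg.initial_state(mesh, params)
        state.c[5] = np.nan
        ctrl = StepController(dt=0.1, tol=1e-3, dt_min=0.1)
        with pytest.raises(NumericalFailure, match="underflow"):
            advance(ctrl, mesh, state, params)
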