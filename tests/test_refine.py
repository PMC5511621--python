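"""Conforming bisection refinement and recoarsement."""

import numpy as np
import pytest

import morphograft as mg
from morphograft.refine import element_indicator, recoarsen, refine_elements, refine_recoarsen


def audit_conformity(mesh):
    """Brute-force hanging-node audit: no node may lie strictly inside
    an edge of an element that does not contain it."""
    coords = mesh.ref_coords
    for e, tri in enumerate(mesh.triangles):
        for k in range(3):
            a, b = coords[tri[k]], coords[tri[(k + 1) % 3]]
            ab = b - a
            L2 = ab @ ab
            for i in range(mesh.n_nodes):
                if i in tri:
                    continue
                t = ((coords[i] - a) @ ab) / L2
                if 1e-9 < t < 1 - 1e-9:
                    closest = a + t * ab
                    if np.linalg.norm(coords[i] - closest) < 1e-9:
                        return False, (e, i)
    return True, None


def mass_integrals(mesh, state):
    areas = mesh.element_areas()
    return {
        k: float(np.sum(areas * getattr(state, k)[mesh.triangles].sum(axis=1) / 3.0))
        for k in ("N", "M", "c", "rho")
    }


@pytest.fixture()
def small_setup(params):
    mesh = mg.build_mesh(10.0, 4.0)
    state = mg.initial_state(mesh, params)
    return mesh, state


class TestRefine:
    def test_no_flags_no_change(self, small_setup):
        mesh, state = small_setup
        m2, s2 = refine_elements(mesh, state, np.zeros(mesh.n_elements, dtype=bool))
        assert m2 is mesh and s2 is state

    def test_single_flag_keeps_conformity(self, small_setup):
        mesh, state = small_setup
        flags = np.zeros(mesh.n_elements, dtype=bool)
        flags[7] = True
        m2, s2 = refine_elements(mesh, state, flags)
        assert m2.n_elements == mesh.n_elements + 2  # flagged + hypotenuse partner
        ok, where = audit_conformity(m2)
        assert ok, where
        assert np.all(m2.element_areas() > 0)
        assert np.sum(m2.element_areas()) == pytest.approx(400.0, rel=1e-9)

    def test_second_level_propagates(self, small_setup):
        """Refining a child whose longest edge faces a coarse neighbor must
        propagate the bisection to keep the mesh conforming."""
        mesh, state = small_setup
        flags = np.zeros(mesh.n_elements, dtype=bool)
        flags[7] = True
        m2, s2 = refine_elements(mesh, state, flags)
        child = int(np.argmax(m2.level == 1))
        flags2 = np.zeros(m2.n_elements, dtype=bool)
        flags2[child] = True
        m3, s3 = refine_elements(m2, s2, flags2)
        ok, where = audit_conformity(m3)
        assert ok, where
        assert np.sum(m3.element_areas()) == pytest.approx(400.0, rel=1e-9)

    def test_linear_field_interpolated_exactly(self, small_setup, params):
        mesh, state = small_setup
        state.N = 5.0 + 2.0 * mesh.ref_coords[:, 0] - 3.0 * mesh.ref_coords[:, 1]
        flags = np.zeros(mesh.n_elements, dtype=bool)
        flags[[3, 11]] = True
        m2, s2 = refine_elements(mesh, state, flags)
        expected = 5.0 + 2.0 * m2.ref_coords[:, 0] - 3.0 * m2.ref_coords[:, 1]
        np.testing.assert_allclose(s2.N, expected, rtol=1e-12)

    def test_mass_conserved_on_refine(self, small_setup):
        mesh, state = small_setup
        before = mass_integrals(mesh, state)
        flags = np.zeros(mesh.n_elements, dtype=bool)
        flags[[0, 5, 9]] = True
        m2, s2 = refine_elements(mesh, state, flags)
        after = mass_integrals(m2, s2)
        for k in before:
            if before[k]:
                assert after[k] == pytest.approx(before[k], rel=1e-12)

    def test_level_cap_warns_and_skips(self, small_setup):
        mesh, state = small_setup
        flags = np.zeros(mesh.n_elements, dtype=bool)
        flags[2] = True
        m2, s2 = refine_elements(mesh, state, flags)
        child = int(np.argmax(m2.level == 1))
        flags2 = np.zeros(m2.n_elements, dtype=bool)
        flags2[child] = True
        with pytest.warns(UserWarning, match="cap"):
            m3, _ = refine_elements(m2, s2, flags2, max_level=1)
        assert m3.n_elements == m2.n_elements


class TestRecoarsen:
    def test_round_trip_recovers_parent_mesh(self, small_setup):
        mesh, state = small_setup
        flags = np.zeros(mesh.n_elements, dtype=bool)
        flags[[7, 20]] = True
        m2, s2 = refine_elements(mesh, state, flags)
        m3, s3 = recoarsen(m2, s2)
        assert m3.n_nodes == mesh.n_nodes
        assert m3.n_elements == mesh.n_elements

        def canon(m):
            return sorted(
                tuple(sorted(map(tuple, np.round(m.ref_coords[t], 9)))) for t in m.triangles
            )

        assert canon(m3) == canon(mesh)

    def test_round_trip_preserves_fields(self, small_setup):
        mesh, state = small_setup
        flags = np.zeros(mesh.n_elements, dtype=bool)
        flags[7] = True
        m2, s2 = refine_elements(mesh, state, flags)
        m3, s3 = recoarsen(m2, s2)
        order = np.lexsort(m3.ref_coords.T)
        base = np.lexsort(mesh.ref_coords.T)
        np.testing.assert_allclose(s3.N[order], state.N[base], rtol=1e-12)
        np.testing.assert_allclose(s3.c[order], state.c[base], rtol=1e-12, atol=1e-25)

    def test_partial_star_not_coarsened(self, small_setup):
        """A midpoint whose star contains a further-refined element must stay."""
        mesh, state = small_setup
        flags = np.zeros(mesh.n_elements, dtype=bool)
        flags[7] = True
        m2, s2 = refine_elements(mesh, state, flags)
        child = int(np.argmax(m2.level == 1))
        flags2 = np.zeros(m2.n_elements, dtype=bool)
        flags2[child] = True
        m3, s3 = refine_elements(m2, s2, flags2)
        allowed = np.zeros(m3.n_elements, dtype=bool)
        allowed[m3.level == 2] = True  # only the deepest pair may merge
        m4, s4 = recoarsen(m3, s3, allowed)
        ok, where = audit_conformity(m4)
        assert ok, where
        assert m4.n_elements < m3.n_elements

    def test_mass_restored_after_noisy_recoarsen(self, small_setup, rng):
        mesh, state = small_setup
        flags = np.zeros(mesh.n_elements, dtype=bool)
        flags[[7, 20]] = True
        m2, s2 = refine_elements(mesh, state, flags)
        s2.rho = s2.rho * rng.uniform(0.8, 1.2, m2.n_nodes)  # not edge-linear anymore
        before = mass_integrals(m2, s2)
        m3, s3 = recoarsen(m2, s2)
        after = mass_integrals(m3, s3)
        assert after["rho"] == pytest.approx(before["rho"], rel=1e-8)


class TestDriver:
    def test_uniform_fields_unchanged(self, params):
        mesh = mg.build_mesh(10.0, 4.0)
        state = mg.initial_state(mesh, params.replace(c_w=0.0, I_w=1.0))
        state.graft_marker[:] = 1.0
        m2, s2 = refine_recoarsen(mesh, state, indicator_threshold=0.5)
        assert m2.n_elements == mesh.n_elements

    def test_graft_boundary_attracts_refinement(self, params):
        mesh = mg.build_mesh(10.0, 2.0)
        state = mg.initial_state(mesh, params)
        ind = element_indicator(mesh, state)
        thr = 0.5 * float(ind.max())
        m2, s2 = refine_recoarsen(mesh, state, indicator_threshold=thr, max_level=1)
        assert m2.n_elements > mesh.n_elements
        ok, where = audit_conformity(m2)
        assert ok, where
        for k in ("N", "M", "c", "rho"):
            assert np.min(getattr(s2, k)) >= 0.0
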