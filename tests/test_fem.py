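"""Forward elasticity: mesh construction, stiffness properties, and the
Lamé thick-walled-cylinder oracle."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from vasoelast.geometry import GeometryError, build_annulus_mesh, quadratic_space
from vasoelast.fem import (
    DirichletBC,
    DisplacementField,
    ForwardModel,
    MaterialField,
    PressureLoad,
    assemble_stiffness,
    cst_stiffness,
    interior_displacement_extract,
    interior_displacement_insert,
    lame_radial_displacement,
    rigid_body_modes,
    solve_forward,
)


class TestMesh:
    def test_annulus_valid_and_deterministic(self):
        m1 = build_annulus_mesh(0.19, 0.30, 0.03)
        m2 = build_annulus_mesh(0.19, 0.30, 0.03)
        assert np.array_equal(m1.nodes, m2.nodes)
        assert np.array_equal(m1.elements, m2.elements)
        assert np.all(m1.element_areas > 0)
        assert set(m1.region_names()) == {"wall"}

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(GeometryError):
            build_annulus_mesh(0.30, 0.19, 0.02)
        with pytest.raises(GeometryError):
            build_annulus_mesh(0.0, 0.19, 0.02)

    def test_concentric_region_areas_match_ring_formula(self, two_region_phantom):
        _, mesh, _ = two_region_phantom
        a, c, b = 0.19, 0.24, 0.30
        exact_intima = np.pi * (c**2 - a**2)
        exact_media = np.pi * (b**2 - c**2)
        assert mesh.region_area("intima") == pytest.approx(exact_intima, rel=0.02)
        assert mesh.region_area("media") == pytest.approx(exact_media, rel=0.02)

    def test_boundary_loops_closed_and_disjoint(self, homog_phantom):
        _, mesh, _ = homog_phantom
        mesh.validate()
        assert np.intersect1d(mesh.inner_nodes, mesh.outer_nodes).size == 0


class TestStiffness:
    def test_cst_element_matches_hand_assembly(self):
        # unit right triangle, E = 1, nu = 0: D = diag(1, 1, 1/2),
        # B from b = (y_j - y_k)/2A etc.; assembled by hand
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        B = np.array(
            [
                [-1.0, 0.0, 1.0, 0.0, 0.0, 0.0],
                [0.0, -1.0, 0.0, 0.0, 0.0, 1.0],
                [-1.0, -1.0, 0.0, 1.0, 1.0, 0.0],
            ]
        )
        D = np.diag([1.0, 1.0, 0.5])
        expected = 0.5 * B.T @ D @ B
        np.testing.assert_allclose(cst_stiffness(coords, 1.0, 0.0), expected, atol=1e-14)

    def test_symmetry_and_linearity_in_modulus(self, homog_phantom):
        _, mesh, mat = homog_phantom
        K1 = assemble_stiffness(mesh, mat)
        asym = abs(K1 - K1.T).max() / abs(K1).max()
        assert asym < 1e-12
        K2 = assemble_stiffness(mesh, mat.scaled(2.0))
        assert abs(K2 - 2 * K1).max() / abs(K1).max() < 1e-12

    def test_psd_with_rigid_body_nullspace(self):
        mesh = build_annulus_mesh(0.19, 0.30, 0.05)
        mat = MaterialField({"wall": 20.0}, 0.3)
        K = assemble_stiffness(mesh, mat)
        R = rigid_body_modes(quadratic_space(mesh))
        assert np.abs(K @ R).max() < 1e-10 * abs(K).max()
        evals = spla.eigsh(K.tocsc().astype(float), k=5, sigma=-1e-6,
                           return_eigenvectors=False)
        evals = np.sort(evals)
        assert np.all(np.abs(evals[:3]) < 1e-8)   # exactly the rigid modes
        assert evals[3] > 1e-6                     # nothing else


class TestForwardSolve:
    def test_zero_pressure_zero_bc_gives_zero(self, homog_phantom):
        _, mesh, mat = homog_phantom
        u = solve_forward(mesh, mat, PressureLoad(0.0), DirichletBC.zero(mesh))
        assert np.abs(u.values).max() == 0.0

    def test_linearity_in_pressure_and_modulus(self, homog_phantom):
        _, mesh, mat = homog_phantom
        u1 = solve_forward(mesh, mat, PressureLoad(50.0))
        u2 = solve_forward(mesh, mat, PressureLoad(100.0))
        np.testing.assert_allclose(u2.values, 2 * u1.values, rtol=1e-9, atol=1e-14)
        u_half = solve_forward(mesh, mat.scaled(2.0), PressureLoad(50.0))
        np.testing.assert_allclose(u_half.values, 0.5 * u1.values, rtol=1e-7, atol=1e-12)

    def test_reciprocity_of_point_loads(self):
        mesh = build_annulus_mesh(0.19, 0.30, 0.05)
        model = ForwardModel(mesh, 0.3, PressureLoad(0.0))
        moduli = {"wall": 20.0}
        sol = model.solve(moduli)
        n_dof = model.n_dof
        f1 = np.zeros(n_dof)
        f2 = np.zeros(n_dof)
        f1[10] = 1.0
        f2[31] = 1.0
        u1 = sol.solve_adjoint(f1)
        u2 = sol.solve_adjoint(f2)
        assert u2 @ f1 == pytest.approx(u1 @ f2, rel=1e-8)


class TestLameOracle:
    # direct evaluation of u(r) = (1+nu)/E [(1-2nu) A r + B/r],
    # A = p a^2/(b^2-a^2), B = A b^2, p = 131 * 0.133322 kPa
    A_REF = 131 * 0.133322 * 0.19**2 / (0.30**2 - 0.19**2)
    U_AT_A = (1.495 / 20.0) * (0.01 * A_REF * 0.19 + A_REF * 0.30**2 / 0.19)

    def test_frozen_reference_value(self):
        u = lame_radial_displacement(0.19, 0.30, 20.0, 0.495, 131.0, 0.19)
        assert u == pytest.approx(self.U_AT_A, rel=1e-12)
        assert u == pytest.approx(0.4159, abs=1e-4)

    def test_zero_pressure_and_modulus_scaling(self):
        r = np.linspace(0.19, 0.30, 7)
        assert np.all(lame_radial_displacement(0.19, 0.30, 20.0, 0.495, 0.0, r) == 0)
        u1 = lame_radial_displacement(0.19, 0.30, 20.0, 0.495, 131.0, r)
        u2 = lame_radial_displacement(0.19, 0.30, 40.0, 0.495, 131.0, r)
        np.testing.assert_allclose(u2, 0.5 * u1, rtol=1e-14)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            lame_radial_displacement(0.30, 0.19, 20.0, 0.495, 131.0, 0.25)

    def test_fem_matches_lame_at_nearly_incompressible_nu(self):
        """No volumetric locking: 1% agreement at nu = 0.495 on a modest mesh."""
        mesh = build_annulus_mesh(0.19, 0.30, 0.02)
        mat = MaterialField({"wall": 20.0}, 0.495)
        u = solve_forward(mesh, mat, PressureLoad(131.0))
        r = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
        ur = (u.values * mesh.nodes / r[:, None]).sum(axis=1)
        exact = lame_radial_displacement(0.19, 0.30, 20.0, 0.495, 131.0, r)
        rel = np.linalg.norm(ur - exact) / np.linalg.norm(exact)
        assert rel < 0.01


class TestInteriorExtract:
    def test_length_zero_and_roundtrip(self, homog_phantom):
        _, mesh, _ = homog_phantom
        n_out = mesh.outer_nodes.size
        zero = DisplacementField(np.zeros((mesh.n_nodes, 2)))
        v = interior_displacement_extract(zero, mesh)
        assert v.shape == (2 * (mesh.n_nodes - n_out),)
        assert np.all(v == 0)
        rng = np.random.default_rng(0)
        field = DisplacementField(rng.normal(size=(mesh.n_nodes, 2)))
        vec = interior_displacement_extract(field, mesh)
        rebuilt = interior_displacement_insert(
            vec, mesh, boundary_values=field.values[mesh.outer_nodes]
        )
        np.testing.assert_array_equal(rebuilt.values, field.values)
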