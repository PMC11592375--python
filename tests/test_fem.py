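"""Voxel hexahedral elasticity: element matrices, solves, strain recovery."""

import numpy as np
import pytest

from osteosim import (
    LoadCase,
    MaterialField,
    RegionLabel,
    VoxelFEModel,
    build_element_stiffness,
    compute_element_strains,
    make_fixture,
    solve_displacements,
)
from osteosim.fem import SingularModelError, solve_system
from osteosim.geometry import VoxelModel


# --- independent dense reference implementation (test-only oracle) ---------

def _reference_hex_stiffness(E, nu, a):
    """Straightforward loop-based hex-8 stiffness (independent of the package)."""
    C = np.zeros((6, 6))
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[3:, 3:] = mu * np.eye(3)
    corners = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]]
    )
    signs = 2 * corners - 1
    K = np.zeros((24, 24))
    g = 1 / np.sqrt(3)
    for gp in signs * g:
        B = np.zeros((6, 24))
        for i in range(8):
            sx, sy, sz = signs[i]
            dN = np.array(
                [
                    sx * (1 + sy * gp[1]) * (1 + sz * gp[2]),
                    (1 + sx * gp[0]) * sy * (1 + sz * gp[2]),
                    (1 + sx * gp[0]) * (1 + sy * gp[1]) * sz,
                ]
            ) / 8 * (2 / a)
            B[0, 3 * i] = dN[0]
            B[1, 3 * i + 1] = dN[1]
            B[2, 3 * i + 2] = dN[2]
            B[3, 3 * i], B[3, 3 * i + 1] = dN[1], dN[0]
            B[4, 3 * i + 1], B[4, 3 * i + 2] = dN[2], dN[1]
            B[5, 3 * i], B[5, 3 * i + 2] = dN[2], dN[0]
        K += B.T @ C @ B * (a / 2) ** 3
    return K


class TestElementStiffness:
    def test_symmetry(self):
        K = build_element_stiffness(1000.0, 0.3, 1.0)
        np.testing.assert_allclose(K, K.T, atol=1e-12)

    def test_rigid_body_modes(self):
        K = build_element_stiffness(1000.0, 0.3, 1.0)
        # translations
        for d in range(3):
            u = np.zeros(24)
            u[d::3] = 1.0
            np.testing.assert_allclose(K @ u, 0.0, atol=1e-9)
        # six zero eigenvalues in total (3 translations + 3 rotations)
        w = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(w) < 1e-8 * w.max()) == 6

    def test_linear_in_modulus(self):
        K1 = build_element_stiffness(500.0, 0.25, 1.0)
        K2 = build_element_stiffness(1000.0, 0.25, 1.0)
        np.testing.assert_allclose(K2, 2 * K1, rtol=1e-12)

    def test_matches_reference(self):
        K = build_element_stiffness(123.0, 0.31, 0.7)
        Kref = _reference_hex_stiffness(123.0, 0.31, 0.7)
        np.testing.assert_allclose(K, Kref, rtol=1e-12, atol=1e-14)

    def test_incompressible_rejected(self):
        with pytest.raises(ValueError):
            build_element_stiffness(1000.0, 0.5, 1.0)


@pytest.fixture(scope="module")
def uniaxial_solution():
    model, materials, _ = make_fixture("homogeneous_block", n=4)
    load = LoadCase(pressure_mpa=0.5, bottom="roller")
    fe = VoxelFEModel(model)
    u = solve_displacements(fe, materials, load)
    return fe, u, materials, load


class TestUniaxialFixture:
    """Homogeneous block, roller base + symmetry planes: exact uniaxial stress."""

    p, E, nu = 0.5, 1000.0, 0.325

    def test_axial_strain_matches_closed_form(self, uniaxial_solution):
        fe, u, _, _ = uniaxial_solution
        strains = compute_element_strains(fe, u)
        ezz = strains.tensor[:, 2]
        np.testing.assert_allclose(ezz, -self.p / self.E, rtol=1e-3)

    def test_principal_strains(self, uniaxial_solution):
        fe, u, _, _ = uniaxial_solution
        pr = compute_element_strains(fe, u).principal
        np.testing.assert_allclose(pr[:, 0], self.nu * self.p / self.E, rtol=1e-3)
        np.testing.assert_allclose(pr[:, 2], -self.p / self.E, rtol=1e-3)
        assert np.all(pr[:, 0] >= pr[:, 1]) and np.all(pr[:, 1] >= pr[:, 2])

    def test_zero_pressure_zero_displacement(self):
        model, materials, _ = make_fixture("homogeneous_block", n=3)
        u = solve_displacements(model, materials, LoadCase(pressure_mpa=0.0, bottom="roller"))
        # a zero right-hand side must produce an identically zero solution
        np.testing.assert_array_equal(u, 0.0)

    def test_linearity_in_load(self, uniaxial_solution):
        fe, u, materials, _ = uniaxial_solution
        u2 = solve_displacements(fe, materials, LoadCase(pressure_mpa=2 * self.p, bottom="roller"))
        np.testing.assert_allclose(u2, 2 * u, rtol=1e-9, atol=1e-15)


class TestPatchAndOracle:
    def test_patch_test_linear_field(self):
        """Prescribing a linear displacement on the boundary reproduces the
        uniform strain exactly in every trilinear element."""
        model, materials, _ = make_fixture("homogeneous_block", n=3)
        fe = VoxelFEModel(model)
        A = np.array([[2e-4, 1e-4, 0.0], [1e-4, -1e-4, 5e-5], [0.0, 5e-5, 3e-4]])
        nxn, nyn, nzn = fe.node_shape
        X = np.stack(
            np.meshgrid(np.arange(nxn), np.arange(nyn), np.arange(nzn), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3) * model.spacing_um
        u_exact = (X @ A.T).ravel()
        boundary = (
            (X[:, 0] == 0) | (X[:, 0] == X[:, 0].max())
            | (X[:, 1] == 0) | (X[:, 1] == X[:, 1].max())
            | (X[:, 2] == 0) | (X[:, 2] == X[:, 2].max())
        )
        fixed = np.repeat(boundary, 3)
        K = fe.assemble(materials)
        u = solve_system(K, np.zeros(fe.n_dofs), fixed, u_fixed=u_exact)
        strains = compute_element_strains(fe, u)
        sym = 0.5 * (A + A.T)
        expected = np.array(
            [sym[0, 0], sym[1, 1], sym[2, 2], 2 * sym[0, 1], 2 * sym[1, 2], 2 * sym[0, 2]]
        )
        np.testing.assert_allclose(
            strains.tensor, np.tile(expected, (fe.n_elements, 1)), rtol=1e-9, atol=1e-13
        )

    def test_rigid_motion_produces_zero_strain(self):
        model, _, _ = make_fixture("homogeneous_block", n=3)
        fe = VoxelFEModel(model)
        u = np.tile([3.0, -2.0, 1.0], fe.n_nodes)
        strains = compute_element_strains(fe, u)
        np.testing.assert_allclose(strains.tensor, 0.0, atol=1e-12)

    def test_dense_reference_oracle(self):
        """Package solver vs an independent dense assembly on a 2x2x2 cube."""
        model, materials, _ = make_fixture("homogeneous_block", n=2)
        fe = VoxelFEModel(model)
        load = LoadCase(pressure_mpa=0.5, bottom="roller")
        fixed, f = fe.boundary_conditions(load)
        u_pkg = solve_displacements(fe, materials, load)

        Kd = np.zeros((fe.n_dofs, fe.n_dofs))
        Ke = _reference_hex_stiffness(1000.0, 0.325, model.spacing_um)
        for dofs in fe.element_dofs:
            Kd[np.ix_(dofs, dofs)] += Ke
        free = ~fixed
        u_ref = np.zeros(fe.n_dofs)
        u_ref[free] = np.linalg.solve(Kd[np.ix_(free, free)], f[free])
        np.testing.assert_allclose(u_pkg, u_ref, rtol=1e-10, atol=1e-14)


class TestGlobalProperties:
    def test_force_balance(self):
        """Reactions on the fixed base equal the applied top load to 1e-6."""
        model, materials, _ = make_fixture("plate_sandwich", n=4)
        fe = VoxelFEModel(model)
        load = LoadCase(pressure_mpa=0.5, bottom="fixed")
        fixed, f = fe.boundary_conditions(load)
        u = solve_displacements(fe, materials, load)
        reactions = fe.element_internal_forces(u, materials) - f
        applied = 0.5 * (4 * model.spacing_um) ** 2
        bottom_rz = reactions[2::3][fixed[2::3]].sum()
        assert bottom_rz == pytest.approx(applied, rel=1e-6)

    def test_solution_residual(self):
        model, materials, _ = make_fixture("plate_sandwich", n=4)
        fe = VoxelFEModel(model)
        load = LoadCase(pressure_mpa=0.5)
        fixed, f = fe.boundary_conditions(load)
        K = fe.assemble(materials)
        u = solve_system(K, f, fixed)
        free = ~fixed
        res = np.linalg.norm((K @ u - f)[free]) / np.linalg.norm(f[free])
        assert res < 1e-8

    def test_global_stiffness_symmetric(self):
        model, materials, _ = make_fixture("homogeneous_block", n=3)
        fe = VoxelFEModel(model)
        K = fe.assemble(materials)
        diff = (K - K.T)
        assert abs(diff).max() < 1e-9

    def test_compression_gives_negative_mean_hydrostatic_strain(self, tiny_gyroid_model):
        from osteosim.regulation import RegenerationSimulator, TissueComposition

        model, _ = tiny_gyroid_model
        sim = RegenerationSimulator(model)
        comp = TissueComposition.granulation(sim.n_healing)
        eH, ed, _ = sim.healing_stimuli(sim.materials_for(comp))
        assert eH.mean() < 0.0
        assert np.all(ed >= 0.0)

    def test_floating_region_raises_diagnostic(self):
        labels = np.zeros((5, 1, 3), dtype=np.uint8)
        labels[:2] = RegionLabel.SCAFFOLD
        labels[3:] = RegionLabel.SCAFFOLD  # gap at ix == 2
        model = VoxelModel(labels=labels, spacing_um=100.0, quarter_symmetry=False,
                           symmetry_planes=())
        with pytest.raises(SingularModelError, match="disconnected"):
            VoxelFEModel(model)
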