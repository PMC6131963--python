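"""Voxel hexahedral elasticity: element matrices, assembly, solve, stress."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

import frogpad as fp
from frogpad import fem
from frogpad.fem import (
    FaceTraction,
    LoadCase,
    SolverError,
    assemble,
    edof_matrix,
    element_stiffness,
    node_index,
)


def minimal_constraints(resolution):
    """3-2-1 rigid-body constraints consistent with a uniform sigma_xx state."""
    nx, ny, nz = resolution
    n000 = int(node_index(resolution, 0, 0, 0))
    nx00 = int(node_index(resolution, nx, 0, 0))
    n0y0 = int(node_index(resolution, 0, ny, 0))
    return (3 * n000, 3 * n000 + 1, 3 * n000 + 2,
            3 * nx00 + 1, 3 * nx00 + 2, 3 * n0y0 + 2)


class TestElementStiffness:
    def test_symmetric_with_zero_row_sums(self, material):
        KE = element_stiffness(material, (0.1, 0.1, 0.1))
        assert KE.shape == (24, 24)
        assert np.allclose(KE, KE.T, atol=1e-12)
        # rigid translation along each axis produces no force
        for axis in range(3):
            u = np.zeros(24)
            u[axis::3] = 1.0
            assert np.allclose(KE @ u, 0.0, atol=1e-12)

    def test_energy_of_affine_field_matches_continuum(self, material):
        # constant-strain displacement: energy = V/2 eps:D:eps exactly
        h = (0.2, 0.1, 0.05)
        KE = element_stiffness(material, h)
        rng = np.random.default_rng(7)
        grad = rng.normal(size=(3, 3)) * 0.01
        corners = fem.NODE_OFFSETS * np.asarray(h)
        u = (corners @ grad.T).ravel()
        eps = 0.5 * (grad + grad.T)
        voigt = np.array([eps[0, 0], eps[1, 1], eps[2, 2],
                          2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[0, 2]])
        D = material.elasticity_matrix()
        V = np.prod(h)
        assert np.isclose(u @ KE @ u, V * voigt @ D @ voigt, rtol=1e-12)


class TestAssembly:
    def test_two_voxel_domain_matches_dense_hand_assembly(self, material):
        dom = fp.solid_box(0.2, 0.1, 0.1, (2, 1, 1))
        K = assemble(dom, material, penalty_p=3.0).toarray()
        # oracle: place the element matrix twice with an independently built map
        KE = element_stiffness(material, dom.voxel_size)
        n = 3 * fem.node_count(dom.resolution)
        Kref = np.zeros((n, n))
        for e in range(2):
            nodes = [node_index(dom.resolution, e + a, b, c) for a, b, c in fem.NODE_OFFSETS]
            dofs = np.array([3 * nd + comp for nd in nodes for comp in range(3)])
            Kref[np.ix_(dofs, dofs)] += KE
        assert np.allclose(K, Kref, atol=1e-12)

    def test_half_density_scales_by_simp_factor(self, material):
        dom1 = fp.solid_box(0.3, 0.2, 0.1, (3, 2, 1))
        domh = dom1.copy()
        domh.density[:] = 0.5
        K1 = assemble(dom1, material, penalty_p=3.0)
        Kh = assemble(domh, material, penalty_p=3.0)
        fac = fem.E_MIN_RATIO + 0.125 * (1 - fem.E_MIN_RATIO)
        assert np.allclose(Kh.toarray(), fac * K1.toarray(), rtol=1e-12)

    def test_fully_void_domain_raises(self, material):
        dom = fp.solid_box(0.1, 0.1, 0.1, (1, 1, 1))
        dom.void_mask[:] = True
        dom.density[:] = 0.0
        with pytest.raises(SolverError, match="void"):
            assemble(dom, material)


class TestSolve:
    def test_patch_test_uniform_axial_stress(self, material):
        # uniform traction on both x-end faces, minimal constraints:
        # trilinear elements reproduce the constant stress state exactly
        dom = fp.solid_box(0.4, 0.2, 0.2, (4, 2, 2))
        sigma0 = 2.0  # MPa
        A = 0.2 * 0.2
        lc = LoadCase(
            fixed_faces={},
            fixed_dof_ids=minimal_constraints(dom.resolution),
            tractions=(
                FaceTraction("distal", (sigma0 * A, 0, 0)),
                FaceTraction("proximal", (-sigma0 * A, 0, 0)),
            ),
        )
        u = fp.solve(dom, material, lc)
        sf = fp.recover_stress(dom, material, u)
        assert np.allclose(sf.tensors[..., 0, 0], sigma0, rtol=1e-9)
        off = sf.tensors.copy()
        off[..., 0, 0] = 0.0
        assert np.allclose(off, 0.0, atol=1e-9 * sigma0)
        assert np.allclose(sf.von_mises, sigma0, rtol=1e-9)
        assert np.allclose(sf.principal_values[..., 0], sigma0, rtol=1e-9)
        d1 = sf.principal_directions[..., :, 0]
        assert np.allclose(np.abs(d1[..., 0]), 1.0, atol=1e-8)

    def test_equilibrium_on_pad_model(self, pad_solution):
        total = pad_solution.reaction_sum()
        applied = np.array([-3.815e-3, 0.0, 0.0])
        assert np.allclose(total, -applied, atol=1e-6 * np.linalg.norm(applied))
        assert pad_solution.residual <= 1e-8

    def test_linearity_in_modulus(self, pad_domain, shear_load_case, material):
        u1 = fp.solve(pad_domain, material, shear_load_case)
        stiff = fp.Material(E_MPa=2 * material.E_MPa, nu=material.nu)
        u2 = fp.solve(pad_domain, stiff, shear_load_case)
        assert np.allclose(u2.values, 0.5 * u1.values, rtol=1e-9, atol=1e-18)

    @pytest.mark.parametrize("resolution", [(1, 1, 1), (2, 2, 1), (3, 3, 3)])
    def test_sparse_solution_matches_dense_brute_force(self, material, resolution):
        nx, ny, nz = resolution
        dom = fp.solid_box(0.1 * nx, 0.1 * ny, 0.1 * nz, resolution)
        lc = LoadCase(tractions=(FaceTraction("dorsal", (1e-3, 5e-4, -2e-3)),))
        u = fp.solve(dom, material, lc)
        # dense oracle: full matrix, penalty by row/col elimination
        K = assemble(dom, material).toarray()
        f = fem.load_vector(dom, lc)
        fixed = fem.fixed_dofs(dom, lc)
        free = np.setdiff1d(np.arange(K.shape[0]), fixed)
        uref = np.zeros(K.shape[0])
        uref[free] = np.linalg.solve(K[np.ix_(free, free)], f[free])
        scale = np.abs(uref).max()
        assert np.allclose(u.values.ravel(), uref, atol=1e-10 * scale)

    def test_missing_constraints_raises(self, material):
        dom = fp.solid_box(0.2, 0.1, 0.1, (2, 1, 1))
        lc = LoadCase(fixed_faces={}, tractions=(FaceTraction("distal", (1e-3, 0, 0)),))
        with pytest.raises(SolverError, match="rigid-body"):
            fp.solve(dom, material, lc)

    def test_traction_on_fully_fixed_face_rejected(self):
        with pytest.raises(ValueError, match="fully fixed"):
            LoadCase(tractions=(FaceTraction("ventral", (0, 0, 1e-3)),))

    def test_nodal_forces_sum_to_total(self, pad_domain, shear_load_case):
        f = fem.load_vector(pad_domain, shear_load_case)
        assert np.allclose(
            f.reshape(-1, 3).sum(axis=0), shear_load_case.total_force_N, rtol=1e-12
        )

    def test_mesh_convergence_of_cantilever_tip(self, material):
        # tip displacement changes by < 2% on the finest doubling
        tips = []
        for res in [(16, 4, 4), (32, 8, 8), (64, 16, 16)]:
            dom = fp.solid_box(1.0, 0.25, 0.25, res)
            lc = LoadCase(
                fixed_faces={"proximal": (True, True, True)},
                tractions=(FaceTraction("distal", (0, 0, -1e-4)),),
            )
            u = fp.solve(dom, material, lc)
            tips.append(u.values[:, 2].min())
        assert abs(tips[2] - tips[1]) / abs(tips[2]) < 0.02
        # and the sequence is converging monotonically from below
        assert abs(tips[2] - tips[1]) < abs(tips[1] - tips[0])


class TestStressRecovery:
    def test_hydrostatic_strain_gives_zero_von_mises(self, material):
        dom = fp.solid_box(0.2, 0.2, 0.2, (2, 2, 2))
        coords = fem.DisplacementField(
            domain=dom, values=np.zeros((27, 3)), reactions=np.zeros((27, 3)),
            load=np.zeros(81), fixed=np.array([]), residual=0.0,
        ).node_coords()
        u = fem.DisplacementField(
            domain=dom, values=1e-3 * coords, reactions=np.zeros((27, 3)),
            load=np.zeros(81), fixed=np.array([]), residual=0.0,
        )
        sf = fp.recover_stress(dom, material, u)
        assert np.allclose(sf.von_mises, 0.0, atol=1e-12)

    def test_pure_shear_von_mises_is_sqrt3_tau(self, material):
        # constructed displacement u_x = g*y gives engineering shear g
        dom = fp.solid_box(0.2, 0.2, 0.2, (2, 2, 2))
        dummy = fem.DisplacementField(
            domain=dom, values=np.zeros((27, 3)), reactions=np.zeros((27, 3)),
            load=np.zeros(81), fixed=np.array([]), residual=0.0,
        )
        coords = dummy.node_coords()
        g = 1e-3
        vals = np.zeros_like(coords)
        vals[:, 0] = g * coords[:, 1]
        u = fem.DisplacementField(
            domain=dom, values=vals, reactions=np.zeros((27, 3)),
            load=np.zeros(81), fixed=np.array([]), residual=0.0,
        )
        sf = fp.recover_stress(dom, material, u)
        mu = material.E_MPa / (2 * (1 + material.nu))
        tau = mu * g
        assert np.allclose(sf.von_mises, np.sqrt(3) * tau, rtol=1e-12)
        assert np.allclose(sf.tensors[..., 0, 1], tau, rtol=1e-12)

    def test_frame_invariance_of_invariants(self, pad_stress):
        t = pad_stress.tensors[pad_stress.mask][:50]
        Q = special_ortho_group.rvs(3, random_state=11)
        tr = np.einsum("ij,njk,lk->nil", Q, t, Q)
        rot = fem.StressField(
            domain=fp.solid_box(0.5, 0.1, 0.1, (50, 1, 1)),
            tensors=tr.reshape(50, 1, 1, 3, 3),
            mask=np.ones((50, 1, 1), bool),
        )
        orig = fem.StressField(
            domain=rot.domain, tensors=t.reshape(50, 1, 1, 3, 3), mask=rot.mask
        )
        assert np.allclose(rot.von_mises, orig.von_mises, atol=1e-8)
        assert np.allclose(rot.principal_values, orig.principal_values, atol=1e-8)

    def test_principal_triads_orthonormal_and_sorted(self, pad_stress):
        pv = pad_stress.principal_values[pad_stress.mask]
        assert np.all(np.diff(pv, axis=-1) <= 1e-12)
        dirs = pad_stress.principal_directions[pad_stress.mask]
        eye = np.einsum("nij,nik->njk", dirs, dirs)
        assert np.allclose(eye, np.eye(3), atol=1e-8)
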