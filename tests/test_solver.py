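"""Field solver: discretization algebra, oracles, conservation laws."""

import numpy as np
import pytest

from cordsteer.exceptions import SolverError
from cordsteer.materials import MaterialTable
from cordsteer.phantom import VoxelPhantom, define_target
from cordsteer.solver import (
    PotentialField,
    assemble_quadratic_forms,
    assemble_system,
    conductance_matrix,
    current_density,
    electrode_currents,
    solve_basis_fields,
    solve_field,
)

from conftest import (
    build_slab,
    point_electrodes,
    slab_divider_exact,
    slab_series_current,
    uniform_phantom,
)


def _slab_op(n, s1, s2, frac, **kw):
    ph, es = build_slab(n, s1, s2, frac, **kw)
    return ph, es, assemble_system(ph, es)


class TestAssembly:
    def test_uniform_stencil_weight(self):
        # off-diagonal weight between x-neighbors must be sigma*hy*hz/hx
        ph = uniform_phantom(shape=(4, 3, 3), sigma_Sm=2000.0, spacing=(0.5, 1.0, 2.0))
        es = point_electrodes(ph, {"E1": (0, 0, 0), "E2": (3, 2, 2)})
        op = assemble_system(ph, es)
        A = op.matrix.toarray()
        a = np.ravel_multi_index((1, 1, 1), ph.shape)
        b = np.ravel_multi_index((2, 1, 1), ph.shape)
        sigma_mm = 2000.0 * 1e-3
        assert A[a, b] == pytest.approx(-sigma_mm * 1.0 * 2.0 / 0.5, rel=1e-14)

    def test_face_conductivity_is_harmonic_mean(self):
        # sigma 1 and 3 S/mm on a unit grid -> face conductivity 1.5
        mats = MaterialTable({"a": 1000.0, "b": 3000.0})
        labels = np.ones((4, 3, 3), dtype=np.int16)
        labels[2:] = 2
        ph = VoxelPhantom(labels, ["exterior", "a", "b"], (1.0, 1.0, 1.0),
                          (0.0, 0.0, 0.0), mats)
        es = point_electrodes(ph, {"E1": (0, 0, 0), "E2": (3, 2, 2)})
        A = assemble_system(ph, es).matrix.toarray()
        i = np.ravel_multi_index((1, 1, 1), ph.shape)
        j = np.ravel_multi_index((2, 1, 1), ph.shape)
        assert A[i, j] == pytest.approx(-1.5, rel=1e-14)

    def test_matrix_symmetric(self):
        rng = np.random.default_rng(3)
        mats = MaterialTable({"a": 50.0, "b": 700.0})
        labels = rng.integers(1, 3, size=(5, 4, 6)).astype(np.int16)
        ph = VoxelPhantom(labels, ["exterior", "a", "b"], (0.7, 1.1, 0.9),
                          (0.0, 0.0, 0.0), mats)
        es = point_electrodes(ph, {"E1": (0, 0, 0), "E2": (4, 3, 5)})
        A = assemble_system(ph, es).matrix
        assert (A - A.T).nnz == 0

    def test_exterior_voxels_excluded(self):
        labels = np.ones((4, 4, 4), dtype=np.int16)
        labels[0, :, :] = 0  # exterior slab
        ph = VoxelPhantom(labels, ["exterior", "tissue"], (1.0, 1.0, 1.0),
                          (0.0, 0.0, 0.0), MaterialTable({"tissue": 1000.0}))
        es = point_electrodes(ph, {"E1": (1, 0, 0), "E2": (3, 3, 3)})
        op = assemble_system(ph, es)
        assert op.n_active == 3 * 4 * 4


class TestSolveField:
    def test_zero_voltages_give_zero_field(self, toy_three):
        _, _, op, _, _ = toy_three
        fld = solve_field(op, np.zeros(3))
        assert np.all(fld.values == 0.0)
        assert np.all(electrode_currents(op, fld) == 0.0)

    def test_constant_voltages_give_constant_field(self, toy_three):
        ph, _, op, _, _ = toy_three
        fld = solve_field(op, np.full(3, 2.5))
        assert np.allclose(fld.values[ph.active_mask()], 2.5, atol=1e-12)

    def test_two_layer_slab_matches_resistor_divider(self):
        # interface aligned with a voxel face: the discrete solution matches
        # the continuum piecewise-linear divider profile at every voxel
        # center, up to the (negligible) plate resistance
        s1, s2, frac, n = 1.0, 4.0, 0.5, 8
        ph, es, op = _slab_op(n, s1, s2, frac)
        fld = solve_field(op, np.array([1.0, 0.0]))
        xc = ph.centers(0)[1:-1]
        prof = fld.values[1:-1, 1, 1]
        f_int = slab_divider_exact(s1, s2, frac)
        exact = np.where(
            xc < frac, 1.0 - (1.0 - f_int) * xc / frac,
            f_int * (1.0 - xc) / (1.0 - frac),
        )
        assert np.abs(prof - exact).max() <= 1e-6
        assert np.interp(frac, ph.centers(0), fld.values[:, 1, 1]) == pytest.approx(
            0.5 * (exact[n // 2 - 1] + exact[n // 2]), abs=1e-6
        )

    def test_slab_current_matches_series_resistance(self):
        s1, s2, frac, n = 2.0, 0.5, 0.5, 8
        ph, es, op = _slab_op(n, s1, s2, frac)
        fld = solve_field(op, np.array([1.0, 0.0]))
        I = electrode_currents(op, fld)
        area = 3 * 0.5 * 3 * 0.5
        expected = slab_series_current(s1, s2, frac, 1.0, area)
        assert I[0] == pytest.approx(expected, rel=1e-6)
        assert I[0] + I[1] == pytest.approx(0.0, abs=1e-6 * abs(I[0]))

    def test_wrong_voltage_count_rejected(self, toy_three):
        _, _, op, _, _ = toy_three
        with pytest.raises(SolverError):
            solve_field(op, np.zeros(5))


class TestBasisFields:
    def test_basis_boundary_values_exact(self, toy_three):
        _, es, op, basis, _ = toy_three
        assert len(basis) == 3
        for q, fld in enumerate(basis.fields):
            for p, eid in enumerate(es.ids):
                vals = fld.values.reshape(-1)[es.voxels[eid]]
                assert np.all(vals == (1.0 if p == q else 0.0))

    def test_basis_fields_bounded_unit_interval(self, toy_three):
        _, _, _, basis, _ = toy_three
        for fld in basis.fields:
            assert fld.values.min() >= -1e-8
            assert fld.values.max() <= 1.0 + 1e-8

    def test_superposition(self, toy_three):
        _, _, op, basis, _ = toy_three
        rng = np.random.default_rng(11)
        v = rng.normal(size=3)
        fld = solve_field(op, v)
        combo = sum(vq * f.values for vq, f in zip(v, basis.fields))
        assert np.abs(fld.values - combo).max() <= 1e-8 * max(np.abs(v))

    def test_partition_of_unity(self, toy_three):
        ph, _, _, basis, _ = toy_three
        total = sum(f.values for f in basis.fields)
        assert np.abs(total[ph.active_mask()] - 1.0).max() <= 1e-8

    def test_maximum_principle(self, toy_three):
        _, _, op, _, _ = toy_three
        rng = np.random.default_rng(5)
        v = rng.normal(size=3)
        fld = solve_field(op, v)
        assert fld.values.reshape(-1)[op.active_flat].max() <= v.max() + 1e-8
        assert fld.values.reshape(-1)[op.active_flat].min() >= v.min() - 1e-8


class TestConductanceMatrix:
    def test_two_electrode_structure(self):
        ph, es, op = _slab_op(6, 1.0, 1.0, 0.5)
        basis = solve_basis_fields(op)
        Y = conductance_matrix(op, basis).matrix
        y = Y[0, 0]
        assert y > 0
        assert np.allclose(Y, [[y, -y], [-y, y]], rtol=1e-10)

    def test_kcl_and_reciprocity(self, toy_three):
        _, _, op, basis, Y = toy_three
        scale = np.abs(Y.matrix).max()
        assert np.abs(Y.matrix - Y.matrix.T).max() <= 1e-6 * scale
        assert np.abs(Y.matrix @ np.ones(3)).max() <= 1e-6 * scale
        assert np.all(np.diag(Y.matrix) > 0)
        off = Y.matrix[~np.eye(3, dtype=bool)]
        assert np.all(off <= 1e-12 * scale)

    def test_matches_dense_schur_complement(self, toy_three):
        _, es, op, basis, Y = toy_three
        A = op.matrix.toarray()
        d = op.dirichlet
        f = op.free
        S = A[np.ix_(d, d)] - A[np.ix_(d, f)] @ np.linalg.solve(
            A[np.ix_(f, f)], A[np.ix_(f, d)]
        )
        # group Schur rows/cols per electrode (each electrode: one voxel here)
        order = {eq[0]: i for i, eq in enumerate(op.electrode_eq)}
        perm = [list(d).index(eq[0]) for eq in op.electrode_eq]
        Yref = S[np.ix_(perm, perm)]
        assert np.abs(Y.matrix - Yref).max() <= 1e-6 * np.abs(Yref).max()


class TestCurrentDensity:
    def test_constant_field_zero_density(self, toy_three):
        ph, _, op, _, _ = toy_three
        fld = solve_field(op, np.full(3, 1.0))
        J = current_density(fld, ph)
        assert np.abs(J).max() <= 1e-12

    def test_linear_field_uniform_density(self):
        ph = uniform_phantom(shape=(6, 5, 5), sigma_Sm=2000.0)
        grids = ph.center_grids()
        fld = PotentialField(values=grids[0].copy(), electrode_voltages=np.zeros(2))
        J = current_density(fld, ph)
        sigma_mm = 2.0
        assert np.allclose(J[..., 0], sigma_mm, rtol=1e-12)
        assert np.abs(J[..., 1:]).max() <= 1e-14

    def test_box_flux_matches_electrode_current(self):
        # net physical flux -J through a box around one electrode must
        # reproduce the reaction current within 5 %
        ph = uniform_phantom(shape=(14, 13, 13), sigma_Sm=1000.0)
        es = point_electrodes(ph, {"E1": (3, 6, 6), "E2": (10, 6, 6)})
        op = assemble_system(ph, es)
        fld = solve_field(op, np.array([1.0, 0.0]))
        I = electrode_currents(op, fld)
        J = -current_density(fld, ph)  # physical sign
        # box: the half-domain i <= 6 around E1; its only open face is the
        # x-plane between i = 6 and 7 (every other face is the insulating
        # boundary, where the flux vanishes)
        face = 0.5 * (J[6, :, :, 0] + J[7, :, :, 0])
        flux = face.sum() * 1.0  # unit face area
        assert flux == pytest.approx(I[0], rel=0.05)


class TestQuadraticForms:
    def test_brute_force_oracle(self):
        ph, es, op = _slab_op(5, 1.0, 3.0, 0.4, ny=4, nz=3)
        basis = solve_basis_fields(op)
        # target: a hand-picked interior voxel pair inside the tissue
        t_flat = np.array(
            [np.ravel_multi_index((2, 1, 1), ph.shape),
             np.ravel_multi_index((3, 2, 1), ph.shape)]
        )
        from cordsteer.phantom import TargetRegion
        target = TargetRegion(center=(0.5, 1.0, 0.75), diameter=1.0, length=1.0,
                              axis=2, voxels=t_flat)
        forms = assemble_quadratic_forms(ph, basis, target)

        # independent direct-summation oracle over the target voxels
        sig = ph.conductivity_per_label()[ph.labels] * 1e-3
        active = ph.active_mask()
        vol = ph.voxel_volume
        n = len(basis)
        Cref = np.zeros((n, n))
        grads = []
        for fld in basis.fields:
            g = np.zeros(ph.shape + (3,))
            for flat in t_flat:
                i, j, k = np.unravel_index(flat, ph.shape)
                idx = [i, j, k]
                for ax, h in enumerate(ph.spacing):
                    up = idx.copy(); up[ax] += 1
                    dn = idx.copy(); dn[ax] -= 1
                    has_up = up[ax] < ph.shape[ax] and active[tuple(up)]
                    has_dn = dn[ax] >= 0 and active[tuple(dn)]
                    if has_up and has_dn:
                        d = (fld.values[tuple(up)] - fld.values[tuple(dn)]) / (2 * h)
                    elif has_up:
                        d = (fld.values[tuple(up)] - fld.values[i, j, k]) / h
                    elif has_dn:
                        d = (fld.values[i, j, k] - fld.values[tuple(dn)]) / h
                    else:
                        d = 0.0
                    g[i, j, k, ax] = d
            grads.append(g)
        for p in range(n):
            for q in range(n):
                acc = 0.0
                for flat in t_flat:
                    i, j, k = np.unravel_index(flat, ph.shape)
                    jp = sig[i, j, k] * grads[p][i, j, k]
                    jq = sig[i, j, k] * grads[q][i, j, k]
                    acc += float(jp @ jq) * vol
                Cref[p, q] = acc
        assert np.abs(forms.C - Cref).max() <= 1e-10 * max(np.abs(Cref).max(), 1e-300)

    def test_quadratic_form_equals_integrated_energy(self, toy_three):
        ph, es, op, basis, _ = toy_three
        from cordsteer.phantom import TargetRegion
        t_flat = np.array([np.ravel_multi_index((3, 2, 2), ph.shape)])
        target = TargetRegion(center=(3.5, 2.5, 2.5), diameter=1.0, length=1.0,
                              axis=2, voxels=t_flat)
        forms = assemble_quadratic_forms(ph, basis, target)
        rng = np.random.default_rng(2)
        for _ in range(5):
            v = rng.normal(size=3)
            fld = solve_field(op, v)
            J = current_density(fld, ph)
            e_target = (J.reshape(-1, 3)[t_flat] ** 2).sum() * ph.voxel_volume
            assert v @ forms.C @ v == pytest.approx(e_target, rel=1e-7, abs=1e-300)
            total = (J.reshape(-1, 3) ** 2).sum() * ph.voxel_volume
            assert v @ (forms.C + forms.C0) @ v == pytest.approx(total, rel=1e-7)

    def test_psd_and_complement_identity(self, small_result):
        forms = small_result.forms
        rng = np.random.default_rng(8)
        for _ in range(100):
            v = rng.normal(size=forms.C.shape[0])
            assert v @ forms.C @ v >= -1e-12 * abs(v @ v)
            assert v @ (forms.C + forms.C0) @ v >= -1e-12 * abs(v @ v)

    def test_target_equals_domain_makes_c0_vanish(self):
        ph, es, op = _slab_op(4, 1.0, 1.0, 0.5)
        basis = solve_basis_fields(op)
        from cordsteer.phantom import TargetRegion
        # every tissue voxel (the full integration domain) is in the target
        tissue = np.isin(ph.labels, [2, 3])
        target = TargetRegion(center=(0.5, 0.75, 0.75), diameter=9.0, length=9.0,
                              axis=2, voxels=np.flatnonzero(tissue))
        forms = assemble_quadratic_forms(ph, basis, target)
        assert np.abs(forms.C0).max() == 0.0


class TestGridConvergence:
    def test_slab_interface_error_shrinks_monotonically(self):
        # interface at x = 1/3 is never face-aligned at these resolutions,
        # so the discretization error is nonzero and must shrink as the
        # grid is refined
        s1, s2, frac = 1.0, 4.0, 1.0 / 3.0
        exact = slab_divider_exact(s1, s2, frac)
        errors = []
        for n in (4, 8, 16):
            ph, es, op = _slab_op(n, s1, s2, frac)
            fld = solve_field(op, np.array([1.0, 0.0]))
            x = ph.centers(0)
            f = np.interp(frac, x, fld.values[:, 1, 1])
            errors.append(abs(f - exact))
        assert errors[0] > errors[1] > errors[2]
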