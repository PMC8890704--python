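"""Dielectric conversion: voxelization oracles, material priorities, subpixel
tensors, cristae labeling, ablation, and base extension."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from mitolens.dielectric_grid import (
    CYTOPLASM, EXTRACELLULAR, MITOCHONDRION, CristaeSpec, MaterialTable,
    ablate, assign_materials, evaluate_cristae, extend_base, load_grid,
    save_grid, subpixel_tensor, uniform_grid, voxelize_mesh,
    MATRIX, INTRAMEMBRANE, INTERNAL_MEMBRANE)
from mitolens.synthetic_geometry import ConeModel, make_cone_envelope


def _cube(center, size=1.0):
    m = trimesh.creation.box(extents=(size, size, size))
    m.apply_translation(center)
    return m


BOUNDS2 = np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]])


class TestVoxelize:
    def test_unit_cube_volume(self):
        vox = voxelize_mesh(_cube((1, 1, 1)), 50.0, BOUNDS2)
        assert vox.occupied_volume_um3 == pytest.approx(1.0, rel=0.01)

    def test_convergence_with_resolution(self):
        """Voxelized volume error decreases when resolution doubles."""
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=0.6)
        sphere.apply_translation((1, 1, 1))
        errs = []
        for res in (10.0, 20.0, 40.0):
            vox = voxelize_mesh(sphere, res, BOUNDS2)
            errs.append(abs(vox.occupied_volume_um3 - sphere.volume))
        assert errs[1] < errs[0] and errs[2] < errs[1]

    def test_face_through_voxel_centers_half_fill(self):
        """A face crossing voxel centers splits the voxel's fill 50/50."""
        # cube face at x = 1.01 um = center of the voxel column at resolution 50
        m = _cube((1.01 - 0.25, 1.0, 1.0), 0.5)
        vox = voxelize_mesh(m, 50.0, BOUNDS2)
        i = int(1.01 * 50)  # voxel whose center is the face plane
        col = vox.fill[i, 45:55, 45:55]
        assert np.allclose(col, 0.5, atol=0.05)

    def test_out_of_bounds_refused(self):
        with pytest.raises(ValueError, match="outside"):
            voxelize_mesh(_cube((1.9, 1, 1)), 20.0, BOUNDS2)
        voxelize_mesh(_cube((1.9, 1, 1)), 20.0, BOUNDS2, clip=True)  # allowed

    def test_non_watertight_refused(self):
        b = trimesh.creation.box(extents=(1, 1, 1))
        bad = trimesh.Trimesh(b.vertices.copy(), b.faces[:-1].copy(), process=False)
        bad.apply_translation((1, 1, 1))
        with pytest.raises(ValueError, match="watertight"):
            voxelize_mesh(bad, 20.0, BOUNDS2)


class TestSubpixelTensor:
    def test_pure_phases(self):
        rec = {"normal": (0, 0, 1), "fill_fraction": 1.0,
               "eps_in": 2.0, "eps_out": 1.8}
        np.testing.assert_allclose(subpixel_tensor(rec), 2.0 * np.eye(3))
        rec["fill_fraction"] = 0.0
        np.testing.assert_allclose(subpixel_tensor(rec), 1.8 * np.eye(3))

    def test_half_fill_closed_form(self):
        """Harmonic mean along the normal, arithmetic tangentially."""
        rec = {"normal": (0, 0, 1), "fill_fraction": 0.5,
               "eps_in": 1.7956, "eps_out": 2.1316}
        T = subpixel_tensor(rec)
        assert T[2, 2] == pytest.approx(1 / (0.5 / 1.7956 + 0.5 / 2.1316), rel=1e-6)
        assert T[0, 0] == T[1, 1] == pytest.approx((1.7956 + 2.1316) / 2, rel=1e-6)
        assert T[2, 2] == pytest.approx(1.9492, abs=2e-4)
        assert T[0, 0] == pytest.approx(1.9636, abs=2e-4)

    @given(fill=st.floats(0.0, 1.0), mem=st.floats(0.0, 0.5),
           nz=st.floats(-1.0, 1.0), ny=st.floats(-1.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_spd_with_bounded_eigenvalues(self, fill, mem, nz, ny):
        n = np.array([0.3, ny, nz])
        if np.linalg.norm(n) < 1e-3:
            n = np.array([0.0, 0.0, 1.0])
        phases = [1.7956, 2.1316, 2.1316]  # in, out, membrane
        rec = {"normal": n, "fill_fraction": fill, "eps_in": phases[0],
               "eps_out": phases[1], "mem_fraction": mem, "eps_mem": phases[2]}
        T = subpixel_tensor(rec)
        np.testing.assert_allclose(T, T.T, atol=1e-12)
        ev = np.linalg.eigvalsh(T)
        assert ev.min() >= min(phases) - 1e-9
        assert ev.max() <= max(phases) + 1e-9


class TestAssignMaterials:
    def _model(self, mitos=(), envelope=True):
        env = make_cone_envelope(4.0, 3.0) if envelope else None
        return ConeModel(envelope=env, mitochondria=list(mitos),
                         distal_tip=np.array([0.0, 0.0, 4.0]))

    def test_empty_model_uniform_extracellular(self):
        model = ConeModel.__new__(ConeModel)
        model.envelope = None
        model.mitochondria = []
        model.tilt_deg = 0.0
        model.distal_tip = np.zeros(3)
        bounds = np.array([[0, 0, 0], [1.0, 1.0, 1.0]])
        grid = assign_materials(model, MaterialTable(), 20.0, bounds=bounds)
        np.testing.assert_allclose(grid.eps, 1.34 ** 2, rtol=1e-6)
        assert len(grid.if_index) == 0

    def test_mitochondrion_interior_and_membrane_records(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=0.8)
        sphere.apply_translation((0, 0, 1.6))
        model = self._model([sphere])
        grid = assign_materials(model, MaterialTable(), 20.0)
        # interior voxels carry eps = 1.40^2 exactly
        assert np.any(grid.labels == MITOCHONDRION)
        np.testing.assert_allclose(grid.eps[grid.labels == MITOCHONDRION],
                                   1.40 ** 2, rtol=1e-6)
        # a shell of interface records with the 10-nm membrane fraction
        mito_recs = np.isclose(grid.if_eps_in, 1.40 ** 2)
        assert mito_recs.sum() > 100
        dx = 1 / 20.0
        np.testing.assert_allclose(
            grid.if_mem_fraction, 0.010 / dx, rtol=1e-6)

    def test_bulk_eps_only_table_values(self):
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=0.5)
        sphere.apply_translation((0, 0, 2.0))
        model = self._model([sphere])
        table = MaterialTable()
        grid = assign_materials(model, table, 16.0)
        allowed = table.eps_by_label().astype(np.float32)
        present = np.unique(grid.eps)
        assert all(np.isclose(v, allowed, rtol=1e-6).any() for v in present)

    def test_degenerate_cristae_equals_uniform(self):
        """Matrix/intramembrane at the mitochondrial index with the internal
        membrane disabled reproduces the uniform-interior lattice."""
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=0.8)
        sphere.apply_translation((0, 0, 1.6))
        model = self._model([sphere])
        table = MaterialTable(n_matrix=1.40, n_intramembrane=1.40)
        spec = CristaeSpec(frequencies=[[2.0, 0, 0]], phases=[0.3],
                           amplitudes=[1.0], membrane_halfwidth_um=0.0)
        g_uniform = assign_materials(model, MaterialTable(), 20.0)
        g_cristae = assign_materials(model, table, 20.0, cristae=spec)
        np.testing.assert_allclose(g_cristae.eps, g_uniform.eps, rtol=1e-6)


class TestCristaeField:
    def test_constant_positive_field_is_matrix(self):
        spec = CristaeSpec(frequencies=[[0.0, 0.0, 0.0]], phases=[0.0],
                           amplitudes=[1.0])
        pts = np.random.default_rng(0).random((100, 3))
        assert np.all(evaluate_cristae(spec, pts) == MATRIX)

    def test_sign_flip_swaps_compartments_keeps_membrane(self):
        spec = CristaeSpec(frequencies=[[2.0, 1.0, 0.5]], phases=[0.3],
                           amplitudes=[1.0])
        neg = CristaeSpec(frequencies=spec.frequencies, phases=spec.phases,
                          amplitudes=-spec.amplitudes)
        pts = np.random.default_rng(1).random((2000, 3))
        a, b = evaluate_cristae(spec, pts), evaluate_cristae(neg, pts)
        mem_a, mem_b = a == INTERNAL_MEMBRANE, b == INTERNAL_MEMBRANE
        np.testing.assert_array_equal(mem_a, mem_b)
        assert np.all(b[a == MATRIX] != MATRIX) or not (a == MATRIX).any()
        swap = {MATRIX: INTRAMEMBRANE, INTRAMEMBRANE: MATRIX}
        for x, y in zip(a[~mem_a], b[~mem_b]):
            assert y == swap[x]

    def test_1d_cosine_membrane_band_closed_form(self):
        """For f = cos(k z), the membrane band |f|/|f'| < w around each zero
        has the analytic half-width arctan(k w)/k."""
        k = 2 * np.pi * 5.0  # wavelength 0.2 um along z
        w = 0.005
        spec = CristaeSpec(frequencies=[[0.0, 0.0, 5.0]], phases=[0.0],
                           amplitudes=[1.0], membrane_halfwidth_um=w)
        z = np.linspace(0.0, 0.2, 20_001)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        lab = evaluate_cristae(spec, pts)
        half_width = np.arctan(k * w) / k
        zero = 0.05  # first zero of cos(k z)
        in_band = np.abs(z - zero) < half_width
        # compare only away from the band edge (one grid step tolerance)
        edge = np.abs(np.abs(z - zero) - half_width) < 2e-5
        got = lab == INTERNAL_MEMBRANE
        sel = ~edge & (z > 0.02) & (z < 0.08)
        np.testing.assert_array_equal(got[sel], in_band[sel])

    def test_matrix_fraction_half_for_zero_mean_field(self):
        from mitolens.synthetic_geometry import make_cristae_spec

        spec = make_cristae_spec(40, seed=3, membrane_halfwidth_um=0.0)
        rng = np.random.default_rng(0)
        pts = rng.random((40_000, 3))
        lab = evaluate_cristae(spec, pts)
        assert np.mean(lab == MATRIX) == pytest.approx(0.5, abs=0.02)


@pytest.fixture(scope="module")
def grid():
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=0.7)
    sphere.apply_translation((0, 0, 1.8))
    env = make_cone_envelope(4.0, 3.0)
    model = ConeModel(envelope=env, mitochondria=[sphere])
    return assign_materials(model, MaterialTable(), 16.0)


class TestAblation:
    def test_intact_is_identity(self, grid):
        assert ablate(grid, "intact") is grid

    def test_no_mitochondria_reassigns_to_cytoplasm(self, grid):
        g2 = ablate(grid, "no_mitochondria")
        mito = grid.labels == MITOCHONDRION
        assert mito.any()
        np.testing.assert_allclose(g2.eps[mito], 1.36 ** 2, rtol=1e-6)
        # non-targeted voxels bit-identical
        np.testing.assert_array_equal(g2.eps[~mito & (grid.labels == EXTRACELLULAR)],
                                      grid.eps[~mito & (grid.labels == EXTRACELLULAR)])
        assert g2.shape == grid.shape

    def test_mitochondria_only_strips_envelope(self, grid):
        g2 = ablate(grid, "mitochondria_only")
        cyto = grid.labels == CYTOPLASM
        np.testing.assert_allclose(g2.eps[cyto], 1.34 ** 2, rtol=1e-6)
        mito = grid.labels == MITOCHONDRION
        np.testing.assert_array_equal(g2.eps[mito], grid.eps[mito])

    def test_composition_yields_uniform_lattice(self, grid):
        g2 = ablate(ablate(grid, "mitochondria_only"), "no_mitochondria")
        np.testing.assert_allclose(g2.eps, 1.34 ** 2, rtol=1e-6)
        assert len(g2.if_index) == 0

    def test_unknown_mode_rejected(self, grid):
        with pytest.raises(ValueError):
            ablate(grid, "everything")


class TestExtendBase:
    def test_tiled_layers_equal_base_layer(self):
        env = make_cone_envelope(3.0, 2.0)
        env.apply_translation((0, 0, 1.5))
        env.metadata["generatrix"] = env.metadata["generatrix"] + [0, 0]
        model = ConeModel(envelope=env, mitochondria=[],
                          distal_tip=np.array([0, 0, 4.5]))
        bounds = np.array([[-1.5, -1.5, 0.0], [1.5, 1.5, 6.0]])
        grid = assign_materials(model, MaterialTable(), 16.0, bounds=bounds)
        ext = extend_base(grid)
        occ = np.argwhere((grid.fill_envelope > 0).any(axis=(0, 1))).ravel()
        k0 = occ[0]
        assert k0 > 0
        for k in range(k0):
            np.testing.assert_array_equal(ext.eps[:, :, k], ext.eps[:, :, k0])
        # above the base everything matches the unextended grid
        np.testing.assert_array_equal(ext.eps[:, :, k0:], grid.eps[:, :, k0:])

    def test_empty_grid_unchanged(self):
        g = uniform_grid((8, 8, 16), 8.0)
        ext = extend_base(g)
        np.testing.assert_array_equal(ext.eps, g.eps)

    def test_grounded_model_warns_no_op(self):
        env = make_cone_envelope(3.0, 2.0)
        model = ConeModel(envelope=env, mitochondria=[])
        bounds = np.array([[-1.5, -1.5, 0.0], [1.5, 1.5, 4.0]])
        grid = assign_materials(model, MaterialTable(), 16.0, bounds=bounds)
        with pytest.warns(UserWarning, match="no-op"):
            ext = extend_base(grid)
        np.testing.assert_array_equal(ext.eps, grid.eps)


class TestPersistence:
    def test_round_trip_and_reskinning(self, tmp_path):
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=0.7)
        sphere.apply_translation((0, 0, 1.8))
        env = make_cone_envelope(4.0, 3.0)
        model = ConeModel(envelope=env, mitochondria=[sphere])
        grid = assign_materials(model, MaterialTable(), 12.0)
        path = tmp_path / "grid.h5"
        save_grid(grid, path)
        loaded = load_grid(path)
        np.testing.assert_array_equal(loaded.eps, grid.eps)
        np.testing.assert_array_equal(loaded.if_index, grid.if_index)
        # the container supports re-skinning without re-voxelizing
        g2 = ablate(loaded, "no_mitochondria")
        assert not np.any(g2.labels == MITOCHONDRION)
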