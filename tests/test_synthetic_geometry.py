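"""Geometry generator: mensuration oracles, packing invariants, cohorts."""

import numpy as np
import pytest
import trimesh

from mitolens.synthetic_geometry import (
    BundleSpec, CohortSpec, KAPPA_ACTIVE, KAPPA_HIBERNATING, PackingError,
    bundle_preset, ellipsoid_taper, make_cohort, make_cone_envelope,
    make_cristae_spec, make_mito_bundle, mesh_volume, sample_vmf,
    vmf_fraction_below)


def _profile(radii):
    z = np.linspace(0.0, 1.0, len(radii))
    return np.column_stack([z, radii])


class TestEnvelope:
    @pytest.mark.parametrize("length,diam,radii,expected", [
        (2.0, 2.0, np.ones(9), 2 * np.pi),                 # cylinder
        (3.0, 2.0, np.linspace(1, 0, 9), np.pi),           # cone of revolution
    ])
    def test_volume_matches_solid_of_revolution(self, length, diam, radii, expected):
        mesh = make_cone_envelope(length, diam, taper_profile=_profile(radii))
        assert mesh.is_watertight
        assert mesh_volume(mesh) == pytest.approx(expected, rel=0.02)

    def test_long_variant_scales_height_not_base(self):
        base = make_cone_envelope(8.0, 4.5)
        longer = make_cone_envelope(12.0, 4.5)
        assert longer.bounds[1, 2] == pytest.approx(1.5 * base.bounds[1, 2])
        # basal radius unchanged
        assert longer.bounds[1, 0] == pytest.approx(base.bounds[1, 0], abs=1e-6)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            make_cone_envelope(-1.0, 2.0)
        with pytest.raises(ValueError):
            make_cone_envelope(2.0, 2.0, taper_profile=_profile(np.ones(4)))

    def test_default_profile_volume_integral(self):
        # numerical solid-of-revolution integral as the independent oracle
        prof = ellipsoid_taper(bulge=0.35)
        mesh = make_cone_envelope(8.0, 4.5, taper_profile=prof)
        z = np.linspace(0, 1, 4001)
        r = np.interp(z, prof[:, 0], prof[:, 1]) * 2.25
        expected = np.pi * np.trapezoid(r ** 2, z * 8.0)
        assert mesh_volume(mesh) == pytest.approx(expected, rel=0.02)


class TestMeshVolume:
    def test_unit_cube(self):
        assert mesh_volume(trimesh.creation.box(extents=(1, 1, 1))) == pytest.approx(1.0)

    def test_icosphere_close_to_analytic(self):
        m = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        assert mesh_volume(m) == pytest.approx(4 * np.pi / 3, rel=0.01)

    def test_inward_winding_flagged(self):
        b = trimesh.creation.box(extents=(1, 1, 1))
        inv = trimesh.Trimesh(vertices=b.vertices.copy(),
                              faces=b.faces[:, ::-1].copy(), process=False)
        with pytest.raises(ValueError, match="winding|watertight"):
            mesh_volume(inv)

    def test_open_mesh_rejected(self):
        b = trimesh.creation.box(extents=(1, 1, 1))
        open_mesh = trimesh.Trimesh(vertices=b.vertices.copy(),
                                    faces=b.faces[:-2].copy(), process=False)
        with pytest.raises(ValueError):
            mesh_volume(open_mesh)


class TestBundles:
    def test_volume_matched_configurations(self, mini_envelope):
        """All four configurations hit the same target volume within 1%."""
        target = 0.14 * mesh_volume(mini_envelope)
        totals = {}
        for config, n in [("elongated", 24), ("spheres", 28), ("mega", 1),
                          ("disordered", 24)]:
            spec = BundleSpec(configuration=config, n_mito=n,
                              target_volume=target, seed=1)
            meshes, _ = make_mito_bundle(spec, mini_envelope)
            totals[config] = sum(mesh_volume(m) for m in meshes)
        for config, tot in totals.items():
            assert tot == pytest.approx(target, rel=0.01), config

    def test_mega_is_single_body(self, mini_envelope):
        spec = BundleSpec(configuration="mega", n_mito=5, target_volume=20.0, seed=0)
        assert spec.n_mito == 1
        meshes, _ = make_mito_bundle(spec, mini_envelope)
        assert len(meshes) == 1
        assert mesh_volume(meshes[0]) == pytest.approx(20.0, abs=0.5)

    def test_spheres_near_spherical(self, mini_envelope):
        spec = BundleSpec(configuration="spheres", n_mito=28,
                          target_volume=0.14 * mesh_volume(mini_envelope), seed=3)
        meshes, _ = make_mito_bundle(spec, mini_envelope)
        for m in meshes:
            ext = m.extents
            assert ext.max() / ext.min() < 1.3

    def test_all_bodies_inside_envelope(self, mini_envelope, active_bundle):
        _, meshes, _ = active_bundle
        gen = mini_envelope.metadata["generatrix"]
        for m in meshes:
            assert m.is_watertight
            v = m.vertices
            r_allowed = np.interp(v[:, 2], gen[:, 0], gen[:, 1], left=-1, right=-1)
            assert np.all(np.hypot(v[:, 0], v[:, 1]) <= r_allowed + 1e-6)

    def test_kappa_infinity_fully_aligned(self, mini_envelope):
        spec = BundleSpec(configuration="elongated", n_mito=24,
                          target_volume=0.15 * mesh_volume(mini_envelope),
                          disorder_kappa=np.inf, seed=0)
        _, skels = make_mito_bundle(spec, mini_envelope)
        ang = skels.branch_angles_to()
        assert np.all(ang < 15.0)
        assert np.all(ang < 1.0)  # kappa -> inf means exactly axial

    def test_infeasible_volume_rejected(self, mini_envelope):
        with pytest.raises(PackingError):
            make_mito_bundle(BundleSpec(configuration="mega", n_mito=1,
                                        target_volume=0.9 * mesh_volume(mini_envelope)),
                             mini_envelope)

    def test_seed_reproducibility(self, mini_envelope):
        spec = bundle_preset("active", mini_envelope, seed=5, fill_fraction=0.17)
        m1, s1 = make_mito_bundle(spec, mini_envelope)
        m2, s2 = make_mito_bundle(spec, mini_envelope)
        assert len(m1) == len(m2)
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a.vertices, b.vertices)
        for a, b in zip(s1.skeletons, s2.skeletons):
            np.testing.assert_array_equal(a.nodes, b.nodes)

    def test_hibernating_volume_is_70_percent_of_active(self, mini_envelope):
        a = bundle_preset("active", mini_envelope, seed=0, fill_fraction=0.2)
        h = bundle_preset("hibernating", mini_envelope, seed=0, fill_fraction=0.2)
        assert h.target_volume == pytest.approx(0.70 * a.target_volume)


class TestModelIO:
    @pytest.mark.parametrize("fmt", ["obj", "ply", "stl"])
    def test_round_trip(self, tmp_path, mini_envelope, active_bundle, fmt):
        from mitolens.synthetic_geometry import ConeModel, read_model, write_model

        _, meshes, skels = active_bundle
        model = ConeModel(envelope=mini_envelope, mitochondria=meshes,
                          skeletons=skels)
        write_model(model, tmp_path / "m", fmt=fmt)
        back = read_model(tmp_path / "m")
        assert len(back.mitochondria) == len(meshes)
        assert back.envelope.is_watertight
        assert mesh_volume(back.envelope) == pytest.approx(
            mesh_volume(mini_envelope), rel=1e-4)
        np.testing.assert_allclose(back.distal_tip, model.distal_tip)
        assert len(back.skeletons.skeletons) == len(skels.skeletons)


class TestVonMisesFisher:
    def test_fraction_below_matches_analytic(self):
        rng = np.random.default_rng(0)
        for kappa in (KAPPA_ACTIVE, KAPPA_HIBERNATING, 5.0):
            d = sample_vmf(rng, kappa, 50_000)
            th = np.degrees(np.arccos(np.abs(d[:, 2])))
            frac = np.mean(th < 15.0)
            expected = vmf_fraction_below(kappa, 15.0)
            se = np.sqrt(expected * (1 - expected) / 50_000)
            assert abs(frac - expected) < 4 * se

    def test_calibration_constants(self):
        assert vmf_fraction_below(KAPPA_ACTIVE, 15.0) == pytest.approx(0.75, abs=1e-6)
        assert vmf_fraction_below(KAPPA_HIBERNATING, 15.0) == pytest.approx(0.30, abs=1e-6)

    def test_unit_norm(self):
        d = sample_vmf(np.random.default_rng(1), 10.0, 1000)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)


class TestCristaeSpec:
    def test_same_seed_identical(self):
        a = make_cristae_spec(10, seed=7)
        b = make_cristae_spec(10, seed=7)
        np.testing.assert_array_equal(a.frequencies, b.frequencies)
        np.testing.assert_array_equal(a.phases, b.phases)
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)

    def test_zero_mean_field(self):
        """Monte-Carlo over independent draws: the spatial mean of the random
        cosine sum on a 1-um^3 sample is zero in expectation (random phases).
        A single draw's spatial mean is not zero — samples within one field
        are correlated — so the oracle averages across seeds."""
        rng = np.random.default_rng(0)
        pts = rng.random((4_000, 3))
        means = []
        for seed in range(40):
            f, _ = make_cristae_spec(50, seed=seed).evaluate(pts)
            means.append(f.mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            make_cristae_spec(0)
        with pytest.raises(ValueError):
            make_cristae_spec(5, freq_range_per_um=(3.0, 1.0))


class TestCohorts:
    def test_zero_sd_gives_exact_group_means(self):
        spec = CohortSpec(between_animal_sd=0.0, within_animal_sd=0.0, seed=0)
        a, b = make_cohort(spec)
        for vals in a.values():
            np.testing.assert_allclose(vals, 4.44)
        for vals in b.values():
            np.testing.assert_allclose(vals, 3.65)
        mean_diff = (np.concatenate(list(a.values())).mean()
                     - np.concatenate(list(b.values())).mean())
        assert mean_diff == pytest.approx(0.79)

    def test_large_sample_mean_difference_clt(self):
        spec = CohortSpec(n_animals_per_group=1, cones_per_animal=(10_000,),
                          between_animal_sd=0.0, within_animal_sd=0.5, seed=3)
        a, b = make_cohort(spec)
        diff = (np.concatenate(list(a.values())).mean()
                - np.concatenate(list(b.values())).mean())
        se = 0.5 * np.sqrt(2 / 10_000)
        assert abs(diff - 0.79) < 3 * se

    def test_seed_reproducible(self):
        s = CohortSpec(seed=11)
        a1, _ = make_cohort(s)
        a2, _ = make_cohort(s)
        for k in a1:
            np.testing.assert_array_equal(a1[k], a2[k])
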