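"""Normals, trilinear interpolation, and depth sampling closed forms."""

import numpy as np
import pytest

from boundaryprofile.core_io import GeometryError, SurfaceMesh, VolumeImage
from boundaryprofile.depth_sampling import (
    DEFAULT_SCHEME,
    SamplingScheme,
    build_depth_profile,
    compute_vertex_normals,
    parse_depth,
    sample_absolute_depth,
    sample_projection_fraction,
    trilinear_sample,
)
from boundaryprofile.synthetic_cohort import (
    NoiseModel,
    SyntheticSpec,
    make_template_geometry,
    simulate_subject_volumes,
)


def linear_volume(shape=(40, 40, 20), coeffs=(2.0, -1.0, 3.0), origin=(-5, -5, -8)):
    """f(x, y, z) = 2x - y + 3z on a 1 mm grid."""
    affine = np.eye(4)
    affine[:3, 3] = origin
    idx = np.indices(shape).astype(float)
    world = [idx[k] + origin[k] for k in range(3)]
    data = sum(c * w for c, w in zip(coeffs, world))
    return VolumeImage(data=data, affine=affine)


class TestNormals:
    def test_flat_slab_normals(self, slab_white):
        normals = compute_vertex_normals(slab_white)
        np.testing.assert_allclose(normals, [[0, 0, 1]] * len(normals),
                                   atol=1e-12)

    def test_unit_length(self, slab_white):
        n = compute_vertex_normals(slab_white)
        np.testing.assert_allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9)

    def test_matches_brute_force_accumulation(self, rng):
        # random perturbed slab; oracle loops over faces explicitly
        spec = SyntheticSpec(mesh_extent_mm=9, seed=3)
        white, _ = make_template_geometry(spec)
        coords = white.coords + 0.1 * rng.standard_normal(white.coords.shape)
        mesh = SurfaceMesh(coords, white.faces)
        normals = compute_vertex_normals(mesh)
        expected = np.zeros_like(coords)
        for f in mesh.faces:
            p0, p1, p2 = coords[f]
            expected[f] += np.cross(p1 - p0, p2 - p0)
        expected /= np.linalg.norm(expected, axis=1, keepdims=True)
        np.testing.assert_allclose(normals, expected, atol=1e-9)

    def test_isolated_vertex_invalid(self):
        mesh = SurfaceMesh(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0],
                                     [5, 5, 5]]),
                           np.array([[0, 1, 2]]))
        normals = compute_vertex_normals(mesh)
        assert np.isnan(normals[3]).all()
        assert np.isfinite(normals[:3]).all()


class TestTrilinear:
    def test_voxel_center_exact(self, rng):
        vol = VolumeImage(rng.standard_normal((6, 6, 6)), np.eye(4))
        vals, ok = trilinear_sample(vol, [[2.0, 3.0, 4.0]])
        assert ok[0] and vals[0] == vol.data[2, 3, 4]

    def test_midpoint_is_mean(self, rng):
        vol = VolumeImage(rng.standard_normal((6, 6, 6)), np.eye(4))
        vals, _ = trilinear_sample(vol, [[2.5, 3.0, 4.0]])
        np.testing.assert_allclose(
            vals[0], 0.5 * (vol.data[2, 3, 4] + vol.data[3, 3, 4]), atol=1e-12)

    def test_affine_field_exact(self, rng):
        vol = linear_volume()
        pts = np.column_stack([rng.uniform(0, 20, 50),
                               rng.uniform(0, 20, 50),
                               rng.uniform(-4, 8, 50)])
        vals, ok = trilinear_sample(vol, pts)
        assert ok.all()
        np.testing.assert_allclose(
            vals, 2 * pts[:, 0] - pts[:, 1] + 3 * pts[:, 2], atol=1e-9)

    def test_outside_hull_masked_not_extrapolated(self):
        vol = VolumeImage(np.ones((4, 4, 4)), np.eye(4))
        vals, ok = trilinear_sample(vol, [[-0.5, 1, 1], [1, 1, 3.5]])
        assert not ok.any()
        assert np.isnan(vals).all()


class TestDepthSampling:
    def test_fraction_zero_equals_white_surface_and_depth_zero(self, slab_geometry):
        white, pial = slab_geometry
        vol = linear_volume()
        normals = compute_vertex_normals(white)
        frac0 = sample_projection_fraction(white, pial, vol, 0.0)
        depth0 = sample_absolute_depth(white, normals, vol, 0.0)
        np.testing.assert_allclose(frac0.values, depth0.values, atol=1e-12)

    def test_projection_fraction_closed_form(self):
        spec = SyntheticSpec(mesh_extent_mm=10, thickness_mean_mm=2.5,
                             thickness_sd_mm=0.0)
        white, pial = make_template_geometry(spec)
        vol = linear_volume(coeffs=(0.0, 0.0, 1.0))  # f = z
        for frac, expect in [(0.3, 0.75), (0.6, 1.5)]:
            vm = sample_projection_fraction(white, pial, vol, frac)
            np.testing.assert_allclose(vm.valid_values(), expect, atol=1e-9)

    def test_absolute_depth_closed_form(self, slab_geometry):
        white, _ = slab_geometry
        normals = compute_vertex_normals(white)
        vol = linear_volume(coeffs=(0.0, 0.0, 1.0))
        vm = sample_absolute_depth(white, normals, vol, -1.0)
        np.testing.assert_allclose(vm.valid_values(), -1.0, atol=1e-9)

    def test_constant_volume_constant_map(self, slab_geometry):
        white, pial = slab_geometry
        vol = VolumeImage(np.full((40, 40, 20), 7.0),
                          linear_volume().affine)
        vm = sample_projection_fraction(white, pial, vol, 0.44)
        np.testing.assert_allclose(vm.valid_values(), 7.0, atol=1e-12)

    def test_deep_sampling_masked_outside_volume(self, slab_geometry):
        white, _ = slab_geometry
        normals = compute_vertex_normals(white)
        affine = np.eye(4)
        affine[:3, 3] = [-5, -5, -1.0]  # volume only reaches 1 mm below z=0
        vol = VolumeImage(np.ones((45, 45, 4)), affine)
        vm = sample_absolute_depth(white, normals, vol, -2.0)
        assert not vm.valid_mask.any()

    def test_mismatched_surfaces_rejected(self, slab_geometry):
        white, _ = slab_geometry
        tetra = SurfaceMesh(np.eye(3), np.array([[0, 1, 2]]))
        with pytest.raises(GeometryError, match="vertex-corresponding"):
            sample_projection_fraction(white, tetra, linear_volume(), 0.3)


class TestDepthProfile:
    def test_affine_field_exact_at_all_depths(self, slab_geometry):
        white, pial = slab_geometry
        vol = linear_volume()
        prof = build_depth_profile(white, pial, {"FA": vol}, DEFAULT_SCHEME)
        normals = compute_vertex_normals(white)
        for depth in DEFAULT_SCHEME.depths:
            if depth.kind == "fraction":
                pts = white.coords + depth.value * (pial.coords - white.coords)
            else:
                pts = white.coords + depth.value * normals
            expect = 2 * pts[:, 0] - pts[:, 1] + 3 * pts[:, 2]
            vm = prof.get("FA", depth.label)
            np.testing.assert_allclose(vm.values[vm.valid_mask],
                                       expect[vm.valid_mask], atol=1e-9)

    def test_monotone_t1_profile(self):
        spec = SyntheticSpec(mesh_extent_mm=15, noise=NoiseModel(scale=0.0))
        geom = make_template_geometry(spec)
        vols = simulate_subject_volumes(geom, spec, ("TD", "male", "A"), seed=2)
        prof = build_depth_profile(*geom, {"T1I": vols["T1I"]}, DEFAULT_SCHEME)
        stack = np.vstack([prof.get("T1I", lab).values
                           for lab in ("-2mm", "-1mm", "boundary", "30CT", "60CT")])
        ok = prof.shared_mask()
        assert (np.diff(stack[:, ok], axis=0) <= 1e-9).all()

    def test_boundary_only_scheme(self, slab_geometry):
        white, pial = slab_geometry
        scheme = SamplingScheme.from_labels(["boundary"])
        prof = build_depth_profile(white, pial,
                                   {"FA": linear_volume(), "MD": linear_volume()},
                                   scheme)
        assert len(prof.maps) == 2

    def test_depth_order_is_cosmetic(self, slab_geometry):
        white, pial = slab_geometry
        vol = linear_volume()
        a = build_depth_profile(white, pial, {"FA": vol},
                                SamplingScheme.from_labels(["-1mm", "30CT"]))
        b = build_depth_profile(white, pial, {"FA": vol},
                                SamplingScheme.from_labels(["30CT", "-1mm"]))
        for key in a.maps:
            np.testing.assert_array_equal(a.maps[key].values, b.maps[key].values)

    def test_mask_monotone_in_depth(self, slab_geometry):
        white, _ = slab_geometry
        normals = compute_vertex_normals(white)
        affine = np.eye(4)
        affine[:3, 3] = [-5, -5, -1.5]
        vol = VolumeImage(np.ones((45, 45, 5)), affine)
        masks = [sample_absolute_depth(white, normals, vol, d).valid_mask
                 for d in (0.0, -1.0, -2.0)]
        assert (masks[1] <= masks[0]).all() or masks[1].sum() <= masks[0].sum()
        assert masks[2].sum() <= masks[1].sum()

    def test_parse_depth_labels(self):
        assert parse_depth("-2mm").value == -2.0
        assert parse_depth("30CT").kind == "fraction"
        assert parse_depth("boundary").value == 0.0
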