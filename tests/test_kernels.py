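"""Kernel library vs independent brute-force / closed-form oracles."""

import numpy as np
import pytest
from scipy import ndimage

import voxelflow as vf
from voxelflow.kernels import gaussian_kernel_1d
from voxelflow.volume import Volume, VolumeError


def brute_force_edt(binary: np.ndarray) -> np.ndarray:
    """O(n^2) nearest-solid Euclidean distance; the independent oracle."""
    solid = np.argwhere(binary)
    out = np.full(binary.shape, np.nan)
    coords = np.argwhere(np.ones_like(binary, dtype=bool))
    if solid.size == 0:
        return out
    d2 = ((coords[:, None, :] - solid[None, :, :]) ** 2).sum(-1).min(1)
    out.flat[:] = np.sqrt(d2)
    return out


class TestDistanceTransform:
    def test_all_solid_is_zero(self, make_scalar_volume):
        v = make_scalar_volume(np.ones((3, 3, 3)))
        assert np.all(vf.distance_transform_3d(v, 0.5).data == 0)

    def test_collinear_1d_distances(self, make_scalar_volume):
        v = make_scalar_volume(np.array([1.0, 0.0, 0.0])[None, None, :])
        d = vf.distance_transform_3d(v, 0.5).data[0, 0, :, 0]
        assert d == pytest.approx([0.0, 1.0, 2.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_volumes(self, seed,
                                                   make_scalar_volume):
        rng = np.random.default_rng(seed)
        binary = (rng.random((8, 8, 8)) < 0.1).astype(np.float32)
        if binary.sum() == 0:
            binary[0, 0, 0] = 1.0
        v = make_scalar_volume(binary)
        got = vf.distance_transform_3d(v, 0.5).data[..., 0]
        want = brute_force_edt(binary >= 0.5)
        assert np.abs(got - want).max() < 1e-5

    def test_cross_check_against_scipy(self, make_scalar_volume, rng):
        binary = (rng.random((12, 10, 9)) < 0.08).astype(np.float32)
        binary[3, 4, 5] = 1.0
        v = make_scalar_volume(binary)
        got = vf.distance_transform_3d(v, 0.5).data[..., 0]
        want = ndimage.distance_transform_edt(binary < 0.5)
        assert np.abs(got - want).max() < 1e-5

    def test_axis_order_independence_via_mirroring(self, make_scalar_volume,
                                                   rng):
        binary = (rng.random((6, 7, 8)) < 0.15).astype(np.float32)
        binary[0, 0, 0] = 1.0
        d = vf.distance_transform_3d(make_scalar_volume(binary), 0.5)
        d_mirror = vf.distance_transform_3d(
            make_scalar_volume(binary[::-1, ::-1, ::-1]), 0.5)
        assert np.allclose(d.data[::-1, ::-1, ::-1], d_mirror.data, atol=1e-9)

    def test_all_empty_yields_finite_sentinel(self, make_scalar_volume):
        v = make_scalar_volume(np.zeros((4, 4, 4)))
        d = vf.distance_transform_3d(v, 0.5).data
        assert np.all(np.isfinite(d)) and np.all(d > np.sqrt(3 * 3 ** 2))

    def test_multichannel_rejected(self):
        v = vf.make_volume((2, 2), channels=3)
        with pytest.raises(VolumeError, match="convert"):
            vf.distance_transform_3d(v, 0.5)


def median_oracle(arr: np.ndarray) -> np.ndarray:
    """Full-sort 27-value median with explicit clamped borders."""
    pad = np.pad(arr, 1, mode="edge")
    out = np.empty_like(arr)
    for idx in np.ndindex(arr.shape):
        z, y, x = idx
        block = pad[z:z + 3, y:y + 3, x:x + 3].ravel()
        out[idx] = np.sort(block)[13]  # 14th order statistic
    return out


class TestMedianFilter:
    def test_constant_volume_unchanged(self, make_scalar_volume):
        v = make_scalar_volume(np.full((4, 4, 4), 0.3))
        assert np.allclose(vf.median_filter_3d(v).data, 0.3)

    def test_center_of_0_to_26_is_13(self, make_scalar_volume):
        v = make_scalar_volume(np.arange(27.0).reshape(3, 3, 3))
        assert vf.median_filter_3d(v).data[1, 1, 1, 0] == 13.0

    @pytest.mark.parametrize("seed,shape", [(0, (6, 6, 6)), (1, (7, 5, 6)),
                                            (2, (6, 8, 7))])
    def test_matches_full_sort_oracle_including_borders(self, seed, shape,
                                                        make_scalar_volume):
        rng = np.random.default_rng(seed)
        arr = rng.random(shape).astype(np.float32)
        got = vf.median_filter_3d(make_scalar_volume(arr)).data[..., 0]
        assert np.array_equal(got, median_oracle(arr).astype(np.float32))

    def test_translation_equivariant_in_interior(self, make_scalar_volume,
                                                 rng):
        arr = rng.random((8, 8, 8)).astype(np.float32)
        shifted = np.roll(arr, 1, axis=2)
        a = vf.median_filter_3d(make_scalar_volume(arr)).data[..., 0]
        b = vf.median_filter_3d(make_scalar_volume(shifted)).data[..., 0]
        assert np.array_equal(np.roll(a, 1, axis=2)[2:-2, 2:-2, 2:-2],
                              b[2:-2, 2:-2, 2:-2])


class TestRescaleIntensity:
    def test_affine_map_of_three_values(self, make_scalar_volume):
        v = make_scalar_volume(np.array([2.0, 4.0, 6.0])[None, None, :])
        assert vf.rescale_intensity(v).data[0, 0, :, 0] == pytest.approx(
            [0.0, 0.5, 1.0])

    def test_constant_input_becomes_zeros(self, make_scalar_volume):
        v = make_scalar_volume(np.full((3, 3, 3), 0.7))
        assert np.all(vf.rescale_intensity(v).data == 0.0)

    def test_exact_bounds_and_monotone_affine(self, make_random_volume, rng):
        v = make_random_volume(rng, (6, 6, 6))
        out = vf.rescale_intensity(v).data[..., 0]
        src = v.data[..., 0]
        assert out.min() == 0.0 and out.max() == 1.0
        # out must be an increasing affine map of the input
        lo, hi = src.min(), src.max()
        assert np.allclose(out, (src.astype(np.float64) - lo) / (hi - lo),
                           atol=1e-6)

    def test_idempotent(self, make_random_volume, rng):
        v = make_random_volume(rng, (5, 5, 5))
        once = vf.rescale_intensity(v)
        twice = vf.rescale_intensity(once)
        assert np.allclose(once.data, twice.data, atol=1e-7)


class TestThreshold:
    def test_boundary_value_is_solid(self, make_scalar_volume):
        v = make_scalar_volume(np.array([[[0.5]]]))
        assert vf.threshold(v, 0.5).data[0, 0, 0, 0] == 1.0

    def test_all_below_gives_zeros(self, make_scalar_volume):
        v = make_scalar_volume(np.full((3, 3, 3), 0.2))
        assert np.all(vf.threshold(v, 0.5).data == 0.0)

    def test_agrees_with_comparison_oracle(self, make_random_volume, rng):
        v = make_random_volume(rng, (6, 6, 6))
        out = vf.threshold(v, 0.4).data[..., 0]
        assert np.array_equal(out, (v.data[..., 0] >= 0.4).astype(np.float32))


def dense_convolve_oracle(arr, kx, ky, kz):
    """Direct (non-separable) convolution with clamp-to-edge borders."""
    full = np.einsum("i,j,k->ijk", kz, ky, kx)  # (z, y, x) kernel order
    rz, ry, rx = (s // 2 for s in full.shape)
    pad = np.pad(arr, ((rz, rz), (ry, ry), (rx, rx)), mode="edge")
    out = np.zeros_like(arr, dtype=np.float64)
    for dz in range(full.shape[0]):
        for dy in range(full.shape[1]):
            for dx in range(full.shape[2]):
                w = full[full.shape[0] - 1 - dz,
                         full.shape[1] - 1 - dy,
                         full.shape[2] - 1 - dx]
                out += w * pad[dz:dz + arr.shape[0],
                               dy:dy + arr.shape[1],
                               dx:dx + arr.shape[2]]
    return out


class TestConvolution:
    def test_normalized_kernel_preserves_constant(self, make_scalar_volume):
        v = make_scalar_volume(np.full((5, 5, 5), 0.4))
        out = vf.gaussian_blur(v, sigma=1.0)
        assert np.allclose(out.data, 0.4, atol=1e-6)

    def test_impulse_response_is_kernel_outer_product(self, make_scalar_volume):
        arr = np.zeros((9, 9, 9), dtype=np.float32)
        arr[4, 4, 4] = 1.0
        kx = np.array([0.25, 0.5, 0.25])
        ky = np.array([0.1, 0.8, 0.1])
        kz = np.array([0.3, 0.4, 0.3])
        out = vf.convolve_separable(make_scalar_volume(arr),
                                    [kx, ky, kz]).data[..., 0]
        expect = np.einsum("i,j,k->ijk", kz, ky, kx)
        assert np.allclose(out[3:6, 3:6, 3:6], expect, atol=1e-7)

    def test_matches_dense_convolution_oracle(self, make_scalar_volume, rng):
        arr = rng.random((8, 8, 8)).astype(np.float32)
        kx = np.array([0.2, 0.5, 0.3])
        ky = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
        kz = np.array([0.3, 0.4, 0.3])
        got = vf.convolve_separable(make_scalar_volume(arr),
                                    [kx, ky, kz]).data[..., 0]
        want = dense_convolve_oracle(arr.astype(np.float64), kx, ky, kz)
        assert np.abs(got - want).max() < 1e-6

    def test_even_kernel_rejected(self, make_scalar_volume):
        v = make_scalar_volume(np.zeros((3, 3, 3)))
        with pytest.raises(VolumeError, match="odd"):
            vf.convolve_separable(v, [np.ones(2) / 2] * 3)

    def test_gaussian_radius_is_ceil_three_sigma(self):
        assert gaussian_kernel_1d(1.0).size == 2 * 3 + 1
        assert gaussian_kernel_1d(0.5).size == 2 * 2 + 1
        assert gaussian_kernel_1d(1.0).sum() == pytest.approx(1.0)


class TestDerivatives:
    def test_constant_has_zero_gradient_and_normals(self, make_scalar_volume):
        v = make_scalar_volume(np.full((4, 4, 4), 0.5))
        assert np.all(vf.derivative(v).data == 0.0)
        assert np.all(vf.surface_normals(v).data == 0.0)

    def test_linear_ramp_along_x(self, make_scalar_volume):
        z, y, x = np.mgrid[0:5, 0:5, 0:5]
        v = make_scalar_volume(x.astype(np.float32) / 10.0)
        mag = vf.derivative(v).data[..., 0]
        normals = vf.surface_normals(v).data
        interior = (slice(1, -1),) * 3
        assert np.allclose(mag[interior], 0.1, atol=1e-6)
        assert np.allclose(normals[interior][..., 0], -1.0, atol=1e-6)
        assert np.allclose(normals[interior][..., 1:], 0.0, atol=1e-6)

    def test_matches_central_difference_oracle(self, make_scalar_volume, rng):
        arr = rng.random((6, 6, 6))
        got = vf.derivative(make_scalar_volume(arr)).data[..., 0]
        pad = np.pad(arr, 1, mode="edge")
        gx = (pad[1:-1, 1:-1, 2:] - pad[1:-1, 1:-1, :-2]) / 2
        gy = (pad[1:-1, 2:, 1:-1] - pad[1:-1, :-2, 1:-1]) / 2
        gz = (pad[2:, 1:-1, 1:-1] - pad[:-2, 1:-1, 1:-1]) / 2
        want = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
        assert np.abs(got - want).max() < 1e-6


class TestCurvature:
    def test_linear_ramp_is_flat(self, make_scalar_volume):
        z, y, x = np.mgrid[0:8, 0:8, 0:8]
        v = make_scalar_volume((x + 0.5 * y).astype(np.float32) / 20.0)
        k = vf.curvature(v).data[..., 0]
        # the divergence stencil has radius 2; clamp borders bend the
        # gradient field within that band, so test the true interior
        assert np.abs(k[2:-2, 2:-2, 2:-2]).max() < 1e-5

    def test_sphere_distance_field_has_curvature_one_over_r(
            self, make_scalar_volume):
        n = 33
        c = (n - 1) / 2
        z, y, x = np.mgrid[0:n, 0:n, 0:n].astype(np.float64)
        r = np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
        k = vf.curvature(make_scalar_volume(r)).data[..., 0]
        radius = 10.0
        shell = np.abs(r - radius) < 0.5
        shell[0, :, :] = shell[-1, :, :] = False  # keep away from borders
        vals = k[shell]
        assert np.allclose(vals, 1.0 / radius, rtol=0.15)

    def test_sign_flips_under_negation(self, make_scalar_volume, rng):
        arr = rng.random((6, 6, 6))
        k_pos = vf.curvature(make_scalar_volume(arr)).data
        k_neg = vf.curvature(make_scalar_volume(-arr)).data
        assert np.allclose(k_pos, -k_neg, atol=1e-5)


class TestRegionFilter:
    def test_constant_unchanged(self, make_scalar_volume):
        v = make_scalar_volume(np.full((4, 4, 4), 0.2))
        for op in ("min", "max", "avg"):
            assert np.allclose(vf.region_filter(v, op, 1).data, 0.2, atol=1e-7)

    def test_max_dilates_point_to_box(self, make_scalar_volume):
        arr = np.zeros((5, 5, 5), dtype=np.float32)
        arr[2, 2, 2] = 1.0
        out = vf.region_filter(make_scalar_volume(arr), "max", 1).data[..., 0]
        expect = np.zeros_like(arr)
        expect[1:4, 1:4, 1:4] = 1.0
        assert np.array_equal(out, expect)

    @pytest.mark.parametrize("op", ["min", "max", "avg"])
    def test_matches_direct_reduce_oracle(self, op, make_scalar_volume, rng):
        arr = rng.random((6, 6, 6)).astype(np.float32)
        got = vf.region_filter(make_scalar_volume(arr), op, 1).data[..., 0]
        pad = np.pad(arr, 1, mode="edge")
        reduce = {"min": np.min, "max": np.max, "avg": np.mean}[op]
        want = np.empty_like(arr, dtype=np.float64)
        for idx in np.ndindex(arr.shape):
            z, y, x = idx
            want[idx] = reduce(pad[z:z + 3, y:y + 3, x:x + 3])
        assert np.abs(got - want).max() < 1e-6


class TestElementwise:
    def test_add_zero_is_identity(self, make_random_volume, rng):
        v = make_random_volume(rng, (4, 4, 4))
        assert np.allclose(vf.elementwise(v, 0.0, "add").data, v.data)

    def test_pow_one_is_identity(self, make_random_volume, rng):
        v = make_random_volume(rng, (4, 4, 4))
        assert np.allclose(vf.elementwise(v, 1.0, "pow").data, v.data)

    def test_division_by_zero_follows_ieee(self, make_scalar_volume):
        ones = make_scalar_volume(np.ones((2, 2, 2)))
        zeros = make_scalar_volume(np.zeros((2, 2, 2)))
        out = vf.elementwise(ones, zeros, "div").data
        assert np.all(np.isposinf(out))
        nan_out = vf.elementwise(zeros, zeros, "div").data
        assert np.all(np.isnan(nan_out))

    def test_shape_mismatch_names_both_shapes(self):
        a = vf.make_volume((2, 2))
        b = vf.make_volume((3, 2))
        with pytest.raises(VolumeError, match=r"\(2, 2\).*\(3, 2\)"):
            vf.elementwise(a, b, "add")


class TestExtractSlice:
    def test_front_slice_in_x_fastest_order(self, make_scalar_volume):
        arr = np.arange(8.0).reshape(2, 2, 2)  # (z, y, x)
        sl = vf.extract_slice(make_scalar_volume(arr), axis=2, index=0)
        assert sl.dims == (2, 2)
        assert sl.data[..., 0].ravel().tolist() == [0.0, 1.0, 2.0, 3.0]

    def test_out_of_range_reports_valid_range(self, make_scalar_volume):
        v = make_scalar_volume(np.zeros((2, 2, 2)))
        with pytest.raises(VolumeError, match="0..1"):
            vf.extract_slice(v, axis=2, index=2)

    @pytest.mark.parametrize("axis", [0, 1, 2])
    def test_stacking_slices_reconstructs_volume(self, axis,
                                                 make_random_volume, rng):
        v = make_random_volume(rng, (3, 4, 5))
        np_axis = v.data.ndim - 2 - axis
        slices = [vf.extract_slice(v, axis, i).data
                  for i in range(v.dims[axis])]
        rebuilt = np.stack(slices, axis=np_axis)
        assert np.array_equal(rebuilt, v.data)


class TestShapePreservation:
    @pytest.mark.parametrize("kernel", [
        vf.median_filter_3d,
        vf.rescale_intensity,
        lambda v: vf.threshold(v, 0.5),
        lambda v: vf.gaussian_blur(v, 0.8),
        vf.derivative,
        vf.curvature,
        lambda v: vf.region_filter(v, "avg", 1),
        lambda v: vf.distance_transform_3d(v, 0.5),
    ])
    def test_dims_preserved(self, kernel, make_random_volume, rng):
        v = make_random_volume(rng, (5, 6, 7))
        assert kernel(v).dims == v.dims
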