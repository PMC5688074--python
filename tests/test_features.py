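import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vessel4d import (
    AcquisitionProtocol,
    BinaryMask3D,
    Volume3D,
    Volume4D,
    assemble_features,
    compute_weights,
    extract_t0,
    hessian_eigenvalues,
    local_histogram_params,
    signed_cavity_distance,
    weighted_temporal_average,
    weighted_temporal_variance,
)
from vessel4d.features import _histogram_stats_at, feature_column_names

from conftest import random_volume4d


def brute_force_wta_wtv(data, omega):
    """Triple-loop evaluation of the weighted temporal average/variance."""
    nx, ny, nz, nt = data.shape
    wta = np.zeros((nx, ny, nz))
    wtv = np.zeros((nx, ny, nz))
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                acc = 0.0
                for i in range(nt):
                    acc += omega[i] * data[x, y, z, i]
                wta[x, y, z] = acc
                var = 0.0
                for i in range(nt):
                    var += omega[i] * (acc - data[x, y, z, i]) ** 2
                wtv[x, y, z] = np.sqrt(var)
    return wta, wtv


class TestTemporalWeights:
    def test_published_protocol_weights(self):
        # 1x200 + 13x100 + 5x75 mAs sums to 1875 mAs
        proto = AcquisitionProtocol(exposures=[200.0] + [100.0] * 13 + [75.0] * 5)
        w = compute_weights(proto)
        assert w.omega[0] == pytest.approx(200 / 1875)
        assert w.omega[1] == pytest.approx(100 / 1875)
        assert w.omega[-1] == pytest.approx(75 / 1875)
        assert w.omega.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_exposures_give_uniform_weights(self):
        w = compute_weights(AcquisitionProtocol(exposures=[80.0] * 4))
        np.testing.assert_allclose(w.omega, 0.25)

    def test_single_time_point_normalises_to_one(self):
        w = compute_weights(AcquisitionProtocol(exposures=[50.0]))
        np.testing.assert_allclose(w.omega, [1.0])

    def test_nonpositive_exposure_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionProtocol(exposures=[100.0, 0.0])


class TestWtaWtv:
    def test_matches_brute_force_on_many_random_volumes(self, rng):
        proto_rng = np.random.default_rng(7)
        for _ in range(100):
            vol = random_volume4d(proto_rng, shape=(3, 3, 3), t=5)
            w = compute_weights(AcquisitionProtocol(exposures=vol.exposures))
            wta = weighted_temporal_average(vol, w)
            wtv = weighted_temporal_variance(vol, w)
            ref_wta, ref_wtv = brute_force_wta_wtv(vol.data, w.omega)
            np.testing.assert_allclose(wta.data, ref_wta, atol=1e-10)
            np.testing.assert_allclose(wtv.data, ref_wtv, atol=1e-10)

    def test_time_constant_volume_has_wta_c_and_zero_wtv(self):
        vol = Volume4D(
            data=np.full((4, 4, 4, 6), 37.0), spacing=(1, 1, 1), exposures=[60, 80, 100, 90, 75, 75]
        )
        w = compute_weights(AcquisitionProtocol(exposures=vol.exposures))
        np.testing.assert_allclose(weighted_temporal_average(vol, w).data, 37.0)
        np.testing.assert_allclose(weighted_temporal_variance(vol, w).data, 0.0, atol=1e-12)

    def test_two_equal_weight_points_give_mean_and_half_gap(self):
        data = np.zeros((1, 1, 1, 2))
        data[0, 0, 0] = [0.0, 100.0]
        vol = Volume4D(data=data, spacing=(1, 1, 1), exposures=[100, 100])
        w = compute_weights(AcquisitionProtocol(exposures=vol.exposures))
        assert weighted_temporal_average(vol, w).data[0, 0, 0] == pytest.approx(50.0)
        assert weighted_temporal_variance(vol, w).data[0, 0, 0] == pytest.approx(50.0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(offset=st.floats(-500, 500), seed=st.integers(0, 10_000))
    def test_constant_offset_shifts_wta_and_leaves_wtv(self, offset, seed):
        vol = random_volume4d(np.random.default_rng(seed), shape=(2, 2, 2), t=4)
        w = compute_weights(AcquisitionProtocol(exposures=vol.exposures))
        shifted = Volume4D(data=vol.data + offset, spacing=vol.spacing, exposures=vol.exposures)
        np.testing.assert_allclose(
            weighted_temporal_average(shifted, w).data,
            weighted_temporal_average(vol, w).data + offset,
            atol=1e-8,
        )
        np.testing.assert_allclose(
            weighted_temporal_variance(shifted, w).data,
            weighted_temporal_variance(vol, w).data,
            atol=1e-8,
        )

    def test_weight_length_mismatch_raises(self, rng):
        vol = random_volume4d(rng, t=5)
        w = compute_weights(AcquisitionProtocol(exposures=[1, 1, 1]))
        with pytest.raises(ValueError):
            weighted_temporal_average(vol, w)


class TestLocalHistogram:
    def test_flat_neighbourhood_hits_single_bin_floor(self):
        wtv = Volume3D(data=np.full((7, 7, 7), 5.0), spacing=(1, 1, 1))
        mean, std, mode, entropy = local_histogram_params(wtv, neighborhood_edge=5)
        np.testing.assert_allclose(mean.data, 5.0)
        np.testing.assert_allclose(std.data, 0.0)
        np.testing.assert_allclose(mode.data, 5.0)
        np.testing.assert_allclose(entropy.data, -np.log2(1 + 1e-4))

    def test_uniform_bin_occupancy_reaches_max_entropy(self):
        # 125 neighbourhood values spread exactly uniformly over 5 bins
        vals = np.repeat(np.arange(5), 25).astype(float)
        data = (vals[np.random.default_rng(0).permutation(125)]).reshape(5, 5, 5)
        wtv = Volume3D(data=data, spacing=(1, 1, 1))
        _, _, _, entropy = local_histogram_params(wtv, neighborhood_edge=5, n_bins=5)
        assert entropy.data[2, 2, 2] == pytest.approx(np.log2(5), abs=1e-3)

    def test_matches_direct_patch_histogram(self, rng):
        data = rng.normal(10, 4, size=(11, 11, 11))
        wtv = Volume3D(data=data, spacing=(1, 1, 1))
        n_bins = 32
        mean, std, mode, entropy = local_histogram_params(wtv, neighborhood_edge=9, n_bins=n_bins)
        # interior voxel: the 9^3 patch is fully inside, no padding involved
        c = 5
        patch = data[c - 4 : c + 5, c - 4 : c + 5, c - 4 : c + 5].ravel()
        assert mean.data[c, c, c] == pytest.approx(patch.mean())
        assert std.data[c, c, c] == pytest.approx(patch.std())
        counts, edges = np.histogram(patch, bins=n_bins, range=(patch.min(), patch.max()))
        p = counts / counts.sum()
        assert entropy.data[c, c, c] == pytest.approx(-(p * np.log2(p + 1e-4)).sum())
        k = counts.argmax()
        assert mode.data[c, c, c] == pytest.approx((edges[k] + edges[k + 1]) / 2)

    def test_even_neighbourhood_and_oversized_neighbourhood_rejected(self, rng):
        data = rng.normal(size=(6, 6, 6))
        with pytest.raises(ValueError, match="odd"):
            _histogram_stats_at(data, np.array([0]), edge=4, n_bins=8, eps=1e-4)
        with pytest.raises(ValueError, match="larger than grid"):
            _histogram_stats_at(data, np.array([0]), edge=9, n_bins=8, eps=1e-4)


class TestCavityDistance:
    def test_border_voxel_distance_is_zero_and_sign_flips_at_border(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[2:7, 2:7, 2:7] = True
        dist = signed_cavity_distance(BinaryMask3D(data=mask, spacing=(1, 1, 1)))
        assert dist.data[2, 4, 4] == 0.0  # on the border shell
        assert dist.data[4, 4, 4] < 0  # deep inside
        assert dist.data[0, 4, 4] > 0  # outside

    def test_axis_distance_from_single_voxel_mask(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[4, 4, 4] = True
        dist = signed_cavity_distance(BinaryMask3D(data=mask, spacing=(1, 1, 1)))
        assert dist.data[7, 4, 4] == pytest.approx(3.0)

    def test_matches_exhaustive_border_search(self, rng):
        from conftest import random_blob_mask

        spacing = (0.7, 1.0, 1.3)
        mask = random_blob_mask(rng, shape=(16, 16, 16), spacing=spacing, threshold=0.8)
        m = mask.data
        # independent border definition: foreground with a 6-neighbour background
        border = []
        for x in range(16):
            for y in range(16):
                for z in range(16):
                    if not m[x, y, z]:
                        continue
                    for dx, dy, dz in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
                        nx, ny, nz = x + dx, y + dy, z + dz
                        if not (0 <= nx < 16 and 0 <= ny < 16 and 0 <= nz < 16) or not m[nx, ny, nz]:
                            border.append((x, y, z))
                            break
        border = np.array(border, dtype=float) * np.asarray(spacing)
        dist = signed_cavity_distance(mask)
        coords = np.argwhere(np.ones_like(m)).astype(float) * np.asarray(spacing)
        brute = np.sqrt(((coords[:, None, :] - border[None, :, :]) ** 2).sum(-1)).min(1)
        signed = np.where(m.ravel(), -brute, brute)
        np.testing.assert_allclose(dist.data.ravel(), signed, atol=1e-6)

    def test_empty_and_full_masks_rejected(self):
        with pytest.raises(ValueError):
            signed_cavity_distance(BinaryMask3D(data=np.zeros((4, 4, 4), dtype=bool), spacing=(1, 1, 1)))
        with pytest.raises(ValueError):
            signed_cavity_distance(BinaryMask3D(data=np.ones((4, 4, 4), dtype=bool), spacing=(1, 1, 1)))


class TestHessian:
    def test_constant_image_has_zero_eigenvalues(self):
        wtv = Volume3D(data=np.full((12, 12, 12), 3.0), spacing=(1, 1, 1))
        for m in hessian_eigenvalues(wtv, scales_mm=[1.0, 2.0]):
            # atol covers the truncation error of the discrete Gaussian kernel
            np.testing.assert_allclose(m.data, 0.0, atol=1e-4)

    def test_bright_tube_shows_tubular_eigenvalue_signature(self):
        # Gaussian-profile bright tube along z on a dark background
        n = 21
        x, y = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2, indexing="ij")
        profile = 100.0 * np.exp(-(x**2 + y**2) / (2 * 1.5**2))
        data = np.repeat(profile[:, :, None], n, axis=2)
        wtv = Volume3D(data=data, spacing=(1, 1, 1))
        l1, l2, l3 = (m.data[n // 2, n // 2, n // 2] for m in hessian_eigenvalues(wtv, scales_mm=[1.5]))
        assert abs(l1) < 0.15 * abs(l3)  # along-tube curvature near zero
        assert l2 < 0 and l3 < 0
        assert abs(l2) == pytest.approx(abs(l3), rel=0.2)

    def test_isotropic_blob_has_three_equal_negative_eigenvalues(self):
        n = 21
        ax = np.arange(n) - n // 2
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        data = 100.0 * np.exp(-(x**2 + y**2 + z**2) / (2 * 2.0**2))
        wtv = Volume3D(data=data, spacing=(1, 1, 1))
        l1, l2, l3 = (m.data[n // 2, n // 2, n // 2] for m in hessian_eigenvalues(wtv, scales_mm=[2.0]))
        assert l1 < 0 and l2 < 0 and l3 < 0
        assert l1 == pytest.approx(l2, rel=1e-6)
        assert l2 == pytest.approx(l3, rel=1e-6)

    def test_subvoxel_scale_warns(self):
        wtv = Volume3D(data=np.zeros((8, 8, 8)), spacing=(1, 1, 1))
        with pytest.warns(UserWarning, match="half the smallest voxel"):
            hessian_eigenvalues(wtv, scales_mm=[0.2])


class TestAssembly:
    def test_t0_is_the_first_time_point(self, rng):
        vol = random_volume4d(rng, shape=(4, 4, 4), t=3)
        np.testing.assert_array_equal(extract_t0(vol).data, vol.data[..., 0])
        vol.data[0, 0, 0, 0] = 999.0
        np.testing.assert_array_equal(extract_t0(vol).data, vol.data[..., 0])

    def test_feature_matrix_has_24_fixed_columns_and_is_deterministic(self, rng):
        vol = random_volume4d(rng, shape=(12, 12, 12), t=4)
        cavity_arr = np.zeros((12, 12, 12), dtype=bool)
        cavity_arr[3:9, 3:9, 3:9] = True
        cavity = BinaryMask3D(data=cavity_arr, spacing=vol.spacing)
        cand_arr = np.zeros((12, 12, 12), dtype=bool)
        cand_arr[5, 5, 5] = cand_arr[6, 7, 8] = True
        candidates = BinaryMask3D(data=cand_arr, spacing=vol.spacing)
        fm = assemble_features(vol, cavity, candidates)
        assert fm.values.shape == (2, 24)
        assert fm.columns == feature_column_names()
        assert len(fm.columns) == 3 + 1 + 4 * 2 + 3 * 4
        fm2 = assemble_features(vol, cavity, candidates)
        np.testing.assert_array_equal(fm.values, fm2.values)

    def test_empty_candidate_mask_is_an_error(self, rng):
        vol = random_volume4d(rng, shape=(10, 10, 10), t=3)
        cavity_arr = np.zeros((10, 10, 10), dtype=bool)
        cavity_arr[2:8, 2:8, 2:8] = True
        cavity = BinaryMask3D(data=cavity_arr, spacing=vol.spacing)
        empty = BinaryMask3D(data=np.zeros((10, 10, 10), dtype=bool), spacing=vol.spacing)
        with pytest.raises(ValueError, match="empty candidate"):
            assemble_features(vol, cavity, empty)

    def test_grid_mismatch_is_an_error(self, rng):
        vol = random_volume4d(rng, shape=(10, 10, 10), t=3)
        cavity = BinaryMask3D(data=np.ones((8, 8, 8), dtype=bool), spacing=vol.spacing)
        cand = BinaryMask3D(data=np.ones((10, 10, 10), dtype=bool), spacing=vol.spacing)
        with pytest.raises(ValueError, match="grid"):
            assemble_features(vol, cavity, cand)
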