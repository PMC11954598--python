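"""Morphometry: segmentation variants, label volumes, windowed metrics vs naive oracles."""

import numpy as np
import pytest

from deepvessel import (
    LabelVolumes,
    METRIC_NAMES,
    MetricMaps,
    PhantomConfig,
    build_label_volumes,
    depth_profiles,
    dispersion,
    generate_vessels,
    metric_correlation,
    otsu_segment,
    region_stats,
    skeletonize,
    surface_extract,
    window_metrics,
)
from deepvessel.phantom import tube_mask


def axial_tube(shape=(32, 32, 32), radius=3.0):
    line = np.array([[0.0, shape[1] / 2, shape[2] / 2], [shape[0] - 1.0, shape[1] / 2, shape[2] / 2]])
    return tube_mask(shape, line, radius)


class TestOtsuSegment:
    def test_two_level_image_exact(self, rng):
        values = np.where(rng.random((4, 16, 16)) < 0.9, 10.0, 200.0)
        for method in ("global_otsu", "proportion_adjusted", "weighted_optimal"):
            mask = otsu_segment(values, method)
            assert np.array_equal(mask.voxels, values == 200.0), method

    def test_constant_image_warns_empty(self):
        with pytest.warns(RuntimeWarning):
            mask = otsu_segment(np.full((2, 8, 8), 3.0))
        assert not mask.voxels.any()

    def test_proportion_adjustment_enters_band(self, rng):
        # heavy-tailed image in which plain Otsu selects far more than 20%
        img = rng.random((4, 32, 32)) ** 0.25
        mask = otsu_segment(img, "proportion_adjusted", fraction_band=(0.01, 0.20))
        assert 0.005 <= mask.voxels.mean() <= 0.205

    def test_per_frame_threshold_varies(self, rng):
        v = np.stack([rng.random((32, 32)) * (k + 1) for k in range(3)])
        stacked = otsu_segment(v, per_frame=True)
        assert stacked.shape == v.shape


class TestSkeletonSurface:
    def test_straight_tube_skeleton_is_axial_path(self):
        A = axial_tube((24, 32, 32), radius=3.0)
        S = skeletonize(A)
        assert np.all(A[S])  # S subset of A
        count = S.sum()
        assert 22 <= count <= 26  # ~1 voxel per slice, ends may differ
        # single 26-connected component
        from scipy import ndimage

        _, n = ndimage.label(S, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_single_voxel_and_empty(self):
        single = np.zeros((5, 5, 5), dtype=bool)
        single[2, 2, 2] = True
        assert np.array_equal(skeletonize(single), single)
        assert not skeletonize(np.zeros((5, 5, 5), dtype=bool)).any()
        assert not surface_extract(np.zeros((5, 5, 5), dtype=bool)).any()
        assert np.array_equal(surface_extract(single), single)

    def test_solid_block_surface_count(self):
        A = np.zeros((14, 14, 14), dtype=bool)
        A[2:12, 2:12, 2:12] = True  # 10^3 block
        P = surface_extract(A)
        assert P.sum() == 10**3 - 8**3  # 488

    def test_three_cube_surface(self):
        A = np.zeros((5, 5, 5), dtype=bool)
        A[1:4, 1:4, 1:4] = True
        assert surface_extract(A).sum() == 26

    def test_border_counts_as_outside(self):
        A = np.ones((4, 4, 4), dtype=bool)
        P = surface_extract(A)
        assert P.sum() == 4**3 - 2**3

    def test_label_volume_invariants_enforced(self):
        A = np.zeros((4, 4, 4), dtype=bool)
        S = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError):
            LabelVolumes(A=A, S=S, P=A)


class TestWindowMetrics:
    def test_naive_triple_loop_oracle(self, rng):
        """Windowed sums match per-window brute force exactly on 8-cubes."""
        A = rng.random((16, 16, 16)) > 0.6
        labels = build_label_volumes(A)
        n, stride = 8, 4
        maps = window_metrics(labels, n, stride)
        for iz, z in enumerate(range(0, 16 - n + 1, stride)):
            for iy, y in enumerate(range(0, 16 - n + 1, stride)):
                for ix, x in enumerate(range(0, 16 - n + 1, stride)):
                    sa = ss = sp = 0
                    for dz in range(n):
                        for dy in range(n):
                            for dx in range(n):
                                sa += labels.A[z + dz, y + dy, x + dx]
                                ss += labels.S[z + dz, y + dy, x + dx]
                                sp += labels.P[z + dz, y + dy, x + dx]
                    assert maps.values["VVD"][iz, iy, ix] == sa / n**3
                    assert maps.values["VSD"][iz, iy, ix] == ss / n**3
                    assert maps.values["VSI"][iz, iy, ix] == sp / n**3
                    if ss > 0:
                        assert maps.values["VTI"][iz, iy, ix] == sa / ss
                    else:
                        assert not maps.defined["VTI"][iz, iy, ix]
                    if sa > 0:
                        assert maps.values["VCI"][iz, iy, ix] == sp**2 / (4 * np.pi * sa)
                    else:
                        assert not maps.defined["VCI"][iz, iy, ix]

    def test_filled_window_values(self):
        A = np.ones((10, 10, 10), dtype=bool)
        S = np.zeros_like(A)
        S[:, 5, 5] = True
        P = surface_extract(A)
        maps = window_metrics(LabelVolumes(A, S, P), window=10, stride=10)
        assert maps.values["VVD"][0, 0, 0] == 1.0
        assert maps.values["VTI"][0, 0, 0] == pytest.approx(1000 / 10)
        # solid 10-cube: surface 488, VCI = 488^2/(4 pi 1000)
        assert maps.values["VCI"][0, 0, 0] == pytest.approx(488**2 / (4 * np.pi * 1000))

    def test_hand_arithmetic_vti(self):
        A = np.zeros((8, 8, 8), dtype=bool)
        A.ravel()[:90] = True
        S = np.zeros_like(A)
        S.ravel()[:10] = True
        maps = window_metrics(LabelVolumes(A, S, np.zeros_like(A)), window=8, stride=8)
        assert maps.values["VTI"][0, 0, 0] == pytest.approx(9.0)

    def test_value_ranges(self, rng):
        A = rng.random((24, 24, 24)) > 0.5
        maps = window_metrics(build_label_volumes(A), window=8, stride=4)
        for name in ("VVD", "VSD", "VSI"):
            v = maps.values[name]
            assert np.all((v >= 0) & (v <= 1))
        vti = maps.values["VTI"][maps.defined["VTI"]]
        assert np.all(vti >= 1.0)
        vci = maps.values["VCI"][maps.defined["VCI"]]
        assert np.all(vci >= 0)
        assert np.all(maps.values["VSI"] <= maps.values["VVD"] + 1e-12)

    def test_undefined_windows_flagged_not_zero(self):
        A = np.zeros((16, 16, 16), dtype=bool)
        A[12:16, 12:16, 12:16] = True  # one corner only
        maps = window_metrics(build_label_volumes(A), window=8, stride=8)
        assert not maps.defined["VTI"][0, 0, 0]
        assert np.isnan(maps.values["VTI"][0, 0, 0])

    def test_vti_monotone_in_tube_radius(self):
        means = []
        for r in (2, 3, 4, 5):
            A = axial_tube((24, 32, 32), radius=r)
            maps = window_metrics(build_label_volumes(A), window=16, stride=8)
            vti = maps.values["VTI"][maps.defined["VTI"]]
            means.append(vti.mean())
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_window_larger_than_volume_rejected(self):
        A = np.zeros((8, 8, 8), dtype=bool)
        with pytest.raises(ValueError):
            window_metrics(build_label_volumes(A), window=16)


def synthetic_maps(values_by_z, window=8, stride=8):
    """MetricMaps with all five metrics sharing one (z, 1, 1) grid of values."""
    grid = np.array(values_by_z, dtype=float)[:, None, None]
    values = {name: grid.copy() for name in METRIC_NAMES}
    defined = {name: np.isfinite(grid) for name in METRIC_NAMES}
    return MetricMaps(
        values=values,
        defined=defined,
        window=window,
        stride=stride,
        origins=(np.arange(len(values_by_z)) * stride, np.array([0]), np.array([0])),
        z_step=2.0,
    )


class TestProfilesDispersion:
    def test_constant_map_flat_profile(self):
        maps = synthetic_maps([0.5, 0.5, 0.5])
        prof = depth_profiles(maps)
        assert np.allclose(prof["VVD"]["mean"], 0.5)

    def test_undefined_slab_is_gap(self):
        maps = synthetic_maps([0.5, np.nan, 0.7])
        prof = depth_profiles(maps)
        assert np.isnan(prof["VVD"]["mean"][1])

    def test_step_profile(self, rng):
        A = np.zeros((32, 16, 16), dtype=bool)
        A[16:, :, :] = rng.random((16, 16, 16)) > 0.3
        maps = window_metrics(build_label_volumes(A), window=8, stride=8)
        prof = depth_profiles(maps)["VVD"]["mean"]
        assert prof[0] < 0.05 and prof[-1] > 0.3

    def test_dispersion_constant_field(self):
        grid = np.full((4, 3, 3), 2.0)
        values = {name: grid.copy() for name in METRIC_NAMES}
        defined = {name: np.ones_like(grid, bool) for name in METRIC_NAMES}
        maps = MetricMaps(values, defined, 8, 8, (np.arange(4) * 8, np.arange(3), np.arange(3)))
        stats = dispersion(maps, region_of_bin=[1, 1, 2, 2])
        assert np.allclose(stats.cv["VVD"], 0.0)
        assert stats.mcv["VVD"][1] == 0.0
        assert stats.dmcv["VVD"][(1, 2)] == 0.0

    def test_dispersion_cv_definition_and_dmcv(self):
        # bin 0: values with std/mean = 0.5; bin 1: cv = 0.2
        def bin_values(mean, cv, n=16):
            half = n // 2
            delta = mean * cv
            return [mean - delta] * half + [mean + delta] * half

        grid = np.array([bin_values(1.0, 0.5), bin_values(1.0, 0.2)])[:, :, None]
        values = {name: grid.copy() for name in METRIC_NAMES}
        defined = {name: np.ones_like(grid, bool) for name in METRIC_NAMES}
        maps = MetricMaps(values, defined, 8, 8, (np.arange(2) * 8, np.arange(16), np.array([0])))
        stats = dispersion(maps, region_of_bin=[1, 2])
        assert stats.cv["VVD"][0] == pytest.approx(0.5)
        assert stats.cv["VVD"][1] == pytest.approx(0.2)
        assert stats.dmcv["VVD"][(1, 2)] == pytest.approx(0.3)


class TestCorrelationAndStats:
    def test_self_correlation_flagged(self, rng):
        A = rng.random((24, 24, 24)) > 0.5
        maps = window_metrics(build_label_volumes(A), window=8, stride=4)
        r, flags = metric_correlation(maps)
        assert np.allclose(np.diag(r), 1.0)
        assert np.all(np.diag(flags))

    def test_independent_random_maps_unflagged(self, rng):
        grid_shape = (40, 1, 1)
        values = {name: rng.random(grid_shape) for name in METRIC_NAMES}
        defined = {name: np.ones(grid_shape, bool) for name in METRIC_NAMES}
        maps = MetricMaps(values, defined, 8, 8, (np.arange(40) * 8, np.array([0]), np.array([0])))
        r, flags = metric_correlation(maps)
        off_diag = flags & ~np.eye(5, dtype=bool)
        assert not off_diag.any()

    def test_vvd_vsi_dependence_on_phantom_flagged(self):
        cfg = PhantomConfig(shape=(32, 64, 64), n_vessels=6, radius_range=(3.0, 3.0))
        _, truth = generate_vessels(cfg, seed=3)
        maps = window_metrics(build_label_volumes(truth.voxels), window=16, stride=8)
        r, flags = metric_correlation(maps)
        i, j = METRIC_NAMES.index("VVD"), METRIC_NAMES.index("VSI")
        assert abs(r[i, j]) >= 0.7
        assert flags[i, j]

    def test_too_few_windows_rejected(self):
        maps = synthetic_maps([0.5, np.nan, np.nan])
        with pytest.raises(ValueError):
            metric_correlation(maps)

    def test_identical_groups_f_near_zero(self, rng):
        g = rng.random(20)
        out = region_stats({1: g, 2: g.copy(), 3: g.copy()})
        assert out["test"]["kind"] == "anova"
        assert out["test"]["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_reject(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(10, 1, 20)
        c = rng.normal(5, 1, 20)
        out = region_stats({1: a, 2: b, 3: c})
        assert out["test"]["p_value"] < 0.05
        assert out["tukey"]["1-2"] < 0.05

    def test_two_group_t_test_and_normalization(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(10, 1, 20)
        out = region_stats({1: a, 2: b})
        assert out["test"]["kind"] == "welch_t"
        assert out["test"]["p_value"] < 0.001
        norms = [out["regions"][k]["normalized_mean"] for k in (1, 2)]
        assert min(norms) == 0.0 and max(norms) == 1.0

    def test_degenerate_group_warns(self, rng):
        with pytest.warns(RuntimeWarning):
            out = region_stats({1: rng.random(5), 2: np.array([1.0])})
        assert "test" not in out
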