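"""Radiomics: discretization, shape features, texture matrices vs oracles."""

import numpy as np
import pytest

from escprog.radiomics import (
    ROIMask,
    VoxelGrid,
    discretize,
    extract_all,
    extract_shape3d,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    registry_size,
)
from escprog.radiomics.base import UNIQUE_DIRECTIONS
from escprog.radiomics.texture import glcm_matrix, glrlm_matrix, glszm_matrix

from .conftest import make_ball_mask
from .oracles import glcm_bruteforce, glrlm_bruteforce, glszm_bruteforce


def _grid(arr, spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(arr, dtype=float), spacing)


def _plane(rows):
    """A 2D level layout as a 1-slice 3D quantized ROI."""
    levels = np.asarray(rows)[None, :, :]
    grid = _grid((levels - 1) * 25.0)
    return discretize(grid, ROIMask(np.ones_like(levels, bool)), 25.0)


class TestDiscretize:
    def test_constant_roi_single_level(self):
        q = discretize(_grid(np.full((2, 2, 2), 7.0)), ROIMask(np.ones((2, 2, 2))), 25)
        assert q.ng == 1 and set(q.roi_levels()) == {1}

    def test_floor_boundary(self):
        vals = np.array([0.0, 24.9, 25.0]).reshape(1, 1, 3)
        q = discretize(_grid(vals), ROIMask(np.ones((1, 1, 3))), 25)
        assert q.roi_levels().tolist() == [1, 1, 2]

    def test_uniform_range_bin_count(self, rng):
        vals = rng.uniform(0, 100, (4, 4, 4))
        vals[0, 0, 0], vals[0, 0, 1] = 0.0, 99.9  # pin the range
        q = discretize(_grid(vals), ROIMask(np.ones((4, 4, 4))), 25)
        assert q.ng == 4

    def test_rejects_nonpositive_bin_width(self):
        with pytest.raises(ValueError):
            discretize(_grid(np.ones((2, 2, 2))), ROIMask(np.ones((2, 2, 2))), 0)


class TestShape3D:
    def test_ball_sphericity_and_diameter(self):
        mask = make_ball_mask(48, 20)
        feats = extract_shape3d(_grid(np.zeros(mask.shape)), ROIMask(mask))
        assert abs(feats["Sphericity"] - 1.0) < 0.02
        assert abs(feats["Maximum3DDiameter"] - 40.0) / 40.0 < 0.05

    def test_sphericity_monotone_toward_one_with_radius(self):
        sph = []
        for r in (5, 10, 20):
            mask = make_ball_mask(48, r)
            f = extract_shape3d(_grid(np.zeros(mask.shape)), ROIMask(mask))
            sph.append(f["Sphericity"])
        assert sph[0] <= sph[1] + 0.01 and sph[1] <= sph[2] + 0.01
        assert all(s <= 1.0 for s in sph)

    def test_ellipsoid_least_axis_matches_moment_oracle(self):
        a, b, c = 20.0, 12.0, 6.0
        n = 48
        ctr = (n - 1) / 2
        zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        mask = ((zz - ctr) / a) ** 2 + ((yy - ctr) / b) ** 2 + (
            (xx - ctr) / c
        ) ** 2 <= 1.0
        feats = extract_shape3d(_grid(np.zeros(mask.shape)), ROIMask(mask))
        # independent moment computation straight from the voxel coordinates
        coords = np.argwhere(mask).astype(float)
        cov = np.cov(coords, rowvar=False)
        least = 4.0 * np.sqrt(np.sort(np.linalg.eigvalsh(cov))[0])
        assert abs(feats["LeastAxisLength"] - least) / least < 0.03

    def test_single_voxel_degenerate_values(self):
        mask = np.zeros((7, 7, 7), bool)
        mask[3, 3, 3] = True
        feats = extract_shape3d(_grid(np.zeros(mask.shape)), ROIMask(mask))
        assert feats["LeastAxisLength"] == 0.0
        assert feats["Maximum3DDiameter"] > 0  # the one-voxel mesh diameter
        assert feats["VoxelVolume"] == 1.0

    def test_spacing_scales_physical_features(self):
        mask = make_ball_mask(24, 8)
        f1 = extract_shape3d(_grid(np.zeros(mask.shape)), ROIMask(mask))
        f2 = extract_shape3d(
            _grid(np.zeros(mask.shape), spacing=(2.0, 2.0, 2.0)), ROIMask(mask)
        )
        assert f2["VoxelVolume"] == pytest.approx(8 * f1["VoxelVolume"])
        assert f2["Maximum3DDiameter"] == pytest.approx(
            2 * f1["Maximum3DDiameter"], rel=1e-6
        )


class TestGLSZM:
    def test_constant_roi_single_zone(self):
        q = discretize(
            _grid(np.full((3, 3, 3), 5.0)), ROIMask(np.ones((3, 3, 3))), 25
        )
        f = glszm_features(q)
        assert f["ZoneEntropy"] == 0.0
        assert f["GrayLevelNonUniformityNormalized"] == 1.0
        # single zone of size s: LargeAreaEmphasis = s^2
        assert f["LargeAreaEmphasis"] == 27.0**2

    def test_hand_layout_matches_flood_fill_oracle(self):
        q = _plane([[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 3, 3], [4, 4, 4, 4]])
        P = glszm_matrix(q)
        P_oracle = glszm_bruteforce(q.levels, q.mask)
        assert np.array_equal(P, P_oracle)
        # and all 16 features are finite on this layout
        f = glszm_features(q)
        assert len(f) == 16 and all(np.isfinite(v) for v in f.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tiny_rois_match_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        shape = (3, 6, 6)
        levels_src = rng.integers(1, 5, shape).astype(float)
        mask = rng.random(shape) < 0.8
        mask.flat[0] = True
        q = discretize(_grid((levels_src - 1) * 10.0), ROIMask(mask), 10.0)
        assert np.array_equal(glszm_matrix(q), glszm_bruteforce(q.levels, q.mask))


class TestGLRLM:
    def test_hand_grid_matches_run_enumeration_oracle(self):
        q = _plane([[1, 1, 2], [2, 2, 3], [3, 3, 3]])
        for direction in UNIQUE_DIRECTIONS:
            P = glrlm_matrix(q, direction)
            P_o = glrlm_bruteforce(q.levels, q.mask, direction)
            # pad to common width: trailing zero-columns are immaterial
            w = max(P.shape[1], P_o.shape[1])
            P = np.pad(P, ((0, 0), (0, w - P.shape[1])))
            P_o = np.pad(P_o, ((0, 0), (0, w - P_o.shape[1])))
            assert np.array_equal(P, P_o), direction

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tiny_rois_match_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        shape = (3, 5, 5)
        levels_src = rng.integers(1, 5, shape).astype(float)
        mask = rng.random(shape) < 0.75
        mask.flat[-1] = True
        q = discretize(_grid((levels_src - 1) * 10.0), ROIMask(mask), 10.0)
        for direction in [(0, 0, 1), (0, 1, 0), (1, 0, 0), (0, 1, 1), (1, 1, 1)]:
            P = glrlm_matrix(q, direction)
            P_o = glrlm_bruteforce(q.levels, q.mask, direction)
            w = max(P.shape[1], P_o.shape[1])
            P = np.pad(P, ((0, 0), (0, w - P.shape[1])))
            P_o = np.pad(P_o, ((0, 0), (0, w - P_o.shape[1])))
            assert np.array_equal(P, P_o)

    def test_feature_count_and_run_percentage_bounds(self):
        q = _plane([[1, 2, 1], [2, 1, 2], [1, 2, 1]])
        f = glrlm_features(q)
        assert len(f) == 16
        assert 0 < f["RunPercentage"] <= 1.0


class TestGLCM:
    def test_constant_roi_zero_contrast(self):
        q = discretize(
            _grid(np.full((3, 3, 3), 9.0)), ROIMask(np.ones((3, 3, 3))), 25
        )
        f = glcm_features(q)
        assert f["Contrast"] == 0.0
        assert np.isnan(f["Correlation"])  # undefined on a flat region

    def test_checkerboard_counts_match_hand_enumeration(self):
        # 2x2 single-slice checkerboard [[1,2],[2,1]], symmetric counts
        # (each unordered pair contributes to both (i,j) and (j,i))
        q = _plane([[1, 2], [2, 1]])
        C = glcm_matrix(q, (0, 0, 1))  # two horizontal pairs, both (1,2)
        assert np.array_equal(C, [[0.0, 2.0], [2.0, 0.0]])
        D = glcm_matrix(q, (0, 1, 1))  # one diagonal pair (1,1)
        assert np.array_equal(D, [[2.0, 0.0], [0.0, 0.0]])
        A = glcm_matrix(q, (0, 1, -1))  # one anti-diagonal pair (2,2)
        assert np.array_equal(A, [[0.0, 0.0], [0.0, 2.0]])

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tiny_rois_match_pair_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        shape = (3, 4, 4)
        levels_src = rng.integers(1, 5, shape).astype(float)
        mask = rng.random(shape) < 0.8
        mask.flat[0] = True
        q = discretize(_grid((levels_src - 1) * 10.0), ROIMask(mask), 10.0)
        for direction in UNIQUE_DIRECTIONS:
            assert np.array_equal(
                glcm_matrix(q, direction),
                glcm_bruteforce(q.levels, q.mask, direction),
            )

    def test_mirror_invariance(self, rng):
        vals = rng.normal(100, 20, (4, 5, 5))
        mask = np.ones(vals.shape, bool)
        q1 = discretize(_grid(vals), ROIMask(mask), 25)
        q2 = discretize(_grid(vals[:, :, ::-1].copy()), ROIMask(mask), 25)
        f1, f2 = glcm_features(q1), glcm_features(q2)
        for name in f1:
            assert f1[name] == pytest.approx(f2[name], rel=1e-9), name

    def test_single_voxel_roi_flagged_undefined(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        q = discretize(_grid(np.ones((3, 3, 3))), ROIMask(mask), 25)
        f = glcm_features(q)
        assert all(np.isnan(v) for v in f.values())

    def test_probability_matrix_sums_to_one(self, rng):
        vals = rng.normal(0, 30, (3, 4, 4))
        q = discretize(_grid(vals), ROIMask(np.ones(vals.shape, bool)), 20)
        for direction in UNIQUE_DIRECTIONS:
            C = glcm_matrix(q, direction)
            if C.sum() > 0:
                assert (C / C.sum()).sum() == pytest.approx(1.0, abs=1e-9)


class TestGLDMAndNGTDM:
    def test_constant_roi(self):
        q = discretize(
            _grid(np.full((3, 3, 3), 4.0)), ROIMask(np.ones((3, 3, 3))), 25
        )
        assert ngtdm_features(q)["Contrast"] == 0.0
        f = gldm_features(q)
        assert len(f) == 14
        # every voxel depends on all its in-mask neighbors
        assert f["GrayLevelNonUniformity"] == 27.0

    def test_two_voxel_firstorder(self):
        from escprog.radiomics import firstorder_features

        vals = np.zeros((1, 1, 2))
        vals[0, 0, 1] = 10.0
        f = firstorder_features(_grid(vals), ROIMask(np.ones((1, 1, 2))))
        assert f["Mean"] == 5.0 and f["Range"] == 10.0
        assert len(f) == 19

    def test_constant_roi_firstorder_variance_zero(self):
        from escprog.radiomics import firstorder_features

        f = firstorder_features(
            _grid(np.full((2, 2, 2), 3.0)), ROIMask(np.ones((2, 2, 2)))
        )
        assert f["Variance"] == 0.0 and np.isnan(f["Skewness"])

    def test_gldm_dependence_counts_on_hand_plane(self):
        # center voxel of a uniform 3x3 plane has 8 dependent neighbors
        q = _plane([[1, 1, 1], [1, 1, 1], [1, 1, 1]])
        from escprog.radiomics.texture import gldm_matrix

        P = gldm_matrix(q, alpha=0)
        # dependencies: 4 corners j=3+1, 4 edges j=5+1, 1 center j=8+1
        assert P[0, 3] == 4 and P[0, 5] == 4 and P[0, 8] == 1


class TestExtractAll:
    def test_core_registry_counts_105(self):
        assert registry_size(False) == 105
        assert registry_size(True) == 110

    def test_ball_case_table_features_present_and_finite(self, rng):
        mask = make_ball_mask(32, 10)
        vol = rng.normal(100, 25, mask.shape)
        vec = extract_all(_grid(vol), ROIMask(mask))
        wanted = [
            "original_shape_LeastAxisLength",
            "original_shape_Maximum2DDiameterColumn",
            "original_shape_Maximum3DDiameter",
            "original_shape_Sphericity",
            "original_glszm_GrayLevelNonUniformityNormalized",
            "original_glszm_LargeAreaEmphasis",
            "original_glszm_ZoneEntropy",
            "original_ngtdm_Contrast",
        ]
        for name in wanted:
            assert name in vec.values and np.isfinite(vec.values[name]), name
        assert 0 < vec.values["original_shape_Sphericity"] <= 1.0
        assert 0 < vec.values["original_glszm_GrayLevelNonUniformityNormalized"] <= 1.0
        assert vec.values["original_glszm_ZoneEntropy"] >= 0.0

    def test_deterministic(self, rng):
        mask = make_ball_mask(24, 7)
        vol = rng.normal(80, 20, mask.shape)
        v1 = extract_all(_grid(vol), ROIMask(mask))
        v2 = extract_all(_grid(vol), ROIMask(mask))
        assert v1.values == v2.values

    def test_texture_shift_invariance(self, rng):
        """Adding a constant before min-referenced binning leaves every
        texture feature unchanged."""
        mask = make_ball_mask(24, 7)
        vol = rng.normal(80, 20, mask.shape)
        v1 = extract_all(_grid(vol), ROIMask(mask))
        v2 = extract_all(_grid(vol + 500.0), ROIMask(mask))
        for name, val in v1.values.items():
            cls = v1.classes[name]
            if cls in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
                assert val == pytest.approx(v2.values[name], rel=1e-9), name

    def test_mask_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            extract_all(_grid(np.ones((3, 3, 3))), ROIMask(np.ones((4, 4, 4))))
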