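import numpy as np
import pytest

from radiofusion import radiomics as rad
from radiofusion import synthetic as syn

from oracles import naive_gldm, naive_glrlm_one_direction, naive_glszm


def roi_from_levels(levels):
    levels = np.asarray(levels, dtype=np.int64)
    return rad.DiscretizedROI(
        levels=levels,
        Ng=int(levels.max()),
        Np=int((levels > 0).sum()),
        bin_width=1.0,
    )


class TestDiscretize:
    def test_formula_and_anchoring(self):
        img = np.array([[[0.0, 24.9, 25.0, 50.0]]])
        mask = np.ones_like(img, bool)
        roi = rad.discretize(img, mask, bin_width=25.0)
        assert roi.levels.ravel().tolist() == [1, 1, 2, 3]
        assert roi.Ng == 3 and roi.Np == 4

    def test_outside_mask_is_level_zero(self, rng):
        img = rng.normal(size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.4
        roi = rad.discretize(img, mask, bin_width=0.5)
        assert np.all(roi.levels[~mask] == 0)
        assert np.all(roi.levels[mask] >= 1)

    def test_empty_mask_and_bad_width_raise(self):
        img = np.zeros((3, 3, 3))
        with pytest.raises(ValueError, match="empty"):
            rad.discretize(img, np.zeros_like(img, bool))
        with pytest.raises(ValueError, match="bin_width"):
            rad.discretize(img, np.ones_like(img, bool), bin_width=0.0)

    def test_shift_invariance(self, rng):
        img = rng.normal(size=(5, 5, 5))
        mask = np.ones((5, 5, 5), bool)
        a = rad.discretize(img, mask, 0.3).levels
        b = rad.discretize(img + 123.456, mask, 0.3).levels
        assert np.array_equal(a, b)


class TestGLDM:
    def test_uniform_cube_hand_counts(self):
        # 3x3x3 constant cube: 8 corners (7 neighbors), 12 edges (11),
        # 6 faces (17), 1 center (26)
        roi = roi_from_levels(np.ones((3, 3, 3), int))
        m = rad.gldm(roi)
        assert m.matrix.shape == (1, 27)
        assert m.matrix[0, 7] == 8
        assert m.matrix[0, 11] == 12
        assert m.matrix[0, 17] == 6
        assert m.matrix[0, 26] == 1
        assert m.total == 27.0

    def test_dnn_of_uniform_cube(self):
        roi = roi_from_levels(np.ones((3, 3, 3), int))
        dnn = rad.feature_gldm_dnn(rad.gldm(roi))
        assert dnn == pytest.approx((64 + 144 + 36 + 1) / 729.0)

    def test_single_voxel_dnn_is_one(self):
        levels = np.zeros((3, 3, 3), int)
        levels[1, 1, 1] = 1
        assert rad.feature_gldm_dnn(rad.gldm(roi_from_levels(levels))) == 1.0

    def test_alpha_widens_dependence(self):
        levels = np.array([[[1, 2, 3]]])
        roi = roi_from_levels(levels)
        strict = rad.gldm(roi, alpha=0)
        loose = rad.gldm(roi, alpha=1)
        assert strict.matrix.sum(axis=0)[0] == 3  # no equal neighbors
        assert loose.matrix.sum(axis=0)[0] == 0  # every neighbor within 1

    def test_matches_bruteforce_on_random_volumes(self, rng):
        for _ in range(25):
            levels = rng.integers(0, 4, size=(4, 4, 4))
            if not (levels > 0).any():
                continue
            got = rad.gldm(roi_from_levels(levels)).matrix
            assert np.array_equal(got, naive_gldm(levels))


class TestGLRLM:
    def test_thirteen_unique_directions(self):
        assert len(set(rad.DIRECTIONS_13)) == 13
        # no direction is the negation of another
        as_set = {tuple(d) for d in rad.DIRECTIONS_13}
        for d in rad.DIRECTIONS_13:
            assert tuple(-np.array(d)) not in as_set

    def test_hand_worked_line(self):
        # levels 1,1,2,2,2 along x: runs (1,len2) and (2,len3) in direction x
        levels = np.array([1, 1, 2, 2, 2]).reshape(5, 1, 1)
        m = rad.glrlm(roi_from_levels(levels))
        dir_x = list(rad.DIRECTIONS_13).index((1, 0, 0))
        mat = m.per_direction[dir_x]
        assert mat[0, 1] == 1 and mat[1, 2] == 1 and mat.sum() == 2
        # orthogonal direction: 5 runs of length 1
        dir_y = list(rad.DIRECTIONS_13).index((0, 1, 0))
        assert m.per_direction[dir_y][:, 0].sum() == 5

    def test_run_conservation_per_direction(self, rng):
        levels = rng.integers(0, 3, size=(5, 5, 5))
        levels[2, 2, 2] = 1
        roi = roi_from_levels(levels)
        m = rad.glrlm(roi)
        lengths = np.arange(1, m.per_direction[0].shape[1] + 1)
        for mat in m.per_direction:
            assert (mat * lengths).sum() == roi.Np

    def test_variance_and_glnn_hand_values(self):
        # single direction view: runs (1,len2),(2,len3) -> p = [0.5, 0.5]
        levels = np.array([1, 1, 2, 2, 2]).reshape(1, 1, 5)
        m = rad.glrlm(roi_from_levels(levels))
        dir_z = list(rad.DIRECTIONS_13).index((0, 0, 1))
        only_z = rad.TextureMatrix(
            kind="GLRLM",
            matrix=m.per_direction[dir_z],
            total=float(m.per_direction[dir_z].sum()),
            per_direction=[m.per_direction[dir_z]],
        )
        assert rad.feature_glrlm_variance(only_z) == pytest.approx(0.25)
        assert rad.feature_glrlm_glnn(only_z) == pytest.approx(0.5)

    def test_constant_image_identities(self):
        roi = roi_from_levels(np.ones((4, 4, 4), int))
        m = rad.glrlm(roi)
        assert rad.feature_glrlm_variance(m) == pytest.approx(0.0)
        assert rad.feature_glrlm_glnn(m) == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_volumes(self, rng):
        for _ in range(10):
            levels = rng.integers(0, 4, size=(4, 4, 4))
            if not (levels > 0).any():
                continue
            m = rad.glrlm(roi_from_levels(levels))
            for d, mat in zip(rad.DIRECTIONS_13, m.per_direction):
                ref = naive_glrlm_one_direction(levels, d)
                assert np.array_equal(mat[:, : ref.shape[1]], ref), d
                assert mat[:, ref.shape[1]:].sum() == 0


class TestGLSZM:
    def test_two_zones_same_level(self):
        levels = np.zeros((5, 5, 5), int)
        levels[0, 0, 0] = 1
        levels[4, 4, 4] = 1
        m = rad.glszm(roi_from_levels(levels))
        assert m.matrix[0, 0] == 2
        assert m.total == 2.0

    def test_diagonal_touch_is_one_zone(self):
        levels = np.zeros((4, 4, 4), int)
        levels[0, 0, 0] = 1
        levels[1, 1, 1] = 1
        m = rad.glszm(roi_from_levels(levels))
        assert m.matrix[0, 1] == 1  # one zone of size 2 (26-connectivity)

    def test_zone_percentage_constant_image(self):
        roi = roi_from_levels(np.ones((4, 4, 4), int))
        m = rad.glszm(roi)
        assert rad.feature_glszm_zone_percentage(m, roi.Np) == pytest.approx(
            1.0 / 64.0
        )

    def test_checkerboard_is_one_zone_per_level(self):
        # at 26-connectivity a 3D checkerboard parity class is fully
        # diagonally connected, so each level forms a single zone
        i, j, k = np.indices((4, 4, 4))
        levels = 1 + ((i + j + k) % 2)
        m = rad.glszm(roi_from_levels(levels))
        assert m.matrix[0, 31] == 1 and m.matrix[1, 31] == 1

    def test_matches_bruteforce_on_random_volumes(self, rng):
        for _ in range(15):
            levels = rng.integers(0, 4, size=(4, 4, 4))
            if not (levels > 0).any():
                continue
            got = rad.glszm(roi_from_levels(levels)).matrix
            ref = naive_glszm(levels)
            assert got.shape == ref.shape and np.array_equal(got, ref)


class TestShape:
    def test_sphere_descriptor_close_to_analytic(self, rng):
        mask = syn.generate_mask([8, 8, 8], (32, 32, 32), rng, perturb_amp=0.0)
        d = rad.shape_descriptor(mask, (1, 1, 1))
        assert d.mesh_volume == pytest.approx(4 / 3 * np.pi * 8**3, rel=0.05)
        assert d.mesh_surface_area == pytest.approx(4 * np.pi * 8**2, rel=0.05)
        feats = rad.feature_shape(d)
        assert feats["sphericity"] == pytest.approx(1.0, abs=0.03)
        assert feats["surface_to_volume_ratio"] == pytest.approx(3 / 8, rel=0.05)
        assert feats["flatness"] == pytest.approx(1.0, abs=0.05)

    def test_spacing_scales_physical_quantities(self, rng):
        mask = syn.generate_mask([6, 6, 6], (24, 24, 24), rng, perturb_amp=0.0)
        d1 = rad.shape_descriptor(mask, (1, 1, 1))
        d2 = rad.shape_descriptor(mask, (2, 2, 2))
        assert d2.mesh_volume == pytest.approx(8 * d1.mesh_volume, rel=0.02)
        assert d2.mesh_surface_area == pytest.approx(
            4 * d1.mesh_surface_area, rel=0.02
        )
        assert d2.voxel_volume == pytest.approx(8 * d1.voxel_volume)

    def test_flatness_of_anisotropic_ellipsoid(self, rng):
        mask = syn.generate_mask([12, 8, 4], (32, 32, 32), rng, perturb_amp=0.0)
        f = rad.feature_shape(rad.shape_descriptor(mask, (1, 1, 1)))
        # PCA flatness of a solid ellipsoid = least/major semi-axis ratio
        assert f["flatness"] == pytest.approx(4 / 12, rel=0.08)

    def test_degenerate_masks_raise(self):
        with pytest.raises(ValueError, match="empty"):
            rad.shape_descriptor(np.zeros((4, 4, 4), bool), (1, 1, 1))
        thin = np.zeros((6, 6, 6), bool)
        thin[2, :, :] = True
        with pytest.raises(ValueError, match="too thin"):
            rad.shape_descriptor(thin, (1, 1, 1))


class TestFeatureExtraction:
    def test_default_feature_names_and_order(self, small_cohort):
        feats = rad.extract_features(small_cohort[0], bin_width=0.25)
        assert tuple(feats) == rad.DEFAULT_FEATURES
        assert all(np.isfinite(v) for v in feats.values())

    def test_unknown_feature_raises_with_listing(self, small_cohort):
        with pytest.raises(KeyError, match="glcm_entropy"):
            rad.extract_features(small_cohort[0], registry=["glcm_entropy"])

    def test_absent_primary_channel_raises(self, small_cohort):
        import copy

        s = copy.deepcopy(small_cohort[0])
        s.present_channels[0] = False
        with pytest.raises(ValueError, match="primary channel"):
            rad.extract_features(s)

    def test_feature_table_shape_and_index(self, small_cohort, small_features):
        assert small_features.shape == (24, len(rad.DEFAULT_FEATURES))
        assert list(small_features.index) == [
            s.subject_id for s in small_cohort
        ]
        assert small_features.notna().all().all()

    def test_translation_invariance(self, rng):
        # the same masked content placed at two positions gives identical
        # texture and shape features
        cfg = syn.CohortConfig(n_subjects=3, seed=9)
        s = syn.generate_cohort(cfg)[0]
        rolled_img = np.roll(s.images[0], (2, -1, 1), axis=(0, 1, 2))
        rolled_mask = np.roll(s.mask, (2, -1, 1), axis=(0, 1, 2))
        moved = syn.SubjectVolume(
            subject_id="moved",
            images=rolled_img[None],
            present_channels=np.array([True]),
            mask=rolled_mask,
            spacing=s.spacing,
            label=s.label,
        )
        a = rad.extract_features(s, bin_width=0.25)
        b = rad.extract_features(moved, bin_width=0.25)
        for name in a:
            # texture features are exactly equal; mesh quantities agree to
            # filter-truncation precision at the volume boundary
            assert a[name] == pytest.approx(b[name], rel=1e-5), name
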