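"""Feature registry and radiomics feature extraction oracles."""

import numpy as np
import pytest

from radiogcn.features import BIN_COUNT, discretize, extract_features
from radiogcn.preprocess import ImageVolume, LesionMask
from radiogcn.registry import build_feature_registry
from radiogcn.synthetic import PhantomSpec, simulate_phantom


def _patch(values, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(values=np.asarray(values, dtype=float), spacing=spacing)


def _mask(values, spacing=(1.0, 1.0, 1.0)):
    return LesionMask(values=np.asarray(values, dtype=np.uint8), spacing=spacing)


@pytest.fixture(scope="module")
def registry():
    return build_feature_registry()


@pytest.fixture(scope="module")
def original_registry():
    return build_feature_registry({"image_types": ["original"],
                                   "max_features": None})


class TestRegistry:
    def test_default_has_1290_entries(self, registry):
        assert len(registry) == 1290

    def test_original_only_has_107_entries(self, original_registry):
        assert len(original_registry) == 107
        by_class = {}
        for e in original_registry.entries:
            by_class[e.feature_class] = by_class.get(e.feature_class, 0) + 1
        assert by_class == {"shape": 14, "firstorder": 18, "glcm": 24,
                            "glrlm": 16, "glszm": 16, "ngtdm": 5, "gldm": 14}

    def test_empty_config_rejected(self):
        with pytest.raises(ValueError):
            build_feature_registry({"feature_classes": []})
        with pytest.raises(ValueError):
            build_feature_registry({"image_types": []})

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError):
            build_feature_registry({"bogus": 1})

    def test_order_and_hash_stable_across_builds(self, registry):
        again = build_feature_registry()
        assert registry.names == again.names
        assert registry.sha256 == again.sha256

    def test_names_unique(self, registry):
        assert len(set(registry.names)) == len(registry)


class TestFirstOrder:
    def test_constant_lesion_closed_forms(self, original_registry):
        patch = _patch(np.full((3, 3, 3), 7.0))
        mask = _mask(np.ones((3, 3, 3)))
        vec = dict(zip(original_registry.names,
                       extract_features(patch, mask, original_registry)))
        assert vec["original_firstorder_Mean"] == 7.0
        assert vec["original_firstorder_Range"] == 0.0
        assert vec["original_firstorder_Variance"] == 0.0
        assert vec["original_firstorder_Energy"] == 27 * 49.0

    def test_known_value_set(self, original_registry):
        vals = np.zeros((1, 1, 4))
        vals[0, 0] = [1.0, 2.0, 3.0, 4.0]
        vec = dict(zip(original_registry.names,
                       extract_features(_patch(vals), _mask(np.ones((1, 1, 4))),
                                        original_registry)))
        assert vec["original_firstorder_Mean"] == 2.5
        assert vec["original_firstorder_Median"] == 2.5
        assert vec["original_firstorder_Range"] == 3.0
        assert vec["original_firstorder_Variance"] == pytest.approx(1.25)
        assert vec["original_firstorder_RootMeanSquared"] == pytest.approx(
            np.sqrt(30.0 / 4))
        assert vec["original_firstorder_MeanAbsoluteDeviation"] == 1.0


class TestShape:
    def test_voxel_volume_counts_voxels_times_spacing(self, original_registry):
        m = np.zeros((4, 4, 4))
        m[1:3, 1:3, 1:3] = 1  # 8 voxels
        spacing = (2.0, 1.5, 0.5)
        vec = dict(zip(original_registry.names,
                       extract_features(_patch(np.random.default_rng(0)
                                               .normal(size=(4, 4, 4)), spacing),
                                        _mask(m, spacing), original_registry)))
        assert vec["original_shape_VoxelVolume"] == pytest.approx(8 * 1.5)

    def test_cube_diameters_and_axis_order(self, original_registry):
        m = np.zeros((6, 6, 6))
        m[1:5, 1:3, 1:2] = 1  # 4 x 2 x 1 voxel box
        vec = dict(zip(original_registry.names,
                       extract_features(_patch(np.zeros((6, 6, 6))),
                                        _mask(m), original_registry)))
        # maximum 3-D diameter spans opposite voxel centres of the box
        assert vec["original_shape_Maximum3DDiameter"] == pytest.approx(
            np.sqrt(3 ** 2 + 1 ** 2 + 0 ** 2))
        assert vec["original_shape_MajorAxisLength"] >= \
            vec["original_shape_MinorAxisLength"] >= \
            vec["original_shape_LeastAxisLength"]

    def test_sphere_mesh_volume_and_sphericity(self, original_registry):
        spec = PhantomSpec(volume_shape=(21, 21, 21), voxel_spacing=(1, 1, 1),
                           lesion_radii=(8, 8, 8), texture_sd=0.0, seed=0)
        vols, mask = simulate_phantom(spec)
        vec = dict(zip(original_registry.names,
                       extract_features(vols["T1-CE"], mask, original_registry)))
        analytic = 4.0 / 3.0 * np.pi * 8 ** 3
        assert vec["original_shape_MeshVolume"] == pytest.approx(analytic, rel=0.05)
        assert 0.9 < vec["original_shape_Sphericity"] <= 1.05
        assert vec["original_shape_Elongation"] == pytest.approx(1.0, abs=0.05)


class TestTextureOracles:
    def test_discretize_fixed_bin_count(self):
        vals = np.linspace(0, 1, 64).reshape(4, 4, 4)
        lev, ng = discretize(vals, np.ones((4, 4, 4)))
        assert ng == BIN_COUNT
        assert lev.min() == 1 and lev.max() == BIN_COUNT

    def test_constant_region_collapses_to_single_level(self):
        lev, ng = discretize(np.full((2, 2, 2), 3.0), np.ones((2, 2, 2)))
        assert ng == 1 and set(lev.ravel()) == {1}

    def test_constant_volume_texture_closed_forms(self, original_registry):
        # one gray level: GLSZM has a single zone covering all Np voxels,
        # GLDM a single dependence size 27 (26 neighbours + centre), NGTDM
        # coarseness hits its capped maximum
        patch = _patch(np.full((3, 3, 3), 5.0))
        mask = _mask(np.ones((3, 3, 3)))
        vec = dict(zip(original_registry.names,
                       extract_features(patch, mask, original_registry)))
        assert vec["original_glszm_ZonePercentage"] == pytest.approx(1 / 27)
        assert vec["original_glszm_LargeAreaEmphasis"] == pytest.approx(27 ** 2)
        assert vec["original_glszm_GrayLevelVariance"] == 0.0
        # dependence size per voxel = in-mask 26-neighbours + 1, enumerated
        sizes = []
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    nb = sum(1 for di in (-1, 0, 1) for dj in (-1, 0, 1)
                             for dk in (-1, 0, 1)
                             if (di, dj, dk) != (0, 0, 0)
                             and 0 <= i + di < 3 and 0 <= j + dj < 3
                             and 0 <= k + dk < 3)
                    sizes.append(nb + 1)
        sizes = np.array(sizes, dtype=float)
        assert vec["original_gldm_LargeDependenceEmphasis"] == pytest.approx(
            np.mean(sizes ** 2))
        assert vec["original_gldm_SmallDependenceEmphasis"] == pytest.approx(
            np.mean(1.0 / sizes ** 2))
        assert vec["original_ngtdm_Coarseness"] == pytest.approx(1e6)
        assert vec["original_glcm_Correlation"] == 1.0
        assert vec["original_glcm_JointEntropy"] == 0.0

    def test_glcm_two_level_line_hand_oracle(self, original_registry):
        # 1x1x4 line [a, a, b, b]: only direction (0,0,1) has pairs;
        # symmetrized pair counts: (1,1)x2, (1,32)+(32,1), (32,32)x2
        vals = np.zeros((1, 1, 4))
        vals[0, 0] = [0.0, 0.0, 1.0, 1.0]
        vec = dict(zip(original_registry.names,
                       extract_features(_patch(vals), _mask(np.ones((1, 1, 4))),
                                        original_registry)))
        p = np.array([[2, 1], [1, 2]]) / 6.0
        contrast = ((BIN_COUNT - 1) ** 2) * (p[0, 1] + p[1, 0])
        assert vec["original_glcm_Contrast"] == pytest.approx(contrast)
        joint_entropy = -np.sum(p * np.log2(p))
        assert vec["original_glcm_JointEntropy"] == pytest.approx(joint_entropy)
        assert vec["original_glcm_MaximumProbability"] == pytest.approx(2 / 6)

    def test_glrlm_two_level_line_hand_oracle(self, original_registry):
        # same line: along (0,0,1) two runs of length 2; the other 12
        # directions each see four runs of length 1
        vals = np.zeros((1, 1, 4))
        vals[0, 0] = [0.0, 0.0, 1.0, 1.0]
        vec = dict(zip(original_registry.names,
                       extract_features(_patch(vals), _mask(np.ones((1, 1, 4))),
                                        original_registry)))
        # ShortRunEmphasis: 1 direction -> mean(1/4, 1/4) = 0.25;
        # 12 directions -> 1.0; averaged over the 13 directions
        sre = (0.25 + 12 * 1.0) / 13.0
        assert vec["original_glrlm_ShortRunEmphasis"] == pytest.approx(sre)
        rp = (2 / 4 + 12 * 1.0) / 13.0
        assert vec["original_glrlm_RunPercentage"] == pytest.approx(rp)


class TestExtraction:
    def test_two_runs_identical(self, original_registry):
        rng = np.random.default_rng(1)
        patch = _patch(rng.normal(size=(4, 5, 5)))
        m = np.zeros((4, 5, 5))
        m[1:3, 1:4, 1:4] = 1
        v1 = extract_features(patch, _mask(m), original_registry)
        v2 = extract_features(patch, _mask(m), original_registry)
        np.testing.assert_array_equal(v1, v2)

    def test_empty_mask_rejected(self, original_registry):
        with pytest.raises(ValueError):
            extract_features(_patch(np.zeros((2, 2, 2))),
                             _mask(np.zeros((2, 2, 2))), original_registry)

    def test_full_registry_vector_is_finite_and_ordered(self, registry):
        spec = PhantomSpec(volume_shape=(6, 16, 16), voxel_spacing=(3, 1, 1),
                           lesion_radii=(4, 5, 5), seed=2)
        vols, mask = simulate_phantom(spec)
        vec = extract_features(vols["T2W"], mask, registry)
        assert vec.shape == (1290,)
        assert np.all(np.isfinite(vec))
        # shape features sit at the registry head in canonical order
        assert registry.entries[0].feature_class == "shape"
        assert registry.entries[14].feature_class == "firstorder"
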