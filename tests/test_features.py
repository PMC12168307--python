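import numpy as np
import pytest

import oracles
from nephroradiomics.cohort import CLASS_RENAL, coarse_grid, default_cohort_spec, generate_kidney_phantom
from nephroradiomics.errors import EmptyVOIError, FeatureComputationError
from nephroradiomics.features import (
    bank_feature_names,
    compute_feature,
    compute_feature_vector,
    default_bank_manifest,
    firstorder_features,
    restricted_manifest,
    shape_features,
)
from nephroradiomics.texture import (
    DiscretizedVOI,
    build_glcm,
    build_gldm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    discretize,
    glcm_features,
    gldm_features,
    glszm_features,
    ngtdm_features,
)


def _dvoi(levels, ng):
    return DiscretizedVOI(np.asarray(levels, dtype=np.int32), ng, np.array([0.0, 1.0]),
                          (1.0, 1.0, 1.0))


class TestDiscretize:
    def test_integer_ramp_maps_to_identity_levels(self):
        vol = np.arange(32, dtype=float).reshape(2, 4, 4)
        mask = np.ones_like(vol, dtype=bool)
        d = discretize(vol, mask, 32)
        np.testing.assert_array_equal(np.sort(np.unique(d.levels)), np.arange(1, 33))
        assert d.levels.ravel()[0] == 1 and d.levels.ravel()[-1] == 32

    def test_constant_region_collapses_to_single_level(self):
        vol = np.full((3, 3, 3), 4.2)
        d = discretize(vol, np.ones((3, 3, 3), bool), 32)
        assert d.ng == 1
        assert set(np.unique(d.levels)) == {1}

    def test_histogram_is_order_independent(self, rng):
        vol = rng.standard_normal((5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.8
        d1 = discretize(vol, mask, 8)
        shuffled = vol.copy()
        d2 = discretize(shuffled, mask, 8)
        h1 = np.bincount(d1.levels[d1.levels > 0], minlength=9)
        h2 = np.bincount(d2.levels[d2.levels > 0], minlength=9)
        np.testing.assert_array_equal(h1, h2)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyVOIError):
            discretize(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool), 8)


class TestMatrixOracleEquivalence:
    """All five builders match exhaustive enumeration on random instances."""

    @pytest.mark.parametrize("seed", range(8))
    def test_all_families_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            levels, ng = oracles.random_instance(rng)
            d = _dvoi(levels, ng)
            np.testing.assert_allclose(
                build_glcm(d).matrix, oracles.glcm_oracle(levels, ng), atol=1e-12
            )
            ours = build_glrlm(d).matrix
            ref = oracles.glrlm_oracle(levels, ng)
            np.testing.assert_allclose(ours[:, : ref.shape[1]], ref, atol=1e-12)
            ours = build_glszm(d).matrix
            ref = oracles.glszm_oracle(levels, ng)
            np.testing.assert_allclose(ours[:, : ref.shape[1]], ref, atol=1e-12)
            np.testing.assert_allclose(
                build_gldm(d).matrix, oracles.gldm_oracle(levels, ng), atol=1e-12
            )
            np.testing.assert_allclose(
                build_ngtdm(d).matrix, oracles.ngtdm_oracle(levels, ng), atol=1e-12
            )

    def test_gldm_constant_cube_center_has_26_dependents(self):
        levels = np.ones((3, 3, 3), dtype=np.int32)
        mat = build_gldm(_dvoi(levels, 1)).matrix
        assert mat[0, 26] == 1  # only the center voxel sees all 26 neighbors
        assert mat.sum() == 27

    def test_two_disjoint_islands_make_two_zones(self):
        levels = np.zeros((5, 5, 1), dtype=np.int32)
        levels[0:2, 0:2, 0] = 1
        levels[3:5, 3:5, 0] = 1
        mat = build_glszm(_dvoi(levels, 1)).matrix
        assert mat.sum() == 2
        assert mat[0, 3] == 2  # two zones of size 4


class TestConservation:
    @pytest.mark.parametrize("seed", range(5))
    def test_family_totals(self, seed):
        rng = np.random.default_rng(100 + seed)
        levels, ng = oracles.random_instance(rng)
        d = _dvoi(levels, ng)
        npv = d.n_voxels
        glcm = build_glcm(d).matrix
        if glcm.sum() > 0:
            assert glcm.sum() == pytest.approx(1.0)
        assert build_gldm(d).matrix.sum() == npv
        glszm = build_glszm(d)
        sizes = np.arange(1, glszm.matrix.shape[1] + 1)
        assert (glszm.matrix * sizes).sum() == npv
        runs = build_glrlm(d)
        lens = np.arange(1, runs.matrix.shape[1] + 1)
        assert (runs.matrix * lens).sum() == npv * len(oracles.DIRS_13)
        ngtdm = build_ngtdm(d)
        if ngtdm.n_voxels:
            assert ngtdm.matrix[:, 0].sum() == ngtdm.n_voxels


class TestNamedFeatures:
    def test_constant_region_degenerate_conventions(self):
        levels = np.ones((2, 2, 1), dtype=np.int32)
        d = _dvoi(levels, 1)
        glcm = build_glcm(d)
        assert glcm.matrix.sum() == pytest.approx(1.0)
        assert glcm_features(glcm)["Idmn"] == pytest.approx(1.0)
        assert ngtdm_features(build_ngtdm(d))["Busyness"] == 0.0
        assert firstorder_features(np.full(4, 3.0))["InterquartileRange"] == 0.0

    def test_single_voxel_yields_finite_defaults(self):
        levels = np.zeros((3, 3, 3), dtype=np.int32)
        levels[1, 1, 1] = 1
        d = _dvoi(levels, 1)
        for builder, fn in [(build_glcm, glcm_features), (build_gldm, gldm_features),
                            (build_glszm, glszm_features), (build_ngtdm, ngtdm_features)]:
            vals = fn(builder(d))
            assert all(np.isfinite(v) for v in vals.values())

    @pytest.mark.parametrize("seed", range(6))
    def test_nine_selected_features_match_direct_summation(self, seed):
        """The nine model-selected feature formulas agree exactly with
        direct summation over brute-force matrices."""
        rng = np.random.default_rng(200 + seed)
        levels, ng = oracles.random_instance(rng)
        d = _dvoi(levels, ng)
        assert compute_feature(build_glcm(d), "Idmn") == pytest.approx(
            oracles.idmn_oracle(levels, ng), abs=1e-12)
        named = oracles.gldm_named_oracle(levels, ng)
        gldm = build_gldm(d)
        for k, v in named.items():
            assert compute_feature(gldm, k) == pytest.approx(v, abs=1e-12)
        assert compute_feature(build_glszm(d), "ZonePercentage") == pytest.approx(
            oracles.zone_percentage_oracle(levels, ng), abs=1e-12)
        assert compute_feature(build_ngtdm(d), "Busyness") == pytest.approx(
            oracles.busyness_oracle(levels, ng), abs=1e-12)
        vals = rng.standard_normal(40)
        fo = oracles.firstorder_named_oracle(vals)
        assert compute_feature(vals, "Maximum") == pytest.approx(fo["Maximum"])
        assert compute_feature(vals, "InterquartileRange") == pytest.approx(
            fo["InterquartileRange"])

    def test_unknown_feature_name_raises(self):
        with pytest.raises(FeatureComputationError):
            compute_feature(np.ones(5), "NotAFeature")


class TestFeatureVector:
    def test_default_bank_width_is_1246(self):
        assert len(bank_feature_names()) == 1246
        m = default_bank_manifest()
        assert len(m["image_types"]) == 15
        per_type = sum(len(m[f]) for f in
                       ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm"))
        assert per_type == 82
        assert len(m["shape"]) == 16

    def test_restricted_manifest_arithmetic(self, phantom):
        vec = compute_feature_vector(
            phantom.t2w, phantom.mask, phantom.spacing,
            manifest=restricted_manifest(["original"]),
        )
        assert len(vec) == 16 + 82

    def test_identical_inputs_give_identical_vectors(self, phantom):
        man = restricted_manifest(["original", "binomialblur"])
        v1 = compute_feature_vector(phantom.t2w, phantom.mask, phantom.spacing, manifest=man)
        v2 = compute_feature_vector(phantom.t2w.copy(), phantom.mask.copy(),
                                    phantom.spacing, manifest=man)
        assert v1.equals(v2)

    def test_translation_invariance_of_intensity_features(self, rng):
        vol = rng.standard_normal((14, 14, 14))
        mask = np.zeros((14, 14, 14), bool)
        mask[2:7, 3:8, 2:6] = True
        man = restricted_manifest(["original"])
        v1 = compute_feature_vector(vol, mask, (1, 1, 1), manifest=man)
        shift = (4, 3, 5)
        vol2 = np.roll(vol, shift, axis=(0, 1, 2))
        mask2 = np.roll(mask, shift, axis=(0, 1, 2))
        v2 = compute_feature_vector(vol2, mask2, (1, 1, 1), manifest=man)
        intensity = [c for c in v1.index if "_shape_" not in c]
        np.testing.assert_allclose(v1[intensity], v2[intensity], rtol=1e-10)

    def test_busyness_tracks_texture_correlation_length(self):
        """Busyness on the original T2 image rises monotonically (Spearman
        rho > 0.8) as the generator's correlation length shrinks."""
        import dataclasses

        from scipy.stats import spearmanr

        from nephroradiomics.cohort import TextureModel
        from nephroradiomics.texture import build_ngtdm, discretize, ngtdm_features

        lengths = np.linspace(8.0, 1.5, 20)
        busy = []
        for ell in lengths:
            spec = default_cohort_spec(master_seed=0, grid=coarse_grid())
            tex = {k: TextureModel(corr_length_mm=float(ell), amplitude=60.0)
                   for k in spec.texture_model}
            spec = dataclasses.replace(spec, texture_model=tex)
            s = generate_kidney_phantom(spec, CLASS_RENAL, 20, 777)
            d = discretize(s.t2w, s.mask.astype(bool), 32, s.spacing)
            busy.append(ngtdm_features(build_ngtdm(d))["Busyness"])
        rho = spearmanr(-lengths, busy).statistic
        assert rho > 0.8


class TestShapeFeatures:
    def test_sphere_is_nearly_spherical(self):
        x, y, z = np.mgrid[0:40, 0:40, 0:40]
        mask = (x - 20) ** 2 + (y - 20) ** 2 + (z - 20) ** 2 <= 15**2
        f = shape_features(mask, (1.0, 1.0, 1.0))
        assert f["Elongation"] == pytest.approx(1.0, abs=0.02)
        assert f["Flatness"] == pytest.approx(1.0, abs=0.02)
        assert f["Maximum3DDiameter"] == pytest.approx(30.0, rel=0.05)
        assert f["VoxelVolume"] == pytest.approx(4 / 3 * np.pi * 15**3, rel=0.02)

    def test_anisotropic_spacing_enters_axis_lengths(self):
        # 10x10x4 voxels at 1x1x5 mm: the slice axis spans 20 mm physically
        # and must become the major PCA axis
        mask = np.ones((10, 10, 4), bool)
        f = shape_features(mask, (1.0, 1.0, 5.0))
        var_z = np.var(np.arange(4) * 5.0)
        assert f["MajorAxisLength"] == pytest.approx(4 * np.sqrt(var_z))
        assert f["MinorAxisLength"] == pytest.approx(f["LeastAxisLength"])
        assert f["VoxelVolume"] == pytest.approx(10 * 10 * 4 * 5.0)
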