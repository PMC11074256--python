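"""Object-level feature extraction: spectral, geometric, texture, indices."""

import numpy as np
import pytest
from skimage.feature import graycomatrix

from obiaveg import (
    GlcmSpec,
    RasterScene,
    SceneConfig,
    build_feature_table,
    default_manifest,
    generate_scene,
    geometric_features,
    glcm,
    glcm_stats,
    gldv_stats,
    index_features,
    spectral_features,
)
from obiaveg.features import BAND_NAMES, FeatureManifest, gldv, quantize_gray


def flat_scene(values_by_band, segments=None, labels=None):
    """Constant-band scene helper."""
    shape = (6, 6)
    bands = {b: np.full(shape, values_by_band[i]) for i, b in enumerate(BAND_NAMES)}
    if segments is None:
        segments = np.ones(shape, dtype=np.int32)
    return RasterScene(bands=bands, segments=segments, labels=labels)


class TestSpectral:
    def test_constant_segment(self):
        scene = flat_scene([0.2, 0.2, 0.2, 0.2])
        out = spectral_features(scene, 1)
        for b in BAND_NAMES:
            assert out[f"mean_{b}"] == pytest.approx(0.2)
            assert out[f"sd_{b}"] == pytest.approx(0.0, abs=1e-12)
        assert out["brightness"] == pytest.approx(0.2)
        assert out["max_diff"] == 0.0

    def test_max_diff_hand_value(self):
        scene = flat_scene([0.1, 0.2, 0.3, 0.4])
        out = spectral_features(scene, 1)
        assert out["brightness"] == pytest.approx(0.25)
        assert out["max_diff"] == pytest.approx(1.2)  # (0.4-0.1)/0.25

    def test_single_pixel_sd_zero(self, small_scene):
        segments = np.ones((3, 3), dtype=np.int32)
        segments[1, 1] = 2
        rng = np.random.default_rng(0)
        bands = {b: rng.uniform(0, 1, (3, 3)) for b in BAND_NAMES}
        scene = RasterScene(bands=bands, segments=segments)
        out = spectral_features(scene, 2)
        assert all(out[f"sd_{b}"] == 0.0 for b in BAND_NAMES)

    def test_missing_segment(self):
        with pytest.raises(KeyError):
            spectral_features(flat_scene([0.1] * 4), 99)


class TestGeometric:
    def test_solid_square(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        out = geometric_features(mask)
        assert out["area"] == 100
        assert out["perimeter"] == 40
        assert out["length_width_ratio"] == pytest.approx(1.0)
        assert out["rect_fit"] == pytest.approx(1.0)

    def test_rectangle_side_ratio(self):
        # closed-form covariance of a uniform 20x5 rectangle gives ratio 4
        mask = np.zeros((24, 9), dtype=bool)
        mask[2:22, 2:7] = True
        out = geometric_features(mask)
        assert out["length_width_ratio"] == pytest.approx(4.0)
        assert out["rect_fit"] == pytest.approx(1.0)

    def test_single_pixel(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        out = geometric_features(mask)
        assert out["area"] == 1 and out["perimeter"] == 4
        assert out["length_width_ratio"] == pytest.approx(1.0)

    def test_translation_invariance(self, rng):
        base = rng.random((8, 8)) > 0.4
        base[4, 4] = True
        big = np.zeros((20, 20), dtype=bool)
        big[2:10, 3:11] = base
        shifted = np.zeros((20, 20), dtype=bool)
        shifted[9:17, 6:14] = base
        a, b = geometric_features(big), geometric_features(shifted)
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-9)

    def test_rotation_invariance_of_area_perimeter(self, rng):
        base = rng.random((9, 7)) > 0.4
        base[4, 3] = True
        pad = np.zeros((15, 15), dtype=bool)
        pad[3:12, 4:11] = base
        rot = np.rot90(pad)
        assert geometric_features(pad)["area"] == geometric_features(rot)["area"]
        assert geometric_features(pad)["perimeter"] == geometric_features(rot)["perimeter"]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            geometric_features(np.zeros((4, 4), dtype=bool))


class TestGlcm:
    def test_constant_image(self):
        P = glcm(np.zeros((4, 4), dtype=int), GlcmSpec(levels=4))
        assert P[0, 0] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    def test_two_by_two_enumeration(self):
        P = glcm(np.array([[0, 1], [0, 1]]), GlcmSpec(levels=2, offsets=((0, 1),)))
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            glcm(np.array([[0, 5]]), GlcmSpec(levels=4))

    def test_against_skimage_on_full_rectangles(self, rng):
        """Unmasked co-occurrence counts match scikit-image's."""
        for _ in range(10):
            img = rng.integers(0, 8, size=(12, 15))
            ours = glcm(img, GlcmSpec(levels=8, offsets=((0, 1),), symmetric=True,
                                      normalized=False))
            sk = graycomatrix(img.astype(np.uint8), [1], [0], levels=8,
                              symmetric=True, normed=False)[:, :, 0, 0]
            assert np.array_equal(ours, sk)

    def test_mask_discards_crossing_pairs(self):
        img = np.array([[0, 1, 2]])
        mask = np.array([[True, False, True]])
        P = glcm(img, GlcmSpec(levels=3, normalized=False), mask)
        assert P.sum() == 0  # both horizontal pairs touch the masked pixel


class TestGlcmStats:
    def test_point_mass(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        out = glcm_stats(P)
        assert out == {
            "homogeneity": 1.0, "variance": 0.0, "dissimilarity": 0.0,
            "asm": 1.0, "entropy": 0.0,
        }

    def test_two_cell_hand_values(self):
        P = np.zeros((3, 3))
        P[0, 1] = P[1, 0] = 0.5
        out = glcm_stats(P)
        assert out["dissimilarity"] == pytest.approx(1.0)
        assert out["asm"] == pytest.approx(0.5)
        assert out["entropy"] == pytest.approx(np.log(2))

    def test_unnormalised_rejected(self):
        with pytest.raises(ValueError):
            glcm_stats(np.ones((2, 2)))

    def test_bruteforce_agreement_on_random_matrices(self, rng):
        """Vectorised stats equal direct summation over all cells."""
        for _ in range(30):
            P = rng.random((8, 8))
            P /= P.sum()
            out = glcm_stats(P)
            hom = dis = asm = ent = 0.0
            mu = sum(i * P[i, j] for i in range(8) for j in range(8))
            var = 0.0
            for i in range(8):
                for j in range(8):
                    hom += P[i, j] / (1 + (i - j) ** 2)
                    dis += P[i, j] * abs(i - j)
                    asm += P[i, j] ** 2
                    if P[i, j] > 0:
                        ent -= P[i, j] * np.log(P[i, j])
                    var += P[i, j] * (i - mu) ** 2
            assert out["homogeneity"] == pytest.approx(hom, abs=1e-12)
            assert out["dissimilarity"] == pytest.approx(dis, abs=1e-12)
            assert out["asm"] == pytest.approx(asm, abs=1e-12)
            assert out["entropy"] == pytest.approx(ent, abs=1e-12)
            assert out["variance"] == pytest.approx(var, abs=1e-12)
            assert 0 < out["asm"] <= 1 and out["entropy"] >= 0


class TestGldv:
    def test_constant_image(self):
        out = gldv_stats(np.zeros((4, 4), dtype=int), levels=4)
        assert out == {"mean": 0.0, "entropy": 0.0, "asm": 1.0}

    def test_alternating_columns(self):
        out = gldv_stats(np.array([[0, 1], [0, 1]]), offsets=((0, 1),), levels=2)
        assert out["mean"] == pytest.approx(1.0)

    def test_equals_antidiagonal_marginal_of_glcm(self, rng):
        """GLDV is the |i-j| marginal of the symmetric GLCM."""
        for _ in range(10):
            img = rng.integers(0, 6, size=(9, 9))
            v = gldv(img, ((0, 1),), 6)
            P = glcm(img, GlcmSpec(levels=6, offsets=((0, 1),)))
            marginal = np.zeros(6)
            for i in range(6):
                for j in range(6):
                    marginal[abs(i - j)] += P[i, j]
            assert np.allclose(v, marginal, atol=1e-12)


class TestIndexFeatures:
    def test_zero_difference_indices(self):
        scene = flat_scene([0.2, 0.3, 0.3, 0.3])  # NIR == red, green == NIR
        out = index_features(scene, 1)
        assert out["ndvi_mean"] == pytest.approx(0.0)
        assert out["water_mean"] == pytest.approx(0.0)

    def test_arvi_hand_value(self):
        scene = flat_scene([0.05, 0.08, 0.1, 0.4])
        out = index_features(scene, 1)
        assert out["arvi_mean"] == pytest.approx((0.4 - 0.15) / (0.4 + 0.15), abs=1e-6)

    def test_missing_band_rejected(self):
        scene = flat_scene([0.1] * 4)
        del scene.bands["nir"]
        with pytest.raises(KeyError):
            index_features(scene, 1)


class TestQuantize:
    def test_spans_levels(self):
        g = quantize_gray(np.linspace(0, 1, 32), 16)
        assert g.min() == 0 and g.max() == 15

    def test_constant_maps_to_zero(self):
        assert np.all(quantize_gray(np.full(5, 0.3), 16) == 0)


class TestBuildTable:
    def test_default_manifest_is_85_columns(self, small_scene):
        table = build_feature_table(small_scene)
        assert len(table.feature_names) == 85
        assert len(set(table.feature_names)) == 85
        assert table.n_objects == small_scene.segment_ids.size
        assert table.labels is not None

    def test_all_features_finite(self, small_scene):
        table = build_feature_table(small_scene)
        assert np.all(np.isfinite(table.X))

    def test_deterministic(self, small_scene):
        a = build_feature_table(small_scene)
        b = build_feature_table(small_scene)
        assert a.df.equals(b.df)

    def test_segment_renumbering_permutes_rows(self):
        scene = generate_scene(SceneConfig(height=30, width=30, n_segments=8, seed=5))
        remap = {old: new for new, old in enumerate(np.random.default_rng(1).permutation(8) + 1, start=1)}
        segs2 = np.vectorize(remap.get)(scene.segments).astype(np.int32)
        labels2 = {remap[s]: l for s, l in scene.labels.items()}
        scene2 = RasterScene(bands=scene.bands, segments=segs2, labels=labels2)
        a = build_feature_table(scene).df.reset_index(drop=True)
        b = build_feature_table(scene2).df.reset_index(drop=True)
        key = a.columns[0]
        a_sorted = a.sort_values(list(a.columns[:3])).reset_index(drop=True)
        b_sorted = b.sort_values(list(b.columns[:3])).reset_index(drop=True)
        assert np.allclose(
            a_sorted.drop(columns="label").to_numpy(dtype=float),
            b_sorted.drop(columns="label").to_numpy(dtype=float),
        )

    def test_manifest_round_trip(self):
        m = default_manifest()
        m2 = FeatureManifest.from_json(m.to_json())
        assert m2.feature_names == m.feature_names
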