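import numpy as np
import pytest

from deshade import (
    Roi,
    SpectralCube,
    VegetationMask,
    cascade_classify,
    class_mean_spectrum,
    class_pixel_stats,
    classify_stage,
    fit_level_scheme,
    vegetation_mask,
)
from deshade.simulate import (
    MATERIAL_SHADED,
    MATERIAL_SOIL,
    default_wavelengths,
    leaf_spectrum,
    soil_spectrum,
)


def green_cube(green_image: np.ndarray) -> SpectralCube:
    """Single-green-band helper: wavelengths resolve 550 within tolerance."""
    wl = np.array([548.9, 670.1, 800.8])
    data = np.stack([green_image, green_image * 0 + 0.1, green_image * 0 + 0.4], axis=-1)
    return SpectralCube(data, wl)


class TestLevelScheme:
    def test_forced_binning_one_label_per_value(self):
        values = np.arange(10, dtype=float)
        scheme = fit_level_scheme(values, 10, "equal_width")
        np.testing.assert_array_equal(scheme.assign(values), np.arange(10))

    def test_max_value_gets_last_closed_bin(self):
        scheme = fit_level_scheme(np.linspace(0, 1, 101), 10)
        assert scheme.assign(np.array([1.0]))[0] == 9

    def test_quantile_mode_balances_counts(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 1, size=1000)
        scheme = fit_level_scheme(values, 10, "quantile")
        counts = np.bincount(scheme.assign(values), minlength=10)
        assert counts.min() >= 100 - 1 and counts.max() <= 100 + 1

    def test_constant_input_equal_width_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_level_scheme(np.full(20, 0.3), 10, "equal_width")

    def test_assign_matches_brute_force_edge_search(self):
        """Level assignment equals an exhaustive scan over the edge vector."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            values = rng.uniform(0, 1, size=300)
            n = int(rng.integers(2, 12))
            scheme = fit_level_scheme(values, n)
            labels = scheme.assign(values)
            edges = np.asarray(scheme.edges)
            for v, lab in zip(values, labels):
                # oracle: first level whose half-open interval holds v
                expect = n - 1
                for i in range(n):
                    if edges[i] <= v < edges[i + 1]:
                        expect = i
                        break
                assert lab == expect
                assert edges[lab] <= v <= edges[lab + 1]


class TestClassifyStage:
    def test_two_valued_image_populates_extreme_levels(self):
        green = np.where(np.arange(64).reshape(8, 8) % 2 == 0, 0.05, 0.45)
        cube = green_cube(green)
        mask = VegetationMask(np.ones((8, 8), dtype=bool))
        pcm = classify_stage(cube, mask)
        assert set(np.unique(pcm.labels)) == {0, 9}

    def test_relabelling_with_stored_scheme_is_bit_exact(self):
        rng = np.random.default_rng(9)
        cube = green_cube(rng.uniform(0.05, 0.5, size=(12, 12)))
        mask = VegetationMask(rng.uniform(size=(12, 12)) > 0.3)
        pcm = classify_stage(cube, mask)
        again = classify_stage(cube, mask, scheme=pcm.scheme)
        np.testing.assert_array_equal(pcm.labels, again.labels)

    def test_unmasked_pixels_get_minus_one(self):
        rng = np.random.default_rng(10)
        cube = green_cube(rng.uniform(0.05, 0.5, size=(10, 10)))
        keep = rng.uniform(size=(10, 10)) > 0.5
        pcm = classify_stage(cube, VegetationMask(keep))
        assert np.all(pcm.labels[~keep] == -1)
        assert np.all(pcm.labels[keep] >= 0)

    def test_empty_mask_rejected(self):
        cube = green_cube(np.full((4, 4), 0.3))
        with pytest.raises(ValueError, match="empty"):
            classify_stage(cube, VegetationMask(np.zeros((4, 4), dtype=bool)))


class TestCascade:
    @pytest.fixture
    def scene(self):
        rng = np.random.default_rng(12)
        green = rng.uniform(0.02, 0.6, size=(40, 40))
        return green_cube(green), VegetationMask(rng.uniform(size=(40, 40)) > 0.2)

    def test_keep_all_reproduces_stage1_scheme(self, scene):
        cube, mask = scene
        s1, s2 = cascade_classify(cube, mask, stage1_keep=range(10))
        assert s1.scheme.edges == s2.scheme.edges

    def test_stage2_scheme_spans_kept_pixels(self, scene):
        cube, mask = scene
        s1, s2 = cascade_classify(cube, mask)
        kept = s1.in_levels({4, 5})
        green = cube.band_image(550)
        assert s2.scheme.lo == pytest.approx(green[kept].min())
        assert s2.scheme.hi == pytest.approx(green[kept].max())
        assert set(np.unique(s2.labels[kept])) == set(range(10))

    def test_nesting_stage2_only_inside_keep1(self, scene):
        cube, mask = scene
        s1, s2 = cascade_classify(cube, mask)
        assert np.all(s1.labels[mask.mask] >= 0)
        outside_keep = ~s1.in_levels({4, 5})
        assert np.all(s2.labels[outside_keep] == -1)

    def test_empty_keep_selection_rejected(self, scene):
        cube, mask = scene
        with pytest.raises(ValueError, match="stage1_keep"):
            cascade_classify(cube, mask, stage1_keep=[])


class TestVegetationMask:
    def test_pure_endmember_scene_recovered_exactly(self):
        wl = default_wavelengths()
        leaf = leaf_spectrum(40.0, wl)
        soil = soil_spectrum(wl)
        truth = np.zeros((10, 10), dtype=bool)
        truth[2:8, 3:9] = True
        data = np.where(truth[:, :, None], leaf[None, None, :], soil[None, None, :])
        cube = SpectralCube(data, wl)
        mask = vegetation_mask(cube, k=2, seed=0)
        np.testing.assert_array_equal(mask.mask, truth)

    def test_identical_pixels_warn_and_mask_all(self):
        wl = np.array([450.0, 550.0, 670.0, 800.0])
        cube = SpectralCube(np.full((5, 5, 4), 0.2), wl)
        with pytest.warns(UserWarning, match="identical"):
            mask = vegetation_mask(cube, k=2, seed=0)
        assert mask.mask.all()

    def test_single_pixel_cube_rejected(self):
        wl = np.array([450.0, 550.0, 670.0, 800.0])
        cube = SpectralCube(np.full((1, 1, 4), 0.2), wl)
        with pytest.raises(ValueError, match="degenerate"):
            vegetation_mask(cube)

    def test_mask_covers_shaded_and_sunlit_leaves(self, default_scene, default_scene_mask):
        cfg, cube, truth = default_scene
        mask = default_scene_mask
        leaves = truth.material != MATERIAL_SOIL
        recall = (mask.mask & leaves).sum() / leaves.sum()
        assert recall > 0.95


class TestPixelStats:
    def test_printed_scene_composition(self):
        """65.75% / 34.25% split of a 1,936,498-pixel scene."""
        mask = np.zeros((2, 968249), dtype=bool)  # 1,936,498 pixels
        mask.reshape(-1)[:1273202] = True
        stats = class_pixel_stats(VegetationMask(mask))
        table = stats.set_index("label")
        assert table.loc["vegetation", "count"] == 1273202
        assert table.loc["total", "count"] == 1936498
        assert round(table.loc["vegetation", "percent"], 2) == 65.75
        assert round(table.loc["other", "percent"], 2) == 34.25

    def test_counts_sum_and_empty_label(self):
        labels = np.full((6, 6), -1, dtype=np.int32)
        labels[0, :3] = 0
        labels[1, :2] = 9
        scheme = fit_level_scheme(np.linspace(0, 1, 50), 10)
        from deshade import PixelClassMap

        stats = class_pixel_stats(PixelClassMap(labels, scheme))
        table = stats.set_index("label")
        assert table.loc["1-0", "count"] == 3
        assert table.loc["1-5", "count"] == 0
        assert table.loc["1-5", "percent"] == 0.0
        body = stats[stats["label"] != "total"]
        assert body["count"].sum() == 36
        assert body["percent"].sum() == pytest.approx(100.0)


class TestClassMeanSpectrum:
    def test_uniform_label_equals_plain_roi_mean(self):
        rng = np.random.default_rng(14)
        cube = green_cube(rng.uniform(0.1, 0.5, size=(20, 20)))
        mask = VegetationMask(np.ones((20, 20), dtype=bool))
        labels = np.zeros((20, 20), dtype=np.int32)
        scheme = fit_level_scheme(np.linspace(0, 1, 50), 10)
        from deshade import PixelClassMap

        pcm = PixelClassMap(labels, scheme)
        roi = Roi((10, 10), 5, 5)
        got = class_mean_spectrum(cube, pcm, roi, levels=0)
        expected = cube.reflectance[8:13, 8:13].mean(axis=(0, 1))
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_two_value_mixture_averages(self):
        wl = np.array([548.9, 670.0])
        data = np.empty((2, 2, 2))
        data[0, :, :] = 0.2
        data[1, :, :] = 0.4
        cube = SpectralCube(data, wl)
        labels = np.zeros((2, 2), dtype=np.int32)
        scheme = fit_level_scheme(np.linspace(0, 1, 50), 10)
        from deshade import PixelClassMap

        got = class_mean_spectrum(cube, PixelClassMap(labels, scheme), Roi((0, 0), 3, 3), 0)
        np.testing.assert_allclose(got, 0.3, atol=1e-12)

    def test_absent_label_yields_missing_marker(self):
        rng = np.random.default_rng(15)
        cube = green_cube(rng.uniform(0.1, 0.5, size=(10, 10)))
        labels = np.zeros((10, 10), dtype=np.int32)
        scheme = fit_level_scheme(np.linspace(0, 1, 50), 10)
        from deshade import PixelClassMap

        assert class_mean_spectrum(cube, PixelClassMap(labels, scheme), Roi((5, 5), 3, 3), 7) is None


class TestSceneContamination:
    def test_cascade_strips_soil_and_shadow(self, default_scene, default_scene_mask):
        """Soil and shadow shares among retained pixels fall stage by stage."""
        cfg, cube, truth = default_scene
        mask = default_scene_mask
        s1, s2 = cascade_classify(cube, mask)

        def frac(sel, material):
            return (truth.material[sel] == material).mean()

        sel0 = mask.mask
        sel2 = s2.in_levels({3, 4, 5})
        assert frac(sel2, MATERIAL_SOIL) <= frac(sel0, MATERIAL_SOIL)
        assert frac(sel2, MATERIAL_SHADED) < frac(sel0, MATERIAL_SHADED)
        # shadows concentrate in the dark stage-1 levels, soil in bright ones
        green = cube.band_image(550)
        shade_levels = s1.labels[(truth.material == MATERIAL_SHADED) & sel0]
        sun_levels = s1.labels[(truth.material == 1) & sel0]
        assert np.median(shade_levels) < np.median(sun_levels)
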