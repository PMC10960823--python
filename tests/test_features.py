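import numpy as np
import pytest

import wetmap as wm
from wetmap.features import (FeatureConfig, FeatureStack, PERCENTILES,
                             PERCENTILE_VARIABLES, TEXTURE_STATS,
                             percentile_composite, quality_mosaic)
from wetmap.indices import BANDS, compute_indices
from wetmap.simulate import SceneCube


def make_cube(refl, valid=None, dates=None):
    """(n_dates, 6, H, W) cube helper."""
    refl = np.asarray(refl, dtype=np.float32)
    nd = refl.shape[0]
    if valid is None:
        valid = np.ones((nd,) + refl.shape[2:], dtype=bool)
    if dates is None:
        dates = np.linspace(10, 350, nd)
    return SceneCube(year=2000, dates=np.asarray(dates, float),
                     reflectance=refl, valid=np.asarray(valid))


class TestQualityMosaic:
    def test_single_observation_is_identity(self):
        rng = np.random.default_rng(0)
        cube = make_cube(rng.random((1, 6, 4, 4)))
        names, data, nodata = quality_mosaic(cube, "mndwi")
        assert not nodata.any()
        np.testing.assert_allclose(data[1:7], cube.reflectance[0], rtol=1e-6)

    def test_argmax_selects_highest_index_observation(self):
        # obs0 land-like (mNDWI<0), obs1 water-like (mNDWI>0)
        land = np.array([0.1, 0.1, 0.1, 0.4, 0.2, 0.1])
        water = np.array([0.06, 0.08, 0.05, 0.03, 0.02, 0.01])
        refl = np.stack([np.tile(land[:, None, None], (1, 3, 3)),
                         np.tile(water[:, None, None], (1, 3, 3))])
        names, data, _ = quality_mosaic(make_cube(refl), "mndwi")
        np.testing.assert_allclose(data[1:7], refl[1], rtol=1e-6)

    def test_exact_tie_takes_earliest_date(self):
        obs = np.tile(np.array([0.1, 0.2, 0.1, 0.1, 0.3, 0.2])[:, None, None],
                      (1, 2, 2))
        refl = np.stack([obs, obs * 1.0])
        refl[1, 4] = 0.9  # same mNDWI (green/NIR unchanged), different SWIR1
        names, data, _ = quality_mosaic(make_cube(refl), "mndwi")
        assert data[names.index("hightide_swir1")][0, 0] == pytest.approx(0.3, rel=1e-6)

    def test_recomputing_index_from_composited_bands_reproduces_max(self, scene):
        names, data, nodata = quality_mosaic(scene, "ltidei")
        recomputed = wm.ltidei(data[1], data[2], data[3], data[4], data[6])
        ok = ~nodata
        np.testing.assert_allclose(recomputed[ok], data[0][ok], atol=1e-6)

    def test_all_masked_pixel_flagged_nodata(self):
        refl = np.random.default_rng(1).random((3, 6, 2, 2)).astype(np.float32)
        valid = np.ones((3, 2, 2), bool)
        valid[:, 0, 0] = False
        names, data, nodata = quality_mosaic(make_cube(refl, valid), "ltidei")
        assert nodata[0, 0] and not nodata[1, 1]
        assert np.isnan(data[:, 0, 0]).all()


class TestPercentileComposite:
    def test_constant_series_every_percentile_equal(self):
        refl = np.full((6, 6, 2, 2), 0.3, dtype=np.float32)
        names, data = percentile_composite(make_cube(refl))
        for p in PERCENTILES:
            np.testing.assert_allclose(data[names.index(f"blue_p{p}")], 0.3,
                                       rtol=1e-6)

    def test_linear_interpolation_of_order_statistics(self):
        # series 1..10 in the blue band of one pixel
        refl = np.zeros((10, 6, 1, 1), dtype=np.float32)
        refl[:, 0, 0, 0] = np.arange(1, 11) / 10.0
        names, data = percentile_composite(make_cube(refl))
        assert data[names.index("blue_p50")][0, 0] == pytest.approx(0.55)
        assert data[names.index("blue_p10")][0, 0] == pytest.approx(0.19)

    def test_monotone_in_percentile_rank(self, scene):
        names, data = percentile_composite(scene)
        for var in PERCENTILE_VARIABLES:
            stackv = np.stack([data[names.index(f"{var}_p{p}")]
                               for p in PERCENTILES])
            d = np.diff(stackv, axis=0)
            assert np.nanmin(d) >= -1e-6

    def test_single_valid_observation_fills_all_percentiles(self):
        refl = np.random.default_rng(2).random((4, 6, 2, 2)).astype(np.float32)
        valid = np.zeros((4, 2, 2), bool)
        valid[2] = True
        names, data = percentile_composite(make_cube(refl, valid))
        for p in PERCENTILES:
            np.testing.assert_allclose(data[names.index(f"red_p{p}")],
                                       refl[2, 2], rtol=1e-6)

    def test_adding_masked_observations_changes_nothing(self, scene):
        names, base = percentile_composite(scene)
        refl = np.concatenate([scene.reflectance,
                               np.full_like(scene.reflectance[:2], 0.77)])
        valid = np.concatenate([scene.valid,
                                np.zeros_like(scene.valid[:2])])
        padded = SceneCube(scene.year, np.concatenate([scene.dates, [360, 361]]),
                           refl, valid)
        names2, data2 = percentile_composite(padded)
        np.testing.assert_array_equal(base, data2)
        # same invariance for the quality mosaics
        _, qm1, _ = quality_mosaic(scene, "ltidei")
        _, qm2, _ = quality_mosaic(padded, "ltidei")
        np.testing.assert_array_equal(qm1, qm2)


class TestTerrain:
    def test_constant_dem_flat(self):
        slope, aspect, flat = wm.terrain_features(np.full((8, 8), 5.0), 30.0)
        assert np.all(slope == 0) and np.all(aspect == 0) and flat.all()

    def test_east_rising_plane(self):
        dem = np.tile(np.arange(16, dtype=float), (16, 1))  # +1 m per pixel
        slope, aspect, flat = wm.terrain_features(dem, 30.0)
        assert slope[8, 8] == pytest.approx(np.degrees(np.arctan(1 / 30)), rel=1e-6)
        assert aspect[8, 8] == pytest.approx(270.0)

    def test_ranges(self, dem):
        slope, aspect, _ = wm.terrain_features(dem, 30.0)
        assert slope.min() >= 0 and slope.max() < 90
        assert aspect.min() >= 0 and aspect.max() < 360


class TestFeatureStack:
    def test_94_bands_decomposed_16_50_25_3(self, stack):
        assert len(stack.names) == 94
        tide = [n for n in stack.names
                if n.startswith(("lowtide_", "hightide_"))]
        tex = [n for n in stack.names if n.endswith(TEXTURE_STATS)]
        terrain = [n for n in stack.names
                   if n in ("elevation", "slope", "aspect")]
        pct = [n for n in stack.names
               if n not in tide + tex + terrain]
        assert (len(tide), len(pct), len(tex), len(terrain)) == (16, 50, 25, 3)

    def test_band_names_unique(self, stack):
        assert len(set(stack.names)) == 94

    def test_shape_mismatch_names_offender(self, scene):
        with pytest.raises(ValueError, match="dem"):
            wm.build_feature_stack(scene, np.zeros((3, 3)))

    def test_mismatched_names_rejected(self):
        with pytest.raises(ValueError):
            FeatureStack(names=("a", "b"), data=np.zeros((3, 2, 2)))
        with pytest.raises(ValueError):
            FeatureStack(names=("a", "a"), data=np.zeros((2, 2, 2)))
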