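import numpy as np
import pandas as pd
import pytest

import wetmap as wm
from wetmap.tiles import (TileGrid, TileModelSpec, assign_tiles, classify_year,
                          pool_neighbors, train_tile_model)


def sample_frame(xs, ys, codes=None):
    return pd.DataFrame({"x": xs, "y": ys,
                         "class_code": codes or [0] * len(xs)})


class TestAssignTiles:
    def test_interior_point_lower_left_anchor(self):
        t = assign_tiles(sample_frame([2.5], [2.5]))
        assert list(t) == [(0.0, 0.0)]
        assert TileGrid().tile_id(0, 0) == "E000N00"

    def test_edge_point_half_open_interval(self):
        t = assign_tiles(sample_frame([5.0], [0.0]))
        assert list(t) == [(5.0, 0.0)]

    def test_empty_pool_empty_partition(self):
        assert assign_tiles(sample_frame([], [])) == {}

    def test_partition_no_sample_lost_or_duplicated(self):
        rng = np.random.default_rng(0)
        df = sample_frame(rng.uniform(-180, 180, 500), rng.uniform(-90, 90, 500))
        tiles = assign_tiles(df)
        counts = sum(len(v) for v in tiles.values())
        assert counts == len(df)
        all_idx = np.concatenate([v.index for v in tiles.values()])
        assert sorted(all_idx) == sorted(df.index)

    def test_out_of_extent_listed(self):
        with pytest.raises(ValueError, match="0"):
            assign_tiles(sample_frame([200.0], [0.0]))


class TestPoolNeighbors:
    def _tiled(self, per_tile, nx=3, ny=3):
        rng = np.random.default_rng(1)
        tiles = {}
        for i in range(nx):
            for j in range(ny):
                x0, y0 = i * 5.0, j * 5.0
                tiles[(x0, y0)] = sample_frame(
                    rng.uniform(x0, x0 + 5, per_tile),
                    rng.uniform(y0, y0 + 5, per_tile),
                    codes=list(rng.choice([0, 180, 187], per_tile)))
        return tiles

    def test_interior_tile_pools_3x3_block(self):
        tiles = self._tiled(100)
        pooled = pool_neighbors((5.0, 5.0), tiles)
        assert len(pooled) == 900

    def test_corner_tile_pools_available_neighbors(self):
        tiles = self._tiled(100)
        pooled = pool_neighbors((0.0, 0.0), tiles)
        assert len(pooled) == 400

    def test_empty_block_is_untrainable(self):
        with pytest.raises(ValueError, match="untrainable"):
            pool_neighbors((50.0, 50.0), self._tiled(10))

    def test_cap_preserves_class_proportions(self):
        rng = np.random.default_rng(2)
        df = sample_frame(rng.uniform(0, 5, 30000), rng.uniform(0, 5, 30000),
                          codes=list(rng.choice([0, 180, 187], 30000,
                                                p=[0.5, 0.3, 0.2])))
        spec = TileModelSpec(sample_cap=24000, min_per_class=2000, seed=0)
        pooled = pool_neighbors((0.0, 0.0), {(0.0, 0.0): df}, spec)
        assert len(pooled) == 24000
        before = df["class_code"].value_counts(normalize=True)
        after = pooled["class_code"].value_counts(normalize=True)
        for code in before.index:
            assert after[code] == pytest.approx(before[code], abs=0.01)

    def test_pooling_independent_of_sample_order(self):
        tiles = self._tiled(50)
        spec = TileModelSpec(sample_cap=300, min_per_class=10, seed=5)
        a = pool_neighbors((5.0, 5.0), tiles, spec)
        shuffled = {k: v.sample(frac=1, random_state=9) for k, v in tiles.items()}
        b = pool_neighbors((5.0, 5.0), shuffled, spec)
        key = lambda df: sorted(zip(df["x"], df["y"], df["class_code"]))
        assert key(a) == key(b)


def separable_training(n=300, seed=0):
    rng = np.random.default_rng(seed)
    names = [f"f{i}" for i in range(4)]
    a = pd.DataFrame(rng.normal(0, 0.1, (n, 4)), columns=names)
    a["class_code"] = 180
    b = pd.DataFrame(rng.normal(2, 0.1, (n, 4)), columns=names)
    b["class_code"] = 0
    return pd.concat([a, b], ignore_index=True), names


class TestTileModel:
    def test_separable_classes_high_training_accuracy(self):
        df, names = separable_training()
        model = train_tile_model(df, names, TileModelSpec(seed=1))
        pred = model.predict(df[names].to_numpy())
        assert (pred == df["class_code"].to_numpy()).mean() >= 0.99

    def test_seeded_retrain_identical_predictions(self):
        df, names = separable_training()
        probe = np.random.default_rng(3).normal(1, 1, (50, 4))
        p1 = train_tile_model(df, names, TileModelSpec(seed=2)).predict(probe)
        p2 = train_tile_model(df, names, TileModelSpec(seed=2)).predict(probe)
        assert np.array_equal(p1, p2)

    def test_only_trained_codes_emitted(self):
        df, names = separable_training()
        model = train_tile_model(df, names)
        pred = model.predict(np.random.default_rng(4).normal(1, 3, (200, 4)))
        assert set(pred.tolist()) <= {0, 180}

    def test_single_class_rejected(self):
        df, names = separable_training()
        with pytest.raises(ValueError):
            train_tile_model(df[df["class_code"] == 0], names)


class TestClassifyYear:
    def test_schema_mismatch_names_bands(self, stack):
        df, names = separable_training()
        model = train_tile_model(df, names)
        with pytest.raises(ValueError, match="f0"):
            classify_year(model, stack)

    def test_nodata_propagates_and_codes_are_legal(self, scene, dem, truth):
        stack = wm.build_feature_stack(scene, dem)
        pts = wm.sample_points({2000: truth}, 30, seed=0)
        tbl = stack.data[:, pts["row"], pts["col"]].T
        train = pd.DataFrame(tbl, columns=stack.names)
        train["class_code"] = pts["class_code"]
        train = train[np.isfinite(train[list(stack.names)]).all(axis=1)]
        model = train_tile_model(train, stack.names, TileModelSpec(seed=0))
        pred = classify_year(model, stack)
        nod = ~np.isfinite(stack.data).all(axis=0)
        assert (pred[nod] == -1).all()
        assert set(np.unique(pred[~nod]).tolist()) <= wm.VALID_CODES


def test_parameter_recovery_on_separable_scene(pipeline_result):
    """With well-separated class spectra the per-year map matches truth."""
    for year, oa in pipeline_result["metrics"]["per_year_oa"].items():
        assert oa >= 0.90
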