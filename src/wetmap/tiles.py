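"""Local-adaptive classification on a 5-degree tile grid.

Instead of a single global model, the globe is partitioned into 5x5-degree
geographic tiles and an independent random forest is trained per tile.  The
training set of a tile pools the samples of the tile and its eight
neighbors (a 3x3 block) — this smooths class boundaries across tile seams
and rescues sparse classes — then is capped by stratified down-sampling.
Each sample belongs to exactly one tile: tile intervals are half-open
``[min, min + size)`` in both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .codes import VALID_CODES
from .features import FeatureStack


@dataclass(frozen=True)
class TileGrid:
    """Axis-aligned geographic tile grid (WGS84 degrees)."""

    tile_size: float = 5.0

    def tile_of(self, lon, lat):
        """Anchor (lon_min, lat_min) of the tile containing a point."""
        s = self.tile_size
        return (np.floor(np.asarray(lon) / s) * s,
                np.floor(np.asarray(lat) / s) * s)

    def tile_id(self, lon_min: float, lat_min: float) -> str:
        """E/W-N/S name of a tile from its lower-left anchor."""
        ew = "E" if lon_min >= 0 else "W"
        ns = "N" if lat_min >= 0 else "S"
        return f"{ew}{abs(int(round(lon_min))):03d}{ns}{abs(int(round(lat_min))):02d}"

    def neighbors(self, lon_min: float, lat_min: float):
        """Anchors of the 3x3 block centred on a tile (clipped at poles,
        wrapped in longitude)."""
        out = []
        for dy in (-1, 0, 1):
            lat = lat_min + dy * self.tile_size
            if lat < -90 or lat + self.tile_size > 90:
                continue
            for dx in (-1, 0, 1):
                lon = lon_min + dx * self.tile_size
                if lon >= 180:
                    lon -= 360
                elif lon < -180:
                    lon += 360
                out.append((lon, lat))
        return out


@dataclass(frozen=True)
class TileModelSpec:
    """Per-tile model parameters.

    n_trees=100 random-forest trees with library defaults otherwise; the
    pooled 3x3 training set is capped at *sample_cap* samples with a
    per-class floor of *min_per_class* (where available).
    """

    n_trees: int = 100
    sample_cap: int = 24000
    min_per_class: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.sample_cap <= 0 or self.min_per_class <= 0:
            raise ValueError("caps must be positive")


def assign_tiles(samples: pd.DataFrame, grid: TileGrid | None = None):
    """Partition samples by tile anchor using their x/y (lon/lat) columns.

    Returns ``dict[(lon_min, lat_min)] -> DataFrame``.  Every sample lands
    in exactly one tile (half-open intervals); out-of-range coordinates
    raise with the offending row indices.
    """
    grid = grid or TileGrid()
    if len(samples) == 0:
        return {}
    lon = samples["x"].to_numpy(dtype=float)
    lat = samples["y"].to_numpy(dtype=float)
    bad = samples.index[(lon < -180) | (lon >= 180) | (lat < -90) | (lat > 90)]
    if len(bad):
        raise ValueError(f"samples outside grid extent: {list(bad)}")
    ax, ay = grid.tile_of(lon, lat)
    out = {}
    keys = pd.DataFrame({"ax": ax, "ay": ay}, index=samples.index)
    for (x0, y0), idx in keys.groupby(["ax", "ay"]).groups.items():
        out[(float(x0), float(y0))] = samples.loc[idx]
    return out


def _largest_remainder(quota, total):
    take = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - take))[: total - take.sum()]:
        take[i] += 1
    return take


def _stratified_cap(pooled: pd.DataFrame, spec: TileModelSpec) -> pd.DataFrame:
    """Down-sample to the cap, stratified by class.

    Allocation is proportional to class availability (largest-remainder
    rounding, preserving class proportions to +-1 sample) except that any
    class whose proportional share would fall below min(min_per_class,
    available) is pinned at that floor first.  Sampling within class is
    seeded and independent of row order.
    """
    if len(pooled) <= spec.sample_cap:
        return pooled
    counts = pooled["class_code"].value_counts().sort_index()
    codes = list(counts.index)
    floor = {c: min(int(counts[c]), spec.min_per_class) for c in codes}
    take = {}
    budget = spec.sample_cap
    unresolved = list(codes)
    if sum(floor.values()) >= budget:
        q = np.array([floor[c] for c in codes], float)
        alloc = _largest_remainder(budget * q / q.sum(), budget)
        take = dict(zip(codes, alloc))
        unresolved = []
    while unresolved:
        avail = np.array([counts[c] for c in unresolved], float)
        share = budget * avail / avail.sum()
        binding = [c for c, s in zip(unresolved, share) if s < floor[c]]
        if not binding:
            alloc = _largest_remainder(share, budget)
            take.update(dict(zip(unresolved, alloc)))
            break
        for c in binding:
            take[c] = floor[c]
            budget -= floor[c]
            unresolved.remove(c)

    # stable ordering so the seeded draw ignores incoming row order
    sort_cols = [c for c in ("class_code", "x", "y", "row", "col")
                 if c in pooled.columns]
    stable = pooled.sort_values(sort_cols, kind="mergesort")
    rng = np.random.default_rng(spec.seed)
    parts = []
    for code in codes:
        grp = stable[stable["class_code"] == code]
        n = int(min(take.get(code, 0), len(grp)))
        pick = rng.choice(len(grp), size=n, replace=False)
        parts.append(grp.iloc[np.sort(pick)])
    return pd.concat(parts)


def pool_neighbors(tile_anchor, tiled_samples: dict,
                   spec: TileModelSpec | None = None,
                   grid: TileGrid | None = None) -> pd.DataFrame:
    """Union of samples from the 3x3 block centred on *tile_anchor*,
    stratified-down-sampled to the cap.  Raises on an empty block."""
    spec = spec or TileModelSpec()
    grid = grid or TileGrid()
    parts = [tiled_samples[a] for a in grid.neighbors(*tile_anchor)
             if a in tiled_samples]
    if not parts or sum(len(p) for p in parts) == 0:
        raise ValueError(f"untrainable tile {tile_anchor}: no samples in 3x3 block")
    pooled = pd.concat(parts)
    return _stratified_cap(pooled, spec)


@dataclass
class TileModel:
    """A trained per-tile classifier with its feature schema."""

    feature_names: tuple
    classes: tuple
    spec: TileModelSpec
    estimator: RandomForestClassifier = field(repr=False, default=None)

    def predict(self, table: np.ndarray) -> np.ndarray:
        return self.estimator.predict(table).astype(np.int64)


def train_tile_model(training: pd.DataFrame, feature_names,
                     spec: TileModelSpec | None = None) -> TileModel:
    """Train a seeded random forest on a pooled tile training set.

    *training* carries ``class_code`` plus one column per feature name.
    Requires at least two classes.
    """
    spec = spec or TileModelSpec()
    feature_names = tuple(feature_names)
    y = training["class_code"].to_numpy(dtype=np.int64)
    classes = tuple(sorted(set(int(v) for v in y)))
    if len(classes) < 2:
        raise ValueError("training set must contain at least two classes")
    X = training[list(feature_names)].to_numpy(dtype=np.float64)
    est = RandomForestClassifier(n_estimators=spec.n_trees,
                                 random_state=spec.seed, n_jobs=1)
    est.fit(X, y)
    return TileModel(feature_names=feature_names, classes=classes,
                     spec=spec, estimator=est)


def classify_year(model: TileModel, stack: FeatureStack) -> np.ndarray:
    """Predict a label grid from a feature stack.

    The stack's band names must match the training schema exactly (the
    error names any missing or extra bands).  Pixels with any non-finite
    feature are nodata and propagate as -1 in the returned int grid.
    """
    missing = [n for n in model.feature_names if n not in stack.names]
    extra = [n for n in stack.names if n not in model.feature_names]
    if missing or extra:
        raise ValueError(
            f"feature schema mismatch: missing {missing}, extra {extra}")
    order = [stack.names.index(n) for n in model.feature_names]
    data = stack.data[order]
    h, w = data.shape[1:]
    table = data.reshape(len(order), -1).T
    ok = np.isfinite(table).all(axis=1)
    out = np.full(h * w, -1, dtype=np.int64)
    if ok.any():
        out[ok] = model.predict(table[ok])
    return out.reshape(h, w)
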