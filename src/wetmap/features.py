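"""Water-level, phenological, texture and terrain feature compositing.

A year of multi-date six-band observations is condensed into a fixed
94-variable per-pixel stack:

* **16 water-level features** — two quality mosaics.  For every pixel the
  observation maximising LTideI (lowest water level / low tide) contributes
  its index value, its six reflectance bands and its mNDWI; the observation
  maximising mNDWI (highest water level) contributes analogously.
* **50 phenological features** — the 10th/30th/50th/70th/90th percentiles of
  the six bands and of NDVI, mNDWI, LSWI and LTideI over the year's valid
  observations (extremes are deliberately not used: they concentrate
  residual cloud/snow contamination).
* **25 texture features** — grey-level co-occurrence statistics (entropy,
  contrast, variance, homogeneity, correlation) of the five NIR percentile
  bands.
* **3 topographical features** — elevation, slope, aspect.

Masked observations never influence any composite; pixels with no valid
observation at all propagate as NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .indices import BANDS, IndexConfig, compute_indices
from .simulate import SceneCube

PERCENTILES = (10, 30, 50, 70, 90)
PERCENTILE_VARIABLES = BANDS + ("ndvi", "mndwi", "lswi", "ltidei")
TEXTURE_STATS = ("entropy", "contrast", "variance", "homogeneity", "correlation")

#: Four unit offsets at 0, 45, 90 and 135 degrees.
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class GLCMConfig:
    """Grey-level co-occurrence parameters (conventional defaults)."""

    levels: int = 32
    window: int = 5
    offsets: tuple = DEFAULT_OFFSETS


@dataclass(frozen=True)
class FeatureConfig:
    index: IndexConfig = field(default_factory=IndexConfig)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    percentiles: tuple = PERCENTILES
    pixel_size_m: float = 30.0


@dataclass
class FeatureStack:
    """Named per-pixel feature array of shape (n_features, H, W)."""

    names: tuple
    data: np.ndarray

    def __post_init__(self):
        if len(self.names) != self.data.shape[0]:
            raise ValueError("names/data length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    def select(self, prefix: str) -> list[str]:
        return [n for n in self.names if n.startswith(prefix)]

    def as_table(self, valid_mask=None):
        """Flatten to (n_pixels, n_features); optionally restrict to a mask."""
        flat = self.data.reshape(self.data.shape[0], -1).T
        if valid_mask is not None:
            flat = flat[np.asarray(valid_mask).ravel()]
        return flat


def _index_series(cube: SceneCube, config: IndexConfig):
    """All four index series of shape (n_dates, H, W)."""
    return compute_indices(np.moveaxis(cube.reflectance, 1, 0), config)


def quality_mosaic(cube: SceneCube, quality_index: str = "ltidei",
                   config: FeatureConfig | None = None):
    """Max-composite: per pixel, the full observation with the largest index.

    Returns ``(names, data, nodata)`` where *data* is an 8-band array —
    the maximised index, the six reflectance bands of the selected
    observation, and the companion index (mNDWI for an LTideI mosaic and
    vice versa) evaluated at that same observation.  Ties in the quality
    index select the earliest acquisition.  Pixels with zero valid
    observations are NaN and flagged in *nodata*.
    """
    if quality_index not in ("ltidei", "mndwi"):
        raise ValueError(f"unsupported quality index {quality_index!r}")
    config = config or FeatureConfig()
    idx = _index_series(cube, config.index)
    q = np.where(cube.valid, idx[quality_index], -np.inf)
    nodata = ~cube.valid.any(axis=0)
    # np.argmax returns the first occurrence of the max; dates ascend, so
    # exact ties resolve to the earliest acquisition.
    best = np.argmax(q, axis=0)
    take = best[None, None]  # (1, 1, H, W)
    bands = np.take_along_axis(cube.reflectance, take, axis=0)[0]
    companion = "mndwi" if quality_index == "ltidei" else "ltidei"
    comp = np.take_along_axis(idx[companion], best[None], axis=0)[0]
    qmax = np.take_along_axis(q, best[None], axis=0)[0]

    prefix = "lowtide" if quality_index == "ltidei" else "hightide"
    names = ([f"{prefix}_{quality_index}"]
             + [f"{prefix}_{b}" for b in BANDS]
             + [f"{prefix}_{companion}"])
    data = np.concatenate([qmax[None], bands, comp[None]]).astype(np.float64)
    data[:, nodata] = np.nan
    return tuple(names), data, nodata


def percentile_composite(cube: SceneCube, config: FeatureConfig | None = None,
                         variables=PERCENTILE_VARIABLES):
    """Percentile phenology composite over the year's valid observations.

    Percentiles use linear interpolation between order statistics.  With a
    single valid observation every percentile equals it; with none the
    pixel is NaN.  Returns ``(names, data)`` with variable-major ordering
    (all percentiles of a variable are adjacent), shape (50, H, W).
    """
    config = config or FeatureConfig()
    idx = _index_series(cube, config.index)
    nd, _, h, w = cube.reflectance.shape
    series = {b: cube.reflectance[:, i].astype(np.float64)
              for i, b in enumerate(BANDS)}
    series.update(idx)

    names, planes = [], []
    invalid = ~cube.valid
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        for var in variables:
            arr = series[var].copy()
            arr[invalid] = np.nan
            pct = np.nanpercentile(arr, config.percentiles, axis=0)
            for k, p in enumerate(config.percentiles):
                names.append(f"{var}_p{p}")
                planes.append(pct[k])
    return tuple(names), np.stack(planes)


def _quantize(band: np.ndarray, levels: int):
    """Quantize to integer grey levels over the finite observed range.

    Returns (levels array, valid mask); constant images map to level 0.
    """
    band = np.asarray(band, dtype=np.float64)
    valid = np.isfinite(band)
    q = np.zeros(band.shape, dtype=np.int64)
    if valid.any():
        lo, hi = band[valid].min(), band[valid].max()
        if hi > lo:
            q[valid] = np.minimum(
                ((band[valid] - lo) / (hi - lo) * levels).astype(np.int64),
                levels - 1)
    return q, valid


def glcm_textures(band: np.ndarray, config: GLCMConfig | None = None):
    """Windowed grey-level co-occurrence texture statistics.

    For every pixel, pairs ``(s, s + o)`` whose first element lies in the
    surrounding ``window``x``window`` block are tabulated symmetrically over
    all configured offsets into one normalised co-occurrence matrix
    ``P(i, j)``, from which

    * entropy     = -sum P ln P
    * contrast    = sum (i - j)^2 P
    * variance    = sum (i - mu)^2 P
    * homogeneity = sum P / (1 + (i - j)^2)
    * correlation = sum (i - mu)(j - mu) P / sigma^2  (0 if sigma = 0)

    are derived.  Returns a dict of float64 grids; pixels whose window
    contains no valid pair are NaN.
    """
    config = config or GLCMConfig()
    h, w = np.asarray(band).shape
    if config.window > min(h, w):
        raise ValueError(f"window {config.window} exceeds grid {h}x{w}")
    L = config.levels
    q, valid = _quantize(band, L)

    counts = np.zeros((L * L, h, w), dtype=np.float32)
    flat = counts.reshape(L * L, h * w)
    rr, cc = np.mgrid[0:h, 0:w]
    for (dr, dc) in config.offsets:
        r2, c2 = rr + dr, cc + dc
        ok = (valid & (r2 >= 0) & (r2 < h) & (c2 >= 0) & (c2 < w))
        ok &= valid[np.clip(r2, 0, h - 1), np.clip(c2, 0, w - 1)]
        a = q[rr[ok], cc[ok]]
        b = q[r2[ok], c2[ok]]
        pix = rr[ok] * w + cc[ok]
        np.add.at(flat, (a * L + b, pix), 1.0)
        np.add.at(flat, (b * L + a, pix), 1.0)

    size = (1, config.window, config.window)
    S = ndimage.uniform_filter(counts, size=size, mode="constant", cval=0.0)
    S *= config.window ** 2
    np.maximum(S, 0.0, out=S)  # filter round-off
    T = S.sum(axis=0)
    empty = T <= 0
    Tsafe = np.where(empty, 1.0, T)

    i_idx, j_idx = np.divmod(np.arange(L * L), L)
    diff2 = (i_idx - j_idx).astype(np.float64) ** 2
    contrast = np.einsum("k,khw->hw", diff2, S) / Tsafe
    homog = np.einsum("k,khw->hw", 1.0 / (1.0 + diff2), S) / Tsafe
    with np.errstate(divide="ignore", invalid="ignore"):
        slogs = np.where(S > 0, S * np.log(S), 0.0).sum(axis=0)
    entropy = np.log(Tsafe) - slogs / Tsafe
    np.maximum(entropy, 0.0, out=entropy)
    mu = np.einsum("k,khw->hw", i_idx.astype(np.float64), S) / Tsafe
    ex2 = np.einsum("k,khw->hw", i_idx.astype(np.float64) ** 2, S) / Tsafe
    var = np.maximum(ex2 - mu ** 2, 0.0)
    exy = np.einsum("k,khw->hw", (i_idx * j_idx).astype(np.float64), S) / Tsafe
    cov = exy - mu ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(var > 1e-12, cov / np.where(var > 1e-12, var, 1.0), 0.0)

    out = {"entropy": entropy, "contrast": contrast, "variance": var,
           "homogeneity": homog, "correlation": corr}
    for k in out:
        out[k] = np.where(empty, np.nan, out[k])
    return out


def terrain_features(dem: np.ndarray, pixel_size_m: float = 30.0):
    """Slope and aspect (degrees) from central differences on the DEM.

    Slope is in [0, 90); aspect is measured clockwise from north toward the
    downslope direction, in [0, 360), with flat cells assigned the sentinel
    0 and flagged.  Returns ``(slope, aspect, flat_mask)``.
    """
    dem = np.asarray(dem, dtype=np.float64)
    if not np.isfinite(dem).all():
        raise ValueError("DEM must be finite")
    dz_drow, dz_dcol = np.gradient(dem, pixel_size_m)
    dzdx = dz_dcol            # east
    dzdy = -dz_drow           # north (row index grows southward)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    flat = (dzdx == 0) & (dzdy == 0)
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect[flat] = 0.0
    return slope, aspect, flat


def build_feature_stack(cube: SceneCube, dem: np.ndarray,
                        config: FeatureConfig | None = None) -> FeatureStack:
    """Assemble the full 94-band feature stack for one year.

    16 water-level + 50 percentile + 25 texture + 3 terrain features, in
    that order.  Raises on grid-shape mismatch between cube and DEM.
    """
    config = config or FeatureConfig()
    dem = np.asarray(dem)
    if dem.shape != cube.shape:
        raise ValueError(
            f"dem shape {dem.shape} does not match scene {cube.shape}")

    lt_names, lt_data, _ = quality_mosaic(cube, "ltidei", config)
    ht_names, ht_data, _ = quality_mosaic(cube, "mndwi", config)
    pc_names, pc_data = percentile_composite(cube, config)

    tx_names, tx_planes = [], []
    for p in config.percentiles:
        nir = pc_data[pc_names.index(f"nir_p{p}")]
        tex = glcm_textures(nir, config.glcm)
        for stat in TEXTURE_STATS:
            tx_names.append(f"nir_p{p}_{stat}")
            tx_planes.append(tex[stat])

    slope, aspect, _ = terrain_features(dem, config.pixel_size_m)
    tr_names = ["elevation", "slope", "aspect"]
    tr_planes = [dem.astype(np.float64), slope, aspect]

    names = tuple(lt_names) + tuple(ht_names) + tuple(pc_names) \
        + tuple(tx_names) + tuple(tr_names)
    data = np.concatenate([lt_data, ht_data, pc_data,
                           np.stack(tx_planes), np.stack(tr_planes)])
    return FeatureStack(names=names, data=data.astype(np.float32))
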