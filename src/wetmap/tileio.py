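"""Delivery-format I/O: named 5-degree GeoTIFF tiles, one band per year.

Annual wetland maps are delivered as 5x5-degree tiles in geographic WGS84
coordinates, one GeoTIFF band per year, class codes 180-187 / 0 / 255, and
file names of the form ``<prefix>_<period>_E115N30`` carrying the
upper-left corner (E/W longitude, N/S latitude).  This module reads and
writes that format bit-exactly, refusing to write any label outside the
published class set.

GeoTIFFs are written with ``tifffile`` plus the standard georeferencing
tags (ModelPixelScale, ModelTiepoint and a minimal GeoKeyDirectory for
geographic WGS84, pixel-is-area).  Genuinely unobserved pixels are flagged
in a separate sidecar mask file rather than by overloading a label code
(255 means ocean, not nodata).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .codes import validate_codes

DEFAULT_PREFIX = "GWL_FCS30D"

# GeoTIFF tag ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
# GTModelType=geographic(2), GTRasterType=area(1), GeographicType=WGS84(4326)
_WGS84_KEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


def format_tile_name(lon_ul: float, lat_ul: float, period: str = "20002022",
                     prefix: str = DEFAULT_PREFIX) -> str:
    """Tile name from the upper-left corner (degrees, multiples of 5).

    Longitude is zero-padded to 3 digits, latitude to 2 (the published
    wildcard does not fix the padding; the parser accepts both).
    """
    if not (-180 <= lon_ul < 180) or not (-90 < lat_ul <= 90):
        raise ValueError(f"corner ({lon_ul}, {lat_ul}) out of range")
    if lon_ul % 5 or lat_ul % 5:
        raise ValueError("tile corners must be multiples of 5 degrees")
    ew = "E" if lon_ul >= 0 else "W"
    ns = "N" if lat_ul >= 0 else "S"
    return (f"{prefix}_{period}_{ew}{abs(int(lon_ul)):03d}"
            f"{ns}{abs(int(lat_ul)):02d}")


_NAME_RE = re.compile(
    r"^(?P<prefix>.+)_(?P<period>\d{4,8})_"
    r"(?P<ew>[EW])(?P<lon>\d{1,3})(?P<ns>[NS])(?P<lat>\d{1,2})$")


def parse_tile_name(name: str):
    """Inverse of :func:`format_tile_name`; accepts unpadded coordinates.

    Returns ``(lon_ul, lat_ul, period, prefix)``.
    """
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"cannot parse tile name {name!r}")
    lon = int(m["lon"]) * (1 if m["ew"] == "E" else -1)
    lat = int(m["lat"]) * (1 if m["ns"] == "N" else -1)
    return float(lon), float(lat), m["period"], m["prefix"]


@dataclass
class AnnualLabelCube:
    """(H, W, n_years) classified label cube with geographic anchoring."""

    labels: np.ndarray
    years: tuple
    lon_ul: float = 0.0
    lat_ul: float = 5.0
    pixel_size_deg: float = 0.025
    mask: np.ndarray | None = None  # True where genuinely unobserved

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.shape[2] != len(self.years):
            raise ValueError("labels must be (H, W, n_years)")


def _geo_tags(lon_ul, lat_ul, px):
    return [
        (_MODEL_PIXEL_SCALE, "d", 3, (px, px, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, lon_ul, lat_ul, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(_WGS84_KEYS), _WGS84_KEYS),
    ]


def write_annual_tile(cube: AnnualLabelCube, path) -> None:
    """Write a label cube as a one-band-per-year WGS84 GeoTIFF.

    Refuses to write labels outside the published class set, listing the
    offenders.  An optional unobserved-pixel mask goes to ``<path>.mask.tif``.
    """
    offenders = validate_codes(cube.labels)
    if offenders:
        raise ValueError(f"illegal class codes, refusing to write: {offenders}")
    desc = json.dumps({"years": list(cube.years)})
    data = np.moveaxis(cube.labels.astype(np.uint8), 2, 0)  # (years, H, W)
    tifffile.imwrite(path, data, photometric="minisblack", description=desc,
                     extratags=_geo_tags(cube.lon_ul, cube.lat_ul,
                                         cube.pixel_size_deg))
    if cube.mask is not None:
        tifffile.imwrite(str(path) + ".mask.tif",
                         cube.mask.astype(np.uint8))


def read_annual_tile(path) -> AnnualLabelCube:
    """Read a cube written by :func:`write_annual_tile` (bit-exact)."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        page = tf.pages[0]
        scale = page.tags[_MODEL_PIXEL_SCALE].value
        tie = page.tags[_MODEL_TIEPOINT].value
        desc = json.loads(page.tags[270].value)
    if data.ndim == 2:
        data = data[None]
    labels = np.moveaxis(data, 0, 2)
    mask = None
    import os
    mpath = str(path) + ".mask.tif"
    if os.path.exists(mpath):
        mask = tifffile.imread(mpath).astype(bool)
    return AnnualLabelCube(labels=labels, years=tuple(desc["years"]),
                           lon_ul=float(tie[3]), lat_ul=float(tie[4]),
                           pixel_size_deg=float(scale[0]), mask=mask)


def write_raster(array: np.ndarray, path, lon_ul=0.0, lat_ul=5.0,
                 pixel_size_deg=0.025, description: str = "") -> None:
    """Write a single- or multi-band float/int raster with geo tags.

    Multi-band input is (bands, H, W); *description* typically carries the
    JSON-encoded band names.
    """
    tifffile.imwrite(path, np.asarray(array), description=description or "{}",
                     extratags=_geo_tags(lon_ul, lat_ul, pixel_size_deg))


def read_raster(path):
    """Read a raster written by :func:`write_raster`; returns
    ``(array, description)``."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].tags[270].value
    return arr, desc
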