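"""Synthetic reflectance scenes with wetland-like structure.

This module generates the inputs the mapping pipeline consumes — multi-date
six-band surface-reflectance stacks with cloud masks, a DEM, truth label
cubes and stratified sample points — with the statistical structure the
method exploits in real imagery:

* **water-level dynamics**: tidal classes (tidal flat, salt marsh fringe)
  are water-covered except on randomly drawn low-tide dates; flooded flats
  follow a deterministic seasonal inundation cycle; permanent water and
  ocean are always water.
* **phenology**: vegetated classes ride a sinusoidal seasonal cycle (NIR up,
  red down in the growing season) so percentile composites carry signal.
* **cloud gaps**: contiguous random blobs, not i.i.d. pixels, to exercise
  mask-aware compositing.
* **topography**: wetland pixels sit systematically lower than non-wetland.

Everything is a pure function of ``(config, seed)``; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .codes import ClassCode, VALID_CODES
from .indices import BANDS, IndexConfig, compute_indices

#: Reflectance of open water in (blue, green, red, nir, swir1, swir2).
WATER_SPECTRUM = np.array([0.060, 0.080, 0.055, 0.030, 0.015, 0.010])
WATER_SD = 0.008


@dataclass(frozen=True)
class ClassSpectralModel:
    """Spectral and inundation behaviour of one land-cover class.

    band_means / band_sd
        Mean reflectance and per-band Gaussian noise SD of the *exposed*
        (non-inundated) surface, in band order blue..swir2, clipped to [0,1].
    phenology_amplitude
        Per-band amplitude of the seasonal sinusoid added to the means.
    inundation_model
        ``"none"``, ``"tidal"`` (Bernoulli low-tide exposure per date),
        ``"seasonal-flood"`` (day-of-year sinusoid with threshold) or
        ``"permanent"`` (always water).
    exposure_prob
        For tidal classes: probability that a date is a low-tide (exposed)
        date.
    flood_fraction
        For seasonal-flood classes: fraction of the year spent inundated.
    """

    class_code: int
    band_means: tuple
    band_sd: tuple = (0.01,) * 6
    phenology_amplitude: tuple = (0.0,) * 6
    inundation_model: str = "none"
    exposure_prob: float = 0.2
    flood_fraction: float = 0.5

    def __post_init__(self):
        if self.class_code not in VALID_CODES:
            raise ValueError(f"unknown class code {self.class_code}")
        if self.inundation_model not in ("none", "tidal", "seasonal-flood", "permanent"):
            raise ValueError(f"unknown inundation model {self.inundation_model!r}")
        if np.any(np.asarray(self.band_sd) < 0):
            raise ValueError("band_sd must be nonnegative")
        means = np.asarray(self.band_means)
        if np.any(means < 0) or np.any(means > 1):
            raise ValueError("band_means must lie in [0, 1]")


def default_spectral_models() -> dict[int, ClassSpectralModel]:
    """A spectral library with well-separated, physically plausible classes."""
    veg_amp = (0.0, 0.005, -0.02, 0.08, 0.02, 0.0)
    return {int(c.class_code): c for c in [
        ClassSpectralModel(ClassCode.NWT, (0.10, 0.13, 0.16, 0.25, 0.28, 0.22),
                           (0.015,) * 6, (0.0, 0.0, -0.01, 0.03, 0.01, 0.0)),
        ClassSpectralModel(ClassCode.PWT, tuple(WATER_SPECTRUM), (WATER_SD,) * 6,
                           inundation_model="permanent"),
        ClassSpectralModel(ClassCode.SWP, (0.04, 0.06, 0.05, 0.32, 0.14, 0.06),
                           (0.012,) * 6, veg_amp),
        ClassSpectralModel(ClassCode.MSH, (0.05, 0.08, 0.07, 0.36, 0.18, 0.09),
                           (0.012,) * 6, veg_amp),
        ClassSpectralModel(ClassCode.FFT, (0.09, 0.11, 0.13, 0.20, 0.16, 0.11),
                           (0.012,) * 6, inundation_model="seasonal-flood",
                           flood_fraction=0.5),
        ClassSpectralModel(ClassCode.SLE, (0.24, 0.27, 0.30, 0.33, 0.30, 0.26),
                           (0.015,) * 6),
        ClassSpectralModel(ClassCode.MGV, (0.03, 0.05, 0.04, 0.28, 0.10, 0.04),
                           (0.010,) * 6, veg_amp),
        ClassSpectralModel(ClassCode.SMH, (0.06, 0.09, 0.09, 0.30, 0.20, 0.12),
                           (0.012,) * 6, veg_amp, inundation_model="tidal",
                           exposure_prob=0.6),
        ClassSpectralModel(ClassCode.TFT, (0.08, 0.10, 0.12, 0.19, 0.15, 0.10),
                           (0.010,) * 6, inundation_model="tidal",
                           exposure_prob=0.2),
        ClassSpectralModel(ClassCode.OCEAN, tuple(WATER_SPECTRUM), (WATER_SD,) * 6,
                           inundation_model="permanent"),
    ]}


@dataclass(frozen=True)
class SimulationConfig:
    """Scene geometry, observation density and randomness of a simulation.

    extent
        (height, width) in pixels.
    years
        Years simulated (annual cubes).
    dates_per_year
        Number of observations per year, spread evenly over the year.
    cloud_fraction
        Expected masked fraction per observation, in [0, 1).
    change_events
        Step land-cover changes: tuples ``(class_from, class_to, year,
        (row0, row1, col0, col1))`` applied to the truth from *year* on.
    lon_ul, lat_ul, pixel_size_deg
        Geographic anchoring (WGS84, upper-left corner, pixel-is-area).
    """

    extent: tuple = (128, 128)
    years: tuple = tuple(range(2000, 2008))
    dates_per_year: int = 12
    cloud_fraction: float = 0.1
    seed: int = 0
    change_events: tuple = ()
    lon_ul: float = 0.0
    lat_ul: float = 5.0
    pixel_size_deg: float = 0.025

    def __post_init__(self):
        if self.dates_per_year < 1:
            raise ValueError("dates_per_year must be >= 1")
        if not 0 <= self.cloud_fraction < 1:
            raise ValueError("cloud_fraction must be in [0, 1)")

    def lonlat(self, rows, cols):
        """Pixel-centre geographic coordinates of (row, col) arrays."""
        lon = self.lon_ul + (np.asarray(cols) + 0.5) * self.pixel_size_deg
        lat = self.lat_ul - (np.asarray(rows) + 0.5) * self.pixel_size_deg
        return lon, lat


@dataclass
class SceneCube:
    """One year of co-registered multi-date six-band observations.

    reflectance : (n_dates, 6, H, W) float32, band order blue..swir2
    valid       : (n_dates, H, W) bool, True where the observation is usable
    dates       : (n_dates,) float day-of-year
    """

    year: int
    dates: np.ndarray
    reflectance: np.ndarray
    valid: np.ndarray

    @property
    def shape(self):
        return self.reflectance.shape[2:]

    @property
    def n_dates(self):
        return len(self.dates)


def _rng(config: SimulationConfig, *keys) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed,) + keys))


def default_truth(extent=(128, 128)) -> np.ndarray:
    """A banded truth map containing all ten classes.

    Vertical bands from left to right: ocean, tidal flat, salt marsh,
    mangrove, marsh, flooded flat, permanent water, swamp, saline,
    non-wetland — a stylised coast-to-inland transect.
    """
    h, w = extent
    order = [ClassCode.OCEAN, ClassCode.TFT, ClassCode.SMH, ClassCode.MGV,
             ClassCode.MSH, ClassCode.FFT, ClassCode.PWT, ClassCode.SWP,
             ClassCode.SLE, ClassCode.NWT]
    truth = np.zeros((h, w), dtype=np.uint8)
    edges = np.linspace(0, w, len(order) + 1).astype(int)
    for code, c0, c1 in zip(order, edges[:-1], edges[1:]):
        truth[:, c0:c1] = int(code)
    return truth


def truth_series(config: SimulationConfig, truth: np.ndarray) -> dict[int, np.ndarray]:
    """Per-year truth grids with the configured change events applied."""
    out = {}
    current = truth.copy()
    for year in config.years:
        for (cfrom, cto, y, region) in config.change_events:
            if y == year:
                r0, r1, c0, c1 = region
                block = current[r0:r1, c0:c1]
                block[block == cfrom] = cto
        out[year] = current.copy()
    return out


def _cloud_mask(config, year, h, w):
    """Contiguous cloud blobs per date: smoothed white noise thresholded
    at the cloud_fraction quantile."""
    rng = _rng(config, year, 7)
    valid = np.ones((config.dates_per_year, h, w), dtype=bool)
    if config.cloud_fraction == 0:
        return valid
    for d in range(config.dates_per_year):
        f = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=8.0)
        thr = np.quantile(f, 1.0 - config.cloud_fraction)
        valid[d] = f <= thr
    return valid


def simulate_year(config: SimulationConfig, truth: np.ndarray,
                  models: dict[int, ClassSpectralModel] | None = None,
                  year: int | None = None) -> SceneCube:
    """Simulate one year of observations for a truth grid.

    Raises ``ValueError`` if the truth grid contains a class code without a
    spectral model.
    """
    models = models if models is not None else default_spectral_models()
    year = year if year is not None else config.years[0]
    truth = np.asarray(truth)
    h, w = truth.shape
    present = [int(v) for v in np.unique(truth)]
    unknown = sorted(set(present) - set(models))
    if unknown:
        raise ValueError(f"truth grid contains codes without spectral models: {unknown}")

    dates = np.linspace(15.0, 350.0, config.dates_per_year)
    refl = np.empty((config.dates_per_year, 6, h, w), dtype=np.float32)
    rng = _rng(config, year, 1)

    for code in present:
        m = models[code]
        mask = truth == code
        npix = int(mask.sum())
        season = np.sin(2 * np.pi * (dates - 120.0) / 365.0)  # peak ~ midsummer
        if m.inundation_model == "tidal":
            exposed = rng.random(config.dates_per_year) < m.exposure_prob
        elif m.inundation_model == "seasonal-flood":
            # inundated during the high-water half-cycle
            exposed = np.sin(2 * np.pi * (dates - 30.0) / 365.0) < (
                1.0 - 2.0 * m.flood_fraction)
        elif m.inundation_model == "permanent":
            exposed = np.zeros(config.dates_per_year, dtype=bool)
        else:
            exposed = np.ones(config.dates_per_year, dtype=bool)
        for d in range(config.dates_per_year):
            if exposed[d]:
                mean = (np.asarray(m.band_means)
                        + np.asarray(m.phenology_amplitude) * season[d])
                sd = np.asarray(m.band_sd)
            else:
                mean, sd = WATER_SPECTRUM, np.full(6, WATER_SD)
            vals = mean[:, None] + sd[:, None] * rng.standard_normal((6, npix))
            refl[d, :, mask] = np.clip(vals, 0.0, 1.0).T.astype(np.float32)

    valid = _cloud_mask(config, year, h, w)
    return SceneCube(year=year, dates=dates, reflectance=refl, valid=valid)


def simulate_dem(config: SimulationConfig, truth: np.ndarray,
                 base_elevation: float = 50.0, wetland_offset: float = 10.0,
                 noise_sd: float = 2.0, noise_sigma: float = 6.0) -> np.ndarray:
    """Smooth DEM in metres with wetlands *wetland_offset* m lower on average.

    With ``noise_sd=0`` and ``wetland_offset=0`` the grid is exactly
    constant at *base_elevation*.
    """
    from .codes import WETLAND_CODES

    truth = np.asarray(truth)
    rng = _rng(config, 11)
    dem = np.full(truth.shape, base_elevation, dtype=np.float64)
    wet = np.isin(truth, list(WETLAND_CODES) + [int(ClassCode.OCEAN)])
    dem[wet] -= wetland_offset
    if noise_sd > 0:
        f = ndimage.gaussian_filter(rng.standard_normal(truth.shape), noise_sigma)
        sd = f.std()
        if sd > 0:
            dem += noise_sd * f / sd
    return dem


def sample_points(truths: dict[int, np.ndarray], n_per_class: int, seed: int,
                  scenes: dict[int, SceneCube] | None = None,
                  config: SimulationConfig | None = None,
                  classes=None):
    """Stratified-by-class sample points with per-year auxiliary series.

    Parameters
    ----------
    truths
        Mapping year -> truth grid (the first year defines the strata).
    n_per_class
        Points drawn per class; a requested class absent from the truth
        yields an empty stratum with a warning, not an error.
    classes
        Class codes to stratify over; defaults to the codes present in the
        first year's truth.
    scenes
        Optional mapping year -> :class:`SceneCube`; when given, the
        NDVI 90th-percentile, yearly max LTideI and a water flag (median
        mNDWI > 0) are computed from the actual simulated series, otherwise
        the auxiliary columns are omitted.
    config
        When given, geographic ``x``/``y`` columns are attached.

    Returns
    -------
    pandas.DataFrame with columns row, col, class_code, (x, y), per-year
    ``epoch_<year>`` truth labels and, with *scenes*, ``ndvi_p90_<year>``,
    ``max_ltidei_<year>``, ``water_<year>``.
    """
    import pandas as pd

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    years = sorted(truths)
    truth0 = np.asarray(truths[years[0]])
    rng = np.random.default_rng(seed)
    if classes is None:
        classes = sorted(int(v) for v in np.unique(truth0))
    rows, cols, labels = [], [], []
    for code in classes:
        r, c = np.nonzero(truth0 == code)
        if len(r) == 0:
            warnings.warn(f"class {code} absent from truth; empty stratum")
            continue
        take = min(n_per_class, len(r))
        if take < n_per_class:
            warnings.warn(f"class {code}: only {take} pixels available")
        idx = rng.choice(len(r), size=take, replace=False)
        rows.extend(r[idx]); cols.extend(c[idx]); labels.extend([code] * take)

    df = pd.DataFrame({"row": rows, "col": cols, "class_code": labels})
    if config is not None:
        lon, lat = config.lonlat(df["row"].to_numpy(), df["col"].to_numpy())
        df["x"], df["y"] = lon, lat
    for year in years:
        df[f"epoch_{year}"] = np.asarray(truths[year])[df["row"], df["col"]]
    if scenes is not None:
        icfg = IndexConfig()
        for year in years:
            cube = scenes[year]
            nd = np.full(len(df), np.nan)
            lt = np.full(len(df), np.nan)
            wf = np.zeros(len(df), dtype=bool)
            idx = compute_indices(
                np.moveaxis(cube.reflectance, 1, 0), icfg)  # (6, nd, H, W)
            for i, (r, c) in enumerate(zip(df["row"], df["col"])):
                ok = cube.valid[:, r, c]
                if not ok.any():
                    continue
                nd[i] = np.percentile(idx["ndvi"][ok, r, c], 90)
                lt[i] = idx["ltidei"][ok, r, c].max()
                wf[i] = np.median(idx["mndwi"][ok, r, c]) > 0
            df[f"ndvi_p90_{year}"] = nd
            df[f"max_ltidei_{year}"] = lt
            df[f"water_{year}"] = wf
    return df
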