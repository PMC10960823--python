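# wetmap

Annual wetland mapping from multi-band surface-reflectance time series, at
desk scale.  The package implements the full methodology behind global
30 m annual wetland products — eight wetland subcategories (permanent
water, swamp, marsh, flooded flat, saline, mangrove, salt marsh, tidal
flat) mapped year by year from Landsat-like observations — as a tested,
importable Python library with a synthetic-scene generator in place of the
petabyte-scale archive.

## What it computes

Wetland reflectance is driven by two confounded signals: **water level**
(tidal flats are water on most dates and mud on a few) and **phenology**
(marshes green up and brown down).  The pipeline condenses a year of
six-band observations (blue, green, red, NIR, SWIR1, SWIR2) into a
94-variable stack:

* **Water-level composites (16).**  The low-tide index

  $$\mathrm{LTideI}=\frac{\rho_{NIR}-\max(\rho_{blue},\rho_{green},\rho_{red},\rho_{SWIR2})}{\rho_{NIR}+\max(\rho_{blue},\rho_{green},\rho_{red},\rho_{SWIR2})+L}\,(1+L),\qquad L=0.1$$

  is positive on exposed flats and negative on water; the modified water
  index $\mathrm{mNDWI}=(\rho_{green}-\rho_{NIR})/(\rho_{green}+\rho_{NIR})$
  is positive over water.  A *quality mosaic* per index selects, for every
  pixel, the full band vector of the observation maximising the index —
  the lowest and highest water level the year offers.
* **Percentile phenology (50).**  10/30/50/70/90th percentiles of the six
  bands and of NDVI, mNDWI, LSWI, LTideI (extremes are skipped: they
  concentrate residual cloud/snow).
* **Texture (25).**  Grey-level co-occurrence entropy, contrast, variance,
  homogeneity and correlation of the five NIR percentile bands.
* **Terrain (3).**  Elevation, slope, aspect.

Around the stack: four **temporal-stability rules** refine a training pool
so one epoch's samples can serve two decades; a **local-adaptive
classifier** trains an independent 100-tree random forest per 5°×5° tile
on samples pooled from the tile's 3×3 neighborhood; a **spatiotemporal
consistency optimizer** evaluates, per pixel-year, the homogeneity
probability

$$P(x,y,t)=\frac{1}{N}\sum_{x'}\sum_{y'}\sum_{t'} I\!\left[L(x',y',t')=L(x,y,t)\right]$$

over a 3×3×3 window and relabels only when both the exact probability
(< 0.5) and the water-level-group probability (≤ 1/3) reject the label;
and a **stratified assessment** module computes validation sample sizes
and error-matrix metrics (OA, Kappa, producer's and user's accuracies).
The published 2020 validation error matrix ships as a fixture.

## A worked example

```bash
python examples/06_accuracy_assessment.py
```

prints (abridged):

```
single-stratum design: n = 384.16 -> 384 points
published 2020 matrix (9 classes): OA = 86.95%, Kappa = 0.822
 class    PA %    UA %
   MSH   64.13   77.16
   TFT   90.40   82.26
   ...
validation points: 22719 total = 10952 non-wetland + 11767 wetland (7833 inland + 3934 coastal)
```

The first line is the classical stratified sample-size formula at worst-case
accuracy 0.5 and a ±5% interval; the table reproduces the published 2020
accuracy figures from the packaged error matrix (producer's accuracy =
per-class recall over reference rows, user's = precision over map columns).

The full pipeline on a synthetic scene — simulate → composite → refine →
classify → optimize → assess:

```bash
wetmap run --config examples/demo_config.yaml
```

```
{
  "oa_final_year": 99.5849609375,
  "kappa": 0.995385450597177,
  "relabels": 55,
  "tile": "GWL_FCS30D_20002004_E000N05"
}
```

Accuracy near 1 reflects the deliberately well-separated synthetic
spectra; see `docs/methods.md` for what the synthetic scenes do and do not
emulate.  `examples/01`–`05` walk through each stage individually, and the
`wetmap` CLI exposes them as `simulate | features | refine | classify |
optimize | assess | run` subcommands.

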