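"""Composite a year of observations into the 94-variable feature stack.

The stack holds 16 water-level features (lowest/highest water-level quality
mosaics), 50 percentile phenology features, 25 co-occurrence texture
features on the NIR percentiles, and 3 terrain features.
"""

import wetmap as wm

cfg = wm.SimulationConfig(extent=(64, 64), years=(2000,), dates_per_year=12,
                          cloud_fraction=0.1, seed=0)
truth = wm.default_truth(cfg.extent)
cube = wm.simulate_year(cfg, truth)
dem = wm.simulate_dem(cfg, truth)
stack = wm.build_feature_stack(cube, dem)

tide = [n for n in stack.names if n.startswith(("lowtide_", "hightide_"))]
tex = [n for n in stack.names if n.endswith(
    ("entropy", "contrast", "variance", "homogeneity", "correlation"))]
terrain = ["elevation", "slope", "aspect"]
pct = [n for n in stack.names if n not in tide + tex + terrain]

print(f"total bands: {len(stack.names)} "
      f"= {len(tide)} water-level + {len(pct)} percentile "
      f"+ {len(tex)} texture + {len(terrain)} terrain")
print("water-level bands:", ", ".join(tide))

tft = truth == 187
print(f"tidal flats: low-tide LTideI composite mean "
      f"{stack['lowtide_ltidei'][tft].mean():.2f} (>0: exposed at low tide), "
      f"median-mNDWI percentile {stack['mndwi_p50'][tft].mean():.2f} "
      f"(>0: water most of the year)")
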