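"""Refine a candidate training pool to temporally stable samples.

Simulates several years including a marsh->non-wetland conversion event,
draws stratified candidate points, and applies the four class-specific
stability rules.  Samples caught by a rule are removed with a recorded
reason.
"""

import wetmap as wm

cfg = wm.SimulationConfig(
    extent=(64, 64), years=tuple(range(2000, 2006)), dates_per_year=10,
    cloud_fraction=0.05, seed=1,
    change_events=((182, 0, 2003, (0, 30, 25, 32)),))  # marsh drained in 2003
truths = wm.truth_series(cfg, wm.default_truth(cfg.extent))
scenes = {y: wm.simulate_year(cfg, truths[y], year=y) for y in cfg.years}

candidates = wm.sample_points(truths, n_per_class=50, seed=2,
                              scenes=scenes, config=cfg)
pool, report = wm.assemble_pool(candidates)

print(f"candidates: {report.input_count}, retained: {report.retained_count}")
for reason, count in sorted(report.removed_by_reason.items()):
    print(f"  removed ({reason}): {count}")

# 'vegetation-change' removals are marsh points whose NDVI p90 series
# dropped by more than 0.2 after the 2003 conversion; 'negative-ltidei'
# removals are flats that never exposed in some year (e.g. under cloud).
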