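"""Stratified validation design and error-matrix metrics.

Computes the sample size required for a 95% confidence interval, then
evaluates the packaged 2020 validation error matrix of the published
global wetland dataset.
"""

import wetmap as wm
from wetmap.assessment import SamplingDesign, allocate_sample_size

# one stratum, anticipated accuracy 0.5 (worst case), +-5% at 95% confidence
al = allocate_sample_size(SamplingDesign(W=(1.0,), p=(0.5,), d=0.05, t=1.96))
print(f"single-stratum design: n = {al.n_real:.2f} -> {al.n} points")

matrix = wm.load_error_matrix_2020()
met = wm.accuracy_metrics(matrix)
print(f"published 2020 matrix ({len(matrix.labels)} classes): "
      f"OA = {met['oa']:.2f}%, Kappa = {met['kappa']:.3f}")
print(f"{'class':>6} {'PA %':>7} {'UA %':>7}")
for lab in matrix.labels:
    print(f"{lab:>6} {met['pa'][lab]:7.2f} {met['ua'][lab]:7.2f}")

design = wm.load_validation_design_2020()
print(f"validation points: {design['total_points']} total = "
      f"{design['strata']['non_wetland']} non-wetland + "
      f"{design['wetland_points']} wetland "
      f"({design['strata']['inland_wetland']} inland + "
      f"{design['strata']['coastal_wetland']} coastal)")
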