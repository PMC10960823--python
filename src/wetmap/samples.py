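"""Temporally stable training-sample refinement.

A training pool representative of one epoch cannot be reused across two
decades of annual mapping unless each sample is certified temporally
stable.  Four class-specific rules do this:

* **non-wetland** samples are dropped if any multi-epoch land-cover map
  labels them water or wetland in any epoch;
* **vegetated wetland** samples (swamp, marsh, mangrove, salt marsh) are
  dropped when a temporal-segmentation change detector flags their
  inter-annual NDVI 90th-percentile series;
* **flat** samples (tidal flat, flooded flat) are dropped if any year's
  maximum LTideI is negative (a genuinely exposed flat scores positive at
  low water in every year);
* **permanent-water** samples must be water in every year.

Saline samples pass through unchanged: they are sparse, concentrated in a
few regions, and assumed pre-vetted by visual interpretation.  Samples with
incomplete series are removed rather than imputed — stability cannot be
certified on gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import ClassCode, WETLAND_CODES

#: Class groups each refinement rule applies to.
NONWETLAND_CLASSES = frozenset({int(ClassCode.NWT)})
VEGETATED_CLASSES = frozenset({int(ClassCode.SWP), int(ClassCode.MSH),
                               int(ClassCode.MGV), int(ClassCode.SMH)})
FLAT_CLASSES = frozenset({int(ClassCode.TFT), int(ClassCode.FFT)})
WATER_CLASSES = frozenset({int(ClassCode.PWT), int(ClassCode.OCEAN)})
PASSTHROUGH_CLASSES = frozenset({int(ClassCode.SLE)})

#: Epoch labels that disqualify a non-wetland sample.
_WATER_OR_WETLAND = frozenset(WETLAND_CODES) | {int(ClassCode.OCEAN)}


@dataclass
class ChangeDetectorConfig:
    """Parameters of the simplified temporal-segmentation detector.

    drop_threshold
        Minimum absolute fitted NDVI change (within a segment, or as a step
        between adjacent segments) that counts as a land-cover change.
    max_segments
        Maximum pieces of the greedy piecewise-linear fit.
    min_segment_length
        Minimum observations per segment.
    rmse_improvement_ratio
        Optional secondary trigger: flag when segmentation reduces RMSE
        relative to a single line by more than this fraction.  Disabled
        (None) by default: on short annual series a multi-segment fit
        almost always improves RMSE by chance, so magnitude is the
        trustworthy signal.
    """

    drop_threshold: float = 0.2
    max_segments: int = 3
    min_segment_length: int = 2
    rmse_improvement_ratio: float | None = None


def _fit_segment(t, y):
    """OLS line fit; returns (fitted values, SSE)."""
    if len(t) == 1:
        return y.copy(), 0.0
    A = np.vstack([t, np.ones_like(t)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fit = A @ coef
    return fit, float(((y - fit) ** 2).sum())


def _piecewise_fit(y, config: ChangeDetectorConfig):
    """Greedy segmentation: repeatedly split the segment whose best split
    reduces total SSE the most.  Returns the list of (start, stop) bounds."""
    n = len(y)
    t = np.arange(n, dtype=float)
    segs = [(0, n)]
    for _ in range(config.max_segments - 1):
        best = None
        for si, (a, b) in enumerate(segs):
            _, sse0 = _fit_segment(t[a:b], y[a:b])
            for cut in range(a + config.min_segment_length,
                             b - config.min_segment_length + 1):
                _, s1 = _fit_segment(t[a:cut], y[a:cut])
                _, s2 = _fit_segment(t[cut:b], y[cut:b])
                gain = sse0 - (s1 + s2)
                if best is None or gain > best[0]:
                    best = (gain, si, cut)
        if best is None or best[0] <= 0:
            break
        _, si, cut = best
        a, b = segs.pop(si)
        segs[si:si] = [(a, cut), (cut, b)]
    return sorted(segs)


def detect_vegetation_change(ndvi_p90_series,
                             config: ChangeDetectorConfig | None = None) -> bool:
    """Flag an inter-annual NDVI p90 series as changed.

    A greedy piecewise-linear fit (up to ``max_segments`` pieces) is
    computed; the series is flagged when any fitted segment's start-to-end
    change, or the fitted step between adjacent segments, exceeds
    ``drop_threshold`` in absolute value.  Deterministic.  Requires a
    finite series of at least 4 years.
    """
    config = config or ChangeDetectorConfig()
    y = np.asarray(ndvi_p90_series, dtype=np.float64)
    if y.ndim != 1 or len(y) < 4:
        raise ValueError("need a 1-D series of at least 4 years")
    if not np.isfinite(y).all():
        raise ValueError("series contains non-finite entries")

    t = np.arange(len(y), dtype=float)
    segs = _piecewise_fit(y, config)
    fits = {}
    total_sse = 0.0
    for (a, b) in segs:
        fit, sse = _fit_segment(t[a:b], y[a:b])
        fits[(a, b)] = fit
        total_sse += sse

    changes = []
    for (a, b) in segs:
        changes.append(abs(fits[(a, b)][-1] - fits[(a, b)][0]))
    for (a, b), (a2, b2) in zip(segs[:-1], segs[1:]):
        changes.append(abs(fits[(a2, b2)][0] - fits[(a, b)][-1]))
    if max(changes) > config.drop_threshold:
        return True

    if config.rmse_improvement_ratio is not None and len(segs) > 1:
        _, sse_line = _fit_segment(t, y)
        if sse_line > 0:
            improvement = 1.0 - np.sqrt(total_sse / sse_line)
            if improvement > config.rmse_improvement_ratio:
                return True
    return False


def filter_flats(max_ltidei_series) -> bool:
    """A flat sample is retained iff every year's max LTideI is >= 0."""
    y = np.asarray(max_ltidei_series, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty LTideI series")
    return bool(np.min(y) >= 0.0)


def filter_permanent_water(water_flag_series) -> bool:
    """A water sample is retained iff it is water in every year."""
    y = np.asarray(water_flag_series)
    if y.size == 0:
        raise ValueError("empty water-flag series")
    return bool(np.all(y.astype(bool)))


def _epoch_stable_nonwetland(epoch_labels) -> bool:
    return not any(int(v) in _WATER_OR_WETLAND for v in epoch_labels)


def filter_nonwetland(samples: pd.DataFrame, epoch_maps: dict) -> pd.DataFrame:
    """Retain non-wetland samples never mapped water/wetland in any epoch.

    *epoch_maps* maps epoch identifiers to label grids; samples index the
    grids through their ``row``/``col`` columns.  Samples falling outside
    any grid are removed (reason "no-data").  Non-"non-wetland" rows pass
    through untouched.
    """
    if not epoch_maps:
        raise ValueError("at least one epoch map is required")
    keep = np.ones(len(samples), dtype=bool)
    for i, (_, s) in enumerate(samples.iterrows()):
        if int(s["class_code"]) not in NONWETLAND_CLASSES:
            continue
        labels = []
        for grid in epoch_maps.values():
            grid = np.asarray(grid)
            r, c = int(s["row"]), int(s["col"])
            if not (0 <= r < grid.shape[0] and 0 <= c < grid.shape[1]):
                keep[i] = False
                break
            labels.append(grid[r, c])
        else:
            keep[i] = _epoch_stable_nonwetland(labels)
    return samples.loc[keep].copy()


@dataclass
class StabilityReport:
    """Bookkeeping of a refinement pass: retained + removed = input."""

    input_count: int = 0
    retained_count: int = 0
    removed_by_reason: dict = field(default_factory=dict)
    per_class: dict = field(default_factory=dict)
    reasons: pd.Series | None = None

    @property
    def removed_count(self) -> int:
        return sum(self.removed_by_reason.values())

    def to_dict(self):
        return {
            "input": self.input_count,
            "retained": self.retained_count,
            "removed": self.removed_count,
            "removed_by_reason": dict(self.removed_by_reason),
            "per_class": {str(k): dict(v) for k, v in self.per_class.items()},
        }


def _series_columns(df: pd.DataFrame, prefix: str):
    cols = sorted((c for c in df.columns if c.startswith(prefix)),
                  key=lambda c: int(c.rsplit("_", 1)[-1]))
    return cols


def assemble_pool(candidates: pd.DataFrame,
                  detector: ChangeDetectorConfig | None = None):
    """Apply every class's stability rule; return (retained, report).

    Expects the candidate table to carry ``class_code``, ``epoch_<year>``
    columns and, per class group as needed, ``ndvi_p90_<year>``,
    ``max_ltidei_<year>`` and ``water_<year>`` columns.  A class outside
    all rule groups raises.  Order-invariant and idempotent.
    """
    detector = detector or ChangeDetectorConfig()
    epoch_cols = _series_columns(candidates, "epoch_")
    ndvi_cols = _series_columns(candidates, "ndvi_p90_")
    lt_cols = _series_columns(candidates, "max_ltidei_")
    water_cols = _series_columns(candidates, "water_")

    known = (NONWETLAND_CLASSES | VEGETATED_CLASSES | FLAT_CLASSES
             | WATER_CLASSES | PASSTHROUGH_CLASSES)
    bad = sorted(set(int(c) for c in candidates["class_code"]) - known)
    if bad:
        raise ValueError(f"no stability rule assigned for classes {bad}")

    reasons = pd.Series("retained", index=candidates.index, dtype=object)
    for i, s in candidates.iterrows():
        code = int(s["class_code"])
        try:
            if code in NONWETLAND_CLASSES:
                vals = s[epoch_cols].to_numpy(dtype=float)
                if np.isnan(vals).any():
                    reasons[i] = "incomplete-series"
                elif not _epoch_stable_nonwetland(vals.astype(int)):
                    reasons[i] = "epoch-unstable"
            elif code in VEGETATED_CLASSES:
                vals = s[ndvi_cols].to_numpy(dtype=float)
                if len(vals) == 0 or np.isnan(vals).any():
                    reasons[i] = "incomplete-series"
                elif detect_vegetation_change(vals, detector):
                    reasons[i] = "vegetation-change"
            elif code in FLAT_CLASSES:
                vals = s[lt_cols].to_numpy(dtype=float)
                if len(vals) == 0 or np.isnan(vals).any():
                    reasons[i] = "incomplete-series"
                elif not filter_flats(vals):
                    reasons[i] = "negative-ltidei"
            elif code in WATER_CLASSES:
                if not water_cols:
                    reasons[i] = "incomplete-series"
                elif not filter_permanent_water(s[water_cols].to_numpy()):
                    reasons[i] = "not-permanent-water"
            # passthrough classes (saline): always retained
        except ValueError:
            reasons[i] = "incomplete-series"

    keep = reasons == "retained"
    retained = candidates.loc[keep].copy()
    report = StabilityReport(
        input_count=len(candidates),
        retained_count=int(keep.sum()),
        reasons=reasons,
    )
    removed = reasons[~keep]
    report.removed_by_reason = removed.value_counts().to_dict()
    for code, grp in candidates.groupby("class_code"):
        rs = reasons.loc[grp.index]
        report.per_class[int(code)] = {
            "retained": int((rs == "retained").sum()),
            "removed": int((rs != "retained").sum()),
        }
    return retained, report
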