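"""Spatiotemporal consistency optimization of annual label cubes.

Independent per-year classification leaves spurious one-year label flips.
For every pixel-year the *homogeneity probability*

    P(x, y, t) = (1/N) * sum over the (2wx+1) x (2wy+1) x (2wt+1) window
                 of I[L(x', y', t') = L(x, y, t)]

measures how well the label agrees with its spatiotemporal neighborhood
(default window 3x3x3, N counts the in-bounds valid cells, and the center
participates, so P >= 1/N > 0).

The relabeling rule is water-level aware.  Some wetland subcategories swap
labels with their inundated counterparts in wet/dry years without any real
land-cover change, so classes are partitioned into groups (inland water /
flooded flat / marsh; ocean / tidal flat / salt marsh; swamp, mangrove,
saline and non-wetland as singletons) and, per pixel-year, evaluated on the
ORIGINAL cube (simultaneous update):

* P_exact >= 0.5                  -> keep;
* P_exact <  0.5, P_group >  1/3  -> keep (change rejected as a
  within-group water-level fluctuation);
* P_group <= 1/3                  -> relabel to the window-majority label.

Majority ties prefer temporal continuity (the label at t-1, then t+1), then
the lowest class code.  A single pass; the thresholds and window are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .codes import DEFAULT_GROUPS


@dataclass(frozen=True)
class OptimizerConfig:
    """Window extents, thresholds and class grouping.

    boundary="valid" normalises P by the in-bounds valid-cell count N;
    boundary="fixed" uses the full window size everywhere and leaves
    boundary pixels (whose window is clipped) unmodified.
    """

    window: tuple = (1, 1, 1)          # half-sizes (w_x, w_y, w_t)
    p_keep: float = 0.5
    p_group: float = 1.0 / 3.0
    groups: tuple = DEFAULT_GROUPS
    nodata: int = -1
    boundary: str = "valid"

    def __post_init__(self):
        if not (0 < self.p_group < self.p_keep < 1):
            raise ValueError("need 0 < p_group < p_keep < 1")
        if self.boundary not in ("valid", "fixed"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")

    def group_of(self, label: int) -> int:
        for gi, g in enumerate(self.groups):
            if label in g:
                return gi
        raise ValueError(f"label {label} missing from optimizer groups")


def _window_counts(indicator: np.ndarray, config: OptimizerConfig) -> np.ndarray:
    wx, wy, wt = config.window
    size = (2 * wx + 1, 2 * wy + 1, 2 * wt + 1)
    out = ndimage.uniform_filter(indicator.astype(np.float32), size=size,
                                 mode="constant", cval=0.0)
    return np.rint(out * np.prod(size)).astype(np.int32)


def _cube_counts(cube: np.ndarray, config: OptimizerConfig):
    """Per-label windowed match counts and bookkeeping arrays."""
    cube = np.asarray(cube)
    labels = sorted(int(v) for v in np.unique(cube) if v != config.nodata)
    label_index = {lab: i for i, lab in enumerate(labels)}
    counts = np.stack([_window_counts(cube == lab, config) for lab in labels])
    valid = cube != config.nodata
    n_valid = _window_counts(valid, config)
    if config.boundary == "fixed":
        n_norm = np.full(cube.shape, np.prod([2 * w + 1 for w in config.window]),
                         dtype=np.int32)
    else:
        n_norm = n_valid
    return labels, label_index, counts, valid, n_valid, n_norm


def homogeneity_probability(cube: np.ndarray, x: int, y: int, t: int,
                            config: OptimizerConfig | None = None,
                            match: str = "exact") -> float:
    """P(x, y, t) for a single pixel-year; match="exact" or "group"."""
    config = config or OptimizerConfig()
    cube = np.asarray(cube)
    center = int(cube[x, y, t])
    if center == config.nodata:
        raise ValueError(f"homogeneity undefined at nodata center ({x},{y},{t})")
    wx, wy, wt = config.window
    win = cube[max(0, x - wx):x + wx + 1,
               max(0, y - wy):y + wy + 1,
               max(0, t - wt):t + wt + 1]
    valid = win != config.nodata
    if config.boundary == "fixed":
        n = int(np.prod([2 * w + 1 for w in config.window]))
    else:
        n = int(valid.sum())
    if match == "exact":
        hits = int((win[valid] == center).sum())
    elif match == "group":
        group = config.groups[config.group_of(center)]
        hits = int(np.isin(win[valid], list(group)).sum())
    else:
        raise ValueError(f"unknown match mode {match!r}")
    return hits / n


def optimize(cube: np.ndarray, config: OptimizerConfig | None = None):
    """Single-pass simultaneous consistency optimization.

    Parameters
    ----------
    cube
        Integer label array of shape (H, W, n_years); ``config.nodata``
        cells are ignored and preserved.

    Returns
    -------
    (optimized cube, change log) — the log is a DataFrame with columns
    row, col, year, old, new, p_exact, p_group, one row per relabel.
    """
    config = config or OptimizerConfig()
    cube = np.asarray(cube)
    labels, label_index, counts, valid, n_valid, n_norm = _cube_counts(cube, config)
    for lab in labels:
        config.group_of(lab)  # raises on uncovered labels

    lab_arr = np.array(labels)
    # index of each cell's own label into the counts stack
    code_to_idx = np.full(int(lab_arr.max()) + 2, -1, dtype=np.int64)
    code_to_idx[lab_arr] = np.arange(len(labels))
    idx_cube = np.where(valid, code_to_idx[np.where(valid, cube, 0)], 0)

    own = np.take_along_axis(counts, idx_cube[None], axis=0)[0]
    group_ids = np.array([config.group_of(lab) for lab in labels])
    gcounts = np.stack([counts[group_ids == gi].sum(axis=0)
                        for gi in range(len(config.groups))])
    own_group = np.take_along_axis(
        gcounts, group_ids[idx_cube][None], axis=0)[0]

    with np.errstate(invalid="ignore", divide="ignore"):
        p_exact = own / n_norm
        p_group = own_group / n_norm

    eligible = valid.copy()
    if config.boundary == "fixed":
        full = np.prod([2 * w + 1 for w in config.window])
        # windows clipped by the cube boundary are not optimized
        eligible &= _window_counts(np.ones_like(cube, dtype=bool), config) == full
    relabel = eligible & (p_exact < config.p_keep) & (p_group <= config.p_group)

    # window-majority label with ties broken by temporal adjacency then
    # lowest code (labels ascend, argmax returns the first maximum)
    majority_idx = np.argmax(counts, axis=0)
    maxcount = np.take_along_axis(counts, majority_idx[None], axis=0)[0]

    def _shifted(offset):
        """(label index, validity, window count) of the label at t+offset."""
        adj = np.zeros(cube.shape, dtype=np.int64)
        adj_valid = np.zeros(cube.shape, bool)
        if offset == -1:
            adj[:, :, 1:] = idx_cube[:, :, :-1]
            adj_valid[:, :, 1:] = valid[:, :, :-1]
        else:
            adj[:, :, :-1] = idx_cube[:, :, 1:]
            adj_valid[:, :, :-1] = valid[:, :, 1:]
        cnt = np.take_along_axis(counts, adj[None], axis=0)[0]
        return adj, adj_valid, cnt

    prev_idx, prev_valid, prev_cnt = _shifted(-1)
    next_idx, next_valid, next_cnt = _shifted(+1)
    prev_pref = prev_valid & (prev_cnt == maxcount)
    next_pref = next_valid & (next_cnt == maxcount) & ~prev_pref
    majority_idx = np.where(prev_pref, prev_idx, majority_idx)
    majority_idx = np.where(next_pref, next_idx, majority_idx)

    new_cube = cube.copy()
    new_cube[relabel] = lab_arr[majority_idx[relabel]]

    changed = relabel & (new_cube != cube)
    rows, cols, years = np.nonzero(changed)
    log = pd.DataFrame({
        "row": rows, "col": cols, "year": years,
        "old": cube[changed], "new": new_cube[changed],
        "p_exact": p_exact[changed], "p_group": p_group[changed],
    })
    return new_cube, log


def count_single_year_flips(cube: np.ndarray, nodata: int = -1) -> int:
    """Number of pixel-years whose label differs from both temporal
    neighbors while those neighbors agree — the one-year flicker the
    optimizer is meant to remove."""
    cube = np.asarray(cube)
    a, b, c = cube[:, :, :-2], cube[:, :, 1:-1], cube[:, :, 2:]
    flips = (a == c) & (b != a) & (a != nodata) & (b != nodata)
    return int(flips.sum())
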