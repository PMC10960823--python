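"""Stratified validation design and error-matrix accuracy metrics.

Two halves:

* **Design** — the classical stratified-sampling size formula

      n = (sum_i W_i sqrt(p_i (1 - p_i)))^2
          / ((d / t)^2 + sum_i W_i p_i (1 - p_i) / N)

  with stratum weights ``W_i``, anticipated per-stratum accuracies ``p_i``,
  confidence multiplier ``t`` (1.96 for 95%), desired half-width ``d`` and
  population size ``N``; per-stratum sizes are allocated proportionally to
  ``W_i p_i (1 - p_i)`` with largest-remainder integer rounding.

* **Assessment** — an :class:`ErrorMatrix` of class *proportions*
  (reference classes as rows, map classes as columns, entries in % of
  area) with overall accuracy, per-class producer's (recall) and user's
  (precision) accuracies, and the chance-corrected Kappa coefficient
  ``(p_o - p_e) / (1 - p_e)``.

Published tables carry independently rounded marginals; when an
:class:`ErrorMatrix` stores such printed totals they are used as the PA/UA
denominators, which avoids compounding the cell rounding.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SamplingDesign:
    """Inputs of the stratified sample-size formula (see module docs)."""

    W: tuple
    p: tuple
    d: float = 0.05
    t: float = 1.96
    N: float = np.inf

    def __post_init__(self):
        W, p = np.asarray(self.W, float), np.asarray(self.p, float)
        if len(W) != len(p):
            raise ValueError("W and p must have equal length")
        if np.any(W < 0) or not np.isclose(W.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("anticipated accuracies must lie in (0, 1)")
        if self.d <= 0:
            raise ValueError("d must be positive")


@dataclass
class SampleAllocation:
    n_real: float
    n: int
    n_i: tuple


def allocate_sample_size(design: SamplingDesign) -> SampleAllocation:
    """Total and per-stratum validation sample sizes.

    Raises on zero total variance (all strata with p in {0, 1} are already
    rejected by the design invariants).
    """
    W = np.asarray(design.W, float)
    p = np.asarray(design.p, float)
    v = p * (1 - p)
    num = (W * np.sqrt(v)).sum() ** 2
    if num == 0:
        raise ValueError("zero variance in every stratum; n undefined")
    den = (design.d / design.t) ** 2
    if np.isfinite(design.N):
        den += (W * v).sum() / design.N
    n_real = num / den
    n = int(round(n_real))
    share = W * v / (W * v).sum()
    quota = n * share
    n_i = np.floor(quota).astype(int)
    rem = quota - n_i
    for i in np.argsort(-rem)[: n - n_i.sum()]:
        n_i[i] += 1
    return SampleAllocation(n_real=n_real, n=n, n_i=tuple(int(x) for x in n_i))


@dataclass
class ErrorMatrix:
    """Square class-proportion confusion matrix (% of area).

    ``proportions[i, j]`` is the estimated percent of area whose reference
    class is ``labels[i]`` and whose map class is ``labels[j]``.  Optional
    ``row_totals``/``col_totals`` hold independently published marginals.
    """

    labels: tuple
    proportions: np.ndarray
    row_totals: np.ndarray | None = None
    col_totals: np.ndarray | None = None

    def __post_init__(self):
        P = np.asarray(self.proportions, dtype=np.float64)
        if P.ndim != 2 or P.shape[0] != P.shape[1] or P.shape[0] != len(self.labels):
            raise ValueError("proportions must be square and match labels")
        if np.any(P < 0):
            raise ValueError("proportions must be nonnegative")
        if abs(P.sum() - 100.0) > 0.05:
            raise ValueError(f"grand total {P.sum():.3f} not within 100 +- 0.05")
        self.proportions = P

    @property
    def _row_tot(self):
        return (np.asarray(self.row_totals, float) if self.row_totals is not None
                else self.proportions.sum(axis=1))

    @property
    def _col_tot(self):
        return (np.asarray(self.col_totals, float) if self.col_totals is not None
                else self.proportions.sum(axis=0))


def build_error_matrix(reference, mapped, labels=None, strata=None,
                       stratum_weights=None) -> ErrorMatrix:
    """Error matrix from paired reference/map labels.

    With *strata* (per-point stratum ids) and *stratum_weights* (mapping
    stratum id -> area weight, summing to 1), each stratum's within-stratum
    confusion proportions are combined with its weight — the standard
    stratified proportion estimator.  Without them, plain counts over the
    pooled points are used.  Entries are percentages summing to 100.
    """
    reference = np.asarray(reference)
    mapped = np.asarray(mapped)
    if reference.shape != mapped.shape:
        raise ValueError("reference and map label arrays differ in length")
    if labels is None:
        labels = tuple(sorted(set(reference.tolist()) | set(mapped.tolist())))
    labels = tuple(labels)
    unknown = (set(reference.tolist()) | set(mapped.tolist())) - set(labels)
    if unknown:
        raise ValueError(f"labels outside the class set: {sorted(unknown)}")
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)

    def counts(ref, mp):
        M = np.zeros((k, k))
        for r, m in zip(ref, mp):
            M[index[r], index[m]] += 1
        return M

    if strata is None:
        M = counts(reference, mapped)
        P = M / M.sum() * 100.0
    else:
        strata = np.asarray(strata)
        P = np.zeros((k, k))
        for s in np.unique(strata):
            sel = strata == s
            Ms = counts(reference[sel], mapped[sel])
            P += stratum_weights[s] * Ms / Ms.sum()
        P *= 100.0
    return ErrorMatrix(labels=labels, proportions=P)


def accuracy_metrics(matrix: ErrorMatrix, stratum_counts=None) -> dict:
    """OA, Kappa, per-class PA/UA (all on the percent scale) and, when
    per-map-class sample counts are supplied, stratified standard errors.

    * OA = trace / grand total; Kappa = (p_o - p_e) / (1 - p_e) with
      p_e = sum_i (row share_i x column share_i).
    * PA_i = diagonal_i / row total_i (producer's, omission view);
      UA_i = diagonal_i / column total_i (user's, commission view).
    * A class with an empty row or column gets NaN PA or UA and is listed
      under ``"undefined"`` rather than silently zeroed.
    * SEs (same % scale): SE(OA) = 100 sqrt(sum_j Wj^2 UAj(1-UAj)/(nj-1))
      with Wj the map-class area share; SE(UA_j) and SE(PA_i) use the
      binomial form with the stratum (column) or effective row sample size.
    """
    P = matrix.proportions
    T = P.sum()
    diag = np.diag(P)
    row = matrix._row_tot
    col = matrix._col_tot
    oa = diag.sum() / T * 100.0
    pe = float((row / T * (col / T)).sum())
    kappa = (oa / 100.0 - pe) / (1.0 - pe)

    undefined = []
    with np.errstate(divide="ignore", invalid="ignore"):
        pa = np.where(row > 0, diag / np.where(row > 0, row, 1) * 100.0, np.nan)
        ua = np.where(col > 0, diag / np.where(col > 0, col, 1) * 100.0, np.nan)
    for i, lab in enumerate(matrix.labels):
        if row[i] == 0 or col[i] == 0:
            undefined.append(lab)

    out = {
        "oa": float(oa), "kappa": float(kappa),
        "pa": dict(zip(matrix.labels, pa.tolist())),
        "ua": dict(zip(matrix.labels, ua.tolist())),
        "undefined": undefined,
    }
    if stratum_counts is not None:
        n_j = np.asarray([stratum_counts[lab] for lab in matrix.labels], float)
        W_j = col / T
        ua_f = ua / 100.0
        var_oa = np.nansum(W_j ** 2 * ua_f * (1 - ua_f) / np.maximum(n_j - 1, 1))
        out["se_oa"] = float(100.0 * np.sqrt(var_oa))
        out["se_ua"] = {
            lab: float(100.0 * np.sqrt(ua_f[j] * (1 - ua_f[j])
                                       / max(n_j[j] - 1, 1)))
            for j, lab in enumerate(matrix.labels)}
        n_total = n_j.sum()
        n_row = np.maximum(row / T * n_total, 2.0)
        pa_f = pa / 100.0
        out["se_pa"] = {
            lab: float(100.0 * np.sqrt(pa_f[i] * (1 - pa_f[i]) / (n_row[i] - 1)))
            for i, lab in enumerate(matrix.labels)}
    return out


def _data_path(name: str):
    return importlib.resources.files("wetmap.data").joinpath(name)


def load_error_matrix_2020() -> ErrorMatrix:
    """The packaged 2020 validation error matrix (9 classes, % of area),
    including its printed row/column totals."""
    with importlib.resources.as_file(_data_path("error_matrix_2020.csv")) as p:
        df = pd.read_csv(p, comment="#")
    body = df[df["class"] != "Total"].set_index("class")
    labels = tuple(body.index)
    P = body[list(labels)].to_numpy(dtype=float)
    row_tot = body["Total"].to_numpy(dtype=float)
    col_tot = (df[df["class"] == "Total"][list(labels)]
               .to_numpy(dtype=float).ravel())
    return ErrorMatrix(labels=labels, proportions=P,
                       row_totals=row_tot, col_totals=col_tot)


def load_validation_design_2020() -> dict:
    """Stratum sizes of the packaged 2020 validation design, reconciled.

    Returns the per-stratum table plus derived totals (wetland points =
    inland + coastal; grand total = wetland + non-wetland).
    """
    with importlib.resources.as_file(_data_path("validation_strata_2020.csv")) as p:
        df = pd.read_csv(p, comment="#")
    counts = dict(zip(df["stratum"], df["count"]))
    wetland = int(df.loc[df["wetland"] == 1, "count"].sum())
    total = int(df["count"].sum())
    return {"strata": counts, "wetland_points": wetland, "total_points": total}
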