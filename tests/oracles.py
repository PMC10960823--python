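"""Independent brute-force reference implementations used only by tests.

These deliberately use naive per-element loops and share no code with the
package's vectorized implementations.
"""

import numpy as np

from wetmap.features import _quantize


def brute_glcm(band, cfg):
    """Per-window double-loop co-occurrence tabulation and statistics."""
    L, win = cfg.levels, cfg.window
    half = win // 2
    q, valid = _quantize(band, L)
    h, w = np.asarray(band).shape
    keys = ("entropy", "contrast", "variance", "homogeneity", "correlation")
    out = {k: np.full((h, w), np.nan) for k in keys}
    for r in range(h):
        for c in range(w):
            P = np.zeros((L, L))
            for rr in range(max(0, r - half), min(h, r + half + 1)):
                for cc in range(max(0, c - half), min(w, c + half + 1)):
                    if not valid[rr, cc]:
                        continue
                    for (dr, dc) in cfg.offsets:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < h and 0 <= c2 < w and valid[r2, c2]:
                            P[q[rr, cc], q[r2, c2]] += 1
                            P[q[r2, c2], q[rr, cc]] += 1
            T = P.sum()
            if T == 0:
                continue
            P /= T
            i, j = np.indices((L, L))
            out["contrast"][r, c] = (P * (i - j) ** 2).sum()
            out["homogeneity"][r, c] = (P / (1 + (i - j) ** 2)).sum()
            nz = P[P > 0]
            out["entropy"][r, c] = -(nz * np.log(nz)).sum()
            mu = (P * i).sum()
            var = (P * (i - mu) ** 2).sum()
            out["variance"][r, c] = var
            cov = (P * (i - mu) * (j - mu)).sum()
            out["correlation"][r, c] = cov / var if var > 1e-12 else 0.0
    return out


def brute_optimize(cube, cfg):
    """Literal per-cell evaluation of the consistency rules."""
    H, W, T = cube.shape
    out = cube.copy()
    wx, wy, wt = cfg.window
    full = (2 * wx + 1) * (2 * wy + 1) * (2 * wt + 1)
    for x in range(H):
        for y in range(W):
            for t in range(T):
                c = cube[x, y, t]
                if c == cfg.nodata:
                    continue
                win = cube[max(0, x - wx):x + wx + 1,
                           max(0, y - wy):y + wy + 1,
                           max(0, t - wt):t + wt + 1]
                if cfg.boundary == "fixed" and win.size < full:
                    continue
                vals = win[win != cfg.nodata]
                n = len(vals) if cfg.boundary == "valid" else full
                p_exact = (vals == c).sum() / n
                group = cfg.groups[cfg.group_of(int(c))]
                p_group = np.isin(vals, list(group)).sum() / n
                if p_exact >= cfg.p_keep or p_group > cfg.p_group:
                    continue
                labs, counts = np.unique(vals, return_counts=True)
                cands = set(labs[counts == counts.max()].tolist())
                if t - 1 >= 0 and cube[x, y, t - 1] != cfg.nodata \
                        and cube[x, y, t - 1] in cands:
                    choice = cube[x, y, t - 1]
                elif t + 1 < T and cube[x, y, t + 1] != cfg.nodata \
                        and cube[x, y, t + 1] in cands:
                    choice = cube[x, y, t + 1]
                else:
                    choice = min(cands)
                out[x, y, t] = choice
    return out


def brute_confusion_metrics(reference, mapped):
    """Direct counting of OA/PA/UA/kappa from paired labels."""
    reference = np.asarray(reference)
    mapped = np.asarray(mapped)
    labels = sorted(set(reference.tolist()) | set(mapped.tolist()))
    n = len(reference)
    oa = (reference == mapped).mean() * 100
    pa = {lab: (mapped[reference == lab] == lab).mean() * 100
          for lab in labels if (reference == lab).any()}
    ua = {lab: (reference[mapped == lab] == lab).mean() * 100
          for lab in labels if (mapped == lab).any()}
    pe = sum((reference == lab).mean() * (mapped == lab).mean() for lab in labels)
    kappa = (oa / 100 - pe) / (1 - pe)
    return oa, kappa, pa, ua
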