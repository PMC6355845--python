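"""Independent brute-force oracles used to check the fast implementations.

Everything here recomputes quantities from raw pixels/values with the
simplest possible code (dicts, double loops), deliberately sharing no code
path with the package.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# exhaustive mutual-best-fitting segmentation
# ---------------------------------------------------------------------------


def _seg_stats(pixels, img):
    """(n, per-band sd, perimeter edges, bbox perimeter) from raw pixels."""
    n = len(pixels)
    vals = np.array([img[r, c] for r, c in pixels], dtype=float)
    sd = vals.std(axis=0)
    e = 0
    pset = set(pixels)
    for r, c in pixels:
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            if (r + dr, c + dc) not in pset:
                e += 1
    rs = [r for r, _ in pixels]
    cs = [c for _, c in pixels]
    bbp = 2 * ((max(rs) - min(rs) + 1) + (max(cs) - min(cs) + 1))
    return n, sd, e, bbp


def _merge_cost(pix_a, pix_b, img, wb, color_weight, compactness_weight):
    na, sda, ea, bba = _seg_stats(pix_a, img)
    nb, sdb, eb, bbb = _seg_stats(pix_b, img)
    nab, sdab, eab, bbab = _seg_stats(pix_a + pix_b, img)
    dh_color = float(np.dot(wb, nab * sdab - na * sda - nb * sdb))
    d_cmpct = np.sqrt(nab) * eab - (np.sqrt(na) * ea + np.sqrt(nb) * eb)
    d_smooth = nab * eab / bbab - na * ea / bba - nb * eb / bbb
    return color_weight * dh_color + (1 - color_weight) * (
        compactness_weight * d_cmpct + (1 - compactness_weight) * d_smooth
    )


def oracle_segment(img, scale, color_weight=0.9, compactness_weight=0.5):
    """Mutual-best-fitting region merging recomputed naively from raw pixels.

    img: (rows, cols) or (rows, cols, bands).  Returns a label array with
    contiguous ids ordered by first pixel occurrence.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        img = img[:, :, None]
    rows, cols, nb = img.shape
    wb = np.full(nb, 1.0 / nb)
    # segment id = minimum pixel linear index among members
    segs = {r * cols + c: [(r, c)] for r in range(rows) for c in range(cols)}

    def neighbours():
        adj = set()
        lab = {}
        for sid, pix in segs.items():
            for p in pix:
                lab[p] = sid
        for (r, c), sid in lab.items():
            for dr, dc in ((0, 1), (1, 0)):
                q = (r + dr, c + dc)
                if q in lab and lab[q] != sid:
                    adj.add((min(sid, lab[q]), max(sid, lab[q])))
        return sorted(adj)

    while True:
        adj = neighbours()
        if not adj:
            break
        costs = {
            (a, b): _merge_cost(segs[a], segs[b], img, wb, color_weight,
                                compactness_weight)
            for a, b in adj
        }
        best = {}
        for sid in segs:
            inc = [(costs[e], e[0] if e[1] == sid else e[1], e)
                   for e in adj if sid in e]
            if inc:
                best[sid] = min(inc)[2]
        merges = [
            e for e in adj
            if best.get(e[0]) == e and best.get(e[1]) == e and costs[e] < scale**2
        ]
        if not merges:
            break
        for a, b in merges:
            segs[a] = segs[a] + segs[b]
            del segs[b]

    labels = np.zeros((rows, cols), dtype=int)
    order = {}
    for r in range(rows):
        for c in range(cols):
            for sid, pix in segs.items():
                if (r, c) in pix:
                    if sid not in order:
                        order[sid] = len(order)
                    labels[r, c] = order[sid]
    return labels


def oracle_lv(img, labels):
    """Local variance: mean over segments of mean per-band standard deviation."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        img = img[:, :, None]
    out = []
    for sid in np.unique(labels):
        vals = img[labels == sid]
        out.append(vals.std(axis=0).mean())
    return float(np.mean(out))


# ---------------------------------------------------------------------------
# GLCM by pair enumeration
# ---------------------------------------------------------------------------


def oracle_glcm_stats(levels_grid, mask, n_levels):
    """Symmetric distance-1 GLCM stats over one segment mask, 4 offsets.

    Returns (homogeneity, entropy, mean) or None if the mask yields no pair.
    """
    g = np.asarray(levels_grid)
    rows, cols = g.shape
    counts = np.zeros((n_levels, n_levels))
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols and mask[r2, c2]:
                    counts[g[r, c], g[r2, c2]] += 1
                    counts[g[r2, c2], g[r, c]] += 1
    total = counts.sum()
    if total == 0:
        return None
    p = counts / total
    i, j = np.meshgrid(np.arange(n_levels), np.arange(n_levels), indexing="ij")
    homog = (p / (1.0 + (i - j) ** 2)).sum()
    nz = p > 0
    entropy = float(-(p[nz] * np.log(p[nz])).sum())
    mean = float((i * p).sum())
    return float(homog), entropy, mean


# ---------------------------------------------------------------------------
# Getis-Ord Gi* by double loop
# ---------------------------------------------------------------------------


def oracle_gi_star(values, band_cells):
    """Gi* Z-scores via the textbook formula, one pair of loops per cell."""
    x = np.asarray(values, dtype=float)
    ny, nx = x.shape
    n = x.size
    xbar = x.mean()
    s = np.sqrt((x**2).sum() / n - xbar**2)
    z = np.zeros_like(x)
    for i in range(ny):
        for j in range(nx):
            wx = 0.0
            w1 = 0.0
            for k in range(ny):
                for m in range(nx):
                    if (i - k) ** 2 + (j - m) ** 2 <= band_cells**2:
                        wx += x[k, m]
                        w1 += 1.0
            denom = s * np.sqrt((n * w1 - w1**2) / (n - 1))
            z[i, j] = (wx - xbar * w1) / denom
    return z


# ---------------------------------------------------------------------------
# confusion-matrix metrics by per-class tally
# ---------------------------------------------------------------------------


def oracle_metrics(y_true, y_pred, codes):
    """Metric bundle from explicit one-vs-rest tallies."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    n = len(y_true)
    overall = sum(t == p for t, p in zip(y_true, y_pred)) / n
    precs, recs, accs = [], [], []
    tp_all = fp_all = fn_all = 0
    for c in codes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        tn = n - tp - fp - fn
        precs.append(tp / (tp + fp) if tp + fp else 0.0)
        recs.append(tp / (tp + fn) if tp + fn else 0.0)
        accs.append((tp + tn) / n)
        tp_all += tp
        fp_all += fp
        fn_all += fn
    return {
        "overall_accuracy": overall,
        "average_accuracy": float(np.mean(accs)),
        "micro_precision": tp_all / (tp_all + fp_all),
        "macro_precision": float(np.mean(precs)),
        "micro_recall": tp_all / (tp_all + fn_all),
        "macro_recall": float(np.mean(recs)),
    }
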