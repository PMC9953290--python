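"""Independent brute-force oracles used to verify the package's statistics.

Everything here is deliberately written with plain loops and first
principles, sharing no code path with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def diet_indices_oracle(stomachs: list[dict], n_examined: int) -> dict:
    """Brute-force %F/%N/%W/IRI/%IRI.

    ``stomachs`` is a list of {taxon: (count, weight)} dicts, one per
    non-empty stomach; ``n_examined`` is the %F denominator.
    """
    taxa = sorted({t for st in stomachs for t in st})
    occ = {t: sum(1 for st in stomachs if t in st) for t in taxa}
    cnt = {t: sum(st[t][0] for st in stomachs if t in st) for t in taxa}
    wgt = {t: sum(st[t][1] for st in stomachs if t in st) for t in taxa}
    c_tot = sum(cnt.values())
    w_tot = sum(wgt.values())
    out = {}
    for t in taxa:
        f = occ[t] * 100.0 / n_examined
        n = cnt[t] * 100.0 / c_tot
        w = wgt[t] * 100.0 / w_tot
        out[t] = {"F": f, "N": n, "W": w, "IRI": (n + w) * f}
    iri_sum = sum(v["IRI"] for v in out.values())
    for v in out.values():
        v["IRI_pct"] = v["IRI"] * 100.0 / iri_sum
    return out


def shannon_oracle(counts) -> float:
    total = sum(counts)
    return -sum((c / total) * math.log(c / total) for c in counts if c > 0)


def bray_curtis_oracle(a, b) -> float:
    num = sum(abs(x - y) for x, y in zip(a, b))
    den = sum(x + y for x, y in zip(a, b))
    return num / den


def hull_area_oracle(points: np.ndarray) -> float:
    """O(n^3) convex hull area: find directed hull edges by the all-points-
    on-the-left test, walk them into a polygon, apply the shoelace formula."""
    pts = [tuple(p) for p in np.asarray(points, dtype=float)]
    uniq = sorted(set(pts))
    n = len(uniq)
    if n < 3:
        return 0.0
    edges = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ax, ay = uniq[i]
            bx, by = uniq[j]
            left = True
            strict = False
            for k in range(n):
                if k in (i, j):
                    continue
                cx, cy = uniq[k]
                cross = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
                if cross < -1e-12:
                    left = False
                    break
                if cross > 1e-12:
                    strict = True
            if left and strict:
                edges[uniq[i]] = uniq[j]
    if not edges:
        return 0.0  # collinear
    start = next(iter(edges))
    poly = [start]
    cur = edges[start]
    while cur != start:
        poly.append(cur)
        cur = edges[cur]
    area = 0.0
    for (x1, y1), (x2, y2) in zip(poly, poly[1:] + poly[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def layman_oracle(points: np.ndarray) -> dict:
    """Double-loop Layman metrics."""
    p = np.asarray(points, dtype=float)
    n = len(p)
    nr = max(p[:, 1]) - min(p[:, 1])
    cr = max(p[:, 0]) - min(p[:, 0])
    cx = sum(p[:, 0]) / n
    cy = sum(p[:, 1]) / n
    cd = sum(math.hypot(x - cx, y - cy) for x, y in p) / n
    nnd = []
    for i in range(n):
        best = math.inf
        for j in range(n):
            if i != j:
                d = math.hypot(p[i, 0] - p[j, 0], p[i, 1] - p[j, 1])
                best = min(best, d)
        nnd.append(best)
    mnnd = sum(nnd) / n
    sdnnd = math.sqrt(sum((d - mnnd) ** 2 for d in nnd) / n)
    return {"NR": nr, "CR": cr, "CD": cd, "MNND": mnnd, "SDNND": sdnnd}


def pearson_oracle(x, y) -> float:
    """Pearson r from explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
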