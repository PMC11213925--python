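"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths (and where possible the libraries)
used by the package: polygon moments come from a triangle-fan decomposition
instead of shoelace edge sums, convex hulls from scipy instead of shapely,
rank statistics from explicit O(n^2) pair loops, and summary statistics from
plain Python loops.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import ConvexHull


# ---------------------------------------------------------------------------
# polygon shape descriptors via triangle-fan decomposition


def _triangle_moments(p0, p1, p2):
    """(area, Sx, Sy, Sxx, Syy, Sxy) integrals over one triangle."""
    x = np.array([p0[0], p1[0], p2[0]])
    y = np.array([p0[1], p1[1], p2[1]])
    a = 0.5 * ((x[1] - x[0]) * (y[2] - y[0]) - (x[2] - x[0]) * (y[1] - y[0]))
    cx, cy = x.mean(), y.mean()
    # second moments about the origin for a triangle (exact closed form)
    sxx = a / 6.0 * (x[0] ** 2 + x[1] ** 2 + x[2] ** 2 + x[0] * x[1] + x[1] * x[2] + x[0] * x[2])
    syy = a / 6.0 * (y[0] ** 2 + y[1] ** 2 + y[2] ** 2 + y[0] * y[1] + y[1] * y[2] + y[0] * y[2])
    sxy = a / 12.0 * (
        x[0] * (2 * y[0] + y[1] + y[2])
        + x[1] * (y[0] + 2 * y[1] + y[2])
        + x[2] * (y[0] + y[1] + 2 * y[2])
    )
    return a, a * cx, a * cy, sxx, syy, sxy


def brute_shape_descriptor(contour, mpp=0.5):
    """The 13 shape descriptors, computed along an independent route."""
    v = np.asarray(contour, dtype=float)
    v = v - v.mean(axis=0)  # local frame: descriptors are translation-invariant
    area = sx = sy = sxx = syy = sxy = 0.0
    for i in range(1, len(v) - 1):
        a, tx, ty, txx, tyy, txy = _triangle_moments(v[0], v[i], v[i + 1])
        area += a
        sx += tx
        sy += ty
        sxx += txx
        syy += tyy
        sxy += txy
    sign = 1.0 if area >= 0 else -1.0
    area, sx, sy, sxx, syy, sxy = (sign * q for q in (area, sx, sy, sxx, syy, sxy))
    cx, cy = sx / area, sy / area
    mu20 = sxx / area - cx * cx  # x-variance
    mu02 = syy / area - cy * cy
    mu11 = sxy / area - cx * cy
    common = math.sqrt(4 * mu11 ** 2 + (mu20 - mu02) ** 2)
    lam1 = (mu20 + mu02 + common) / 2
    lam2 = min(max((mu20 * mu02 - mu11 ** 2) / lam1, 0.0), lam1) if lam1 > 0 else 0.0
    ecc = math.sqrt(1 - lam2 / lam1) if lam1 > 0 else 0.0
    orient = 0.5 * math.atan2(2 * mu11, mu20 - mu02)

    hull_area = ConvexHull(v).volume  # 2-D hull "volume" is its area
    per = sum(
        math.dist(v[i], v[(i + 1) % len(v)]) for i in range(len(v))
    )
    xmin, ymin = v.min(axis=0)
    xmax, ymax = v.max(axis=0)
    bw, bh = xmax - xmin, ymax - ymin
    radius = float(np.mean([math.dist(p, (cx, cy)) for p in v]))
    a2 = mpp * mpp
    return {
        "eccentricity": min(ecc, np.nextafter(1.0, 0.0)),
        "convex_area": hull_area * a2,
        "contour_area": area * a2,
        "extent": area / (bw * bh),
        "perimeter": per * mpp,
        "solidity": area / hull_area,
        "orientation": orient,
        "radius": radius * mpp,
        "major_axis": 4 * math.sqrt(lam1) * mpp,
        "minor_axis": 4 * math.sqrt(lam2) * mpp,
        "equivalent_diameter": math.sqrt(4 * area / math.pi) * mpp,
        "bbox_area": bw * bh * a2,
        "bbox_aspect_ratio": bw / bh,
    }


# ---------------------------------------------------------------------------
# spatial / aggregation oracles


def brute_neighbor_counts(centroids, class_idx, radii=(100, 200, 300, 400)):
    n = len(centroids)
    counts = np.zeros((n, 2, len(radii)), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = math.dist(centroids[i], centroids[j])
            for ri, r in enumerate(radii):
                if d <= r:
                    counts[i, class_idx[j], ri] += 1
    return counts


def _four_stats(values):
    if not values:
        return [0.0, 0.0, 0.0, 0.0]
    mean = sum(values) / len(values)
    var = sum((v - mean) ** 2 for v in values) / len(values)
    return [mean, min(values), max(values), math.sqrt(var)]


def brute_tile_vector(nuclei, mpp=0.5):
    """Independent assembly of the full 168-element tile feature vector."""
    shape_order = [
        "eccentricity", "convex_area", "contour_area", "extent", "perimeter",
        "solidity", "orientation", "radius", "major_axis", "minor_axis",
        "equivalent_diameter", "bbox_area", "bbox_aspect_ratio",
    ]
    cls = [1 if n.model_class.value == "other" else 0 for n in nuclei]
    descs = [brute_shape_descriptor(n.contour, mpp) for n in nuclei]
    out = []
    for c in (0, 1):
        mine = [d for d, k in zip(descs, cls) if k == c]
        for name in shape_order:
            out.extend(_four_stats([d[name] for d in mine]))
    cents = [n.centroid for n in nuclei]
    counts = brute_neighbor_counts(cents, cls)
    for ref in (0, 1):
        for nbr in (0, 1):
            refs = [i for i, k in enumerate(cls) if k == ref]
            for ri in range(4):
                out.extend(_four_stats([float(counts[i, nbr, ri]) for i in refs]))
    return np.array(out)


def brute_top_k(probs, k):
    """Top-k indices by probability, ties broken by lowest index."""
    decorated = sorted(enumerate(probs), key=lambda t: (-t[1], t[0]))
    return [i for i, _ in decorated[: min(k, len(probs))]]


def brute_auroc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_concordance(scores, times, events):
    """Harrell's C by explicit pair enumeration (higher score = higher risk)."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i must have the earlier observed event
            if events[i] == 1 and (times[i] < times[j] or (times[i] == times[j] and events[j] == 0)):
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def brute_bh(pvals):
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(pvals[i] * m / rank_from_top, prev)
        adj[i] = val
        prev = val
    return adj


def brute_kaplan_meier(times, events):
    """Hand product-limit estimate: list of (time, survival) at event times."""
    pts = sorted(zip(times, events))
    s = 1.0
    out = []
    distinct = sorted({t for t, e in pts if e == 1})
    for t in distinct:
        at_risk = sum(1 for ti, _ in pts if ti >= t)
        d = sum(1 for ti, ei in pts if ti == t and ei == 1)
        s *= 1 - d / at_risk
        out.append((t, s))
    return out
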