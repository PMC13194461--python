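"""Independent brute-force oracles shared by the unit and acceptance suites.

Each oracle implements its quantity by direct enumeration or elementary
arithmetic, never by calling the code path it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# ----------------------------------------------------------------------
# minimum enclosing circle: O(M^3) search over point pairs and triples
# ----------------------------------------------------------------------

def _circle_from_two(a, b):
    center = (a + b) / 2.0
    return center, float(np.linalg.norm(a - center))


def _circle_from_three(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(a - center))


def brute_force_mec(points):
    """Smallest circle through some pair or triple that encloses all points."""
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    if n == 1:
        return pts[0], 0.0
    best = None
    tol = 1e-9 * max(1.0, np.abs(pts).max())
    for i, j in combinations(range(n), 2):
        center, r = _circle_from_two(pts[i], pts[j])
        if np.all(np.linalg.norm(pts - center, axis=1) <= r + tol):
            if best is None or r < best[1]:
                best = (center, r)
    if best is not None:
        return best
    for i, j, k in combinations(range(n), 3):
        circ = _circle_from_three(pts[i], pts[j], pts[k])
        if circ is None:
            continue
        center, r = circ
        if np.all(np.linalg.norm(pts - center, axis=1) <= r + tol):
            if best is None or r < best[1]:
                best = (center, r)
    return best


# ----------------------------------------------------------------------
# quadratic DBSCAN (classical label-propagation algorithm, all-pairs)
# ----------------------------------------------------------------------

def brute_force_dbscan(points, eps, min_samples):
    """Classical DBSCAN by BFS over all-pairs neighborhoods.

    Matches sklearn's semantics: ``min_samples`` counts the point itself;
    clusters are numbered by first-core-point index order; border points
    join the first cluster whose expansion reaches them.
    Returns ``(labels, core mask)``.
    """
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    neighbors = [np.flatnonzero(dist[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neighbors])
    labels = np.full(n, -1, dtype=np.int64)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        queue = [i]
        labels[i] = cluster
        while queue:
            p = queue.pop(0)
            if not core[p]:
                continue
            for q in neighbors[p]:
                if labels[q] == -1:
                    labels[q] = cluster
                    queue.append(q)
        cluster += 1
    return labels, core


# ----------------------------------------------------------------------
# misc small oracles
# ----------------------------------------------------------------------

def triangle_area_cross(p0, p1, p2):
    """Half cross-product magnitude."""
    p0, p1, p2 = (np.asarray(p, dtype=np.float64) for p in (p0, p1, p2))
    if p0.size == 2:
        p0, p1, p2 = (np.append(p, 0.0) for p in (p0, p1, p2))
    return 0.5 * float(np.linalg.norm(np.cross(p1 - p0, p2 - p0)))


def confusion_tally(pred, true, n_classes):
    """Per-class TP/FP/FN by an explicit loop over points."""
    tp = np.zeros(n_classes, dtype=int)
    fp = np.zeros(n_classes, dtype=int)
    fn = np.zeros(n_classes, dtype=int)
    for p, t in zip(pred, true):
        if p == t:
            tp[p] += 1
        else:
            fp[p] += 1
            fn[t] += 1
    return tp, fp, fn


def direct_conv1d(x, w, b):
    """Same-length zero-padded 1D convolution by explicit loops."""
    m, cin = x.shape
    k, _, cout = w.shape
    half = k // 2
    out = np.zeros((m, cout))
    for i in range(m):
        for t in range(k):
            j = i + t - half
            if 0 <= j < m:
                out[i] += x[j] @ w[t]
    return out + b


def partitions_equal(labels_a, labels_b):
    """True when two labelings induce the same partition (noise = -1 fixed)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if not np.array_equal(labels_a == -1, labels_b == -1):
        return False
    mapping = {}
    for a, b in zip(labels_a, labels_b):
        if a == -1:
            continue
        if a in mapping and mapping[a] != b:
            return False
        mapping[a] = b
    return len(set(mapping.values())) == len(mapping)
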