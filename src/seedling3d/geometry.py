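"""Geometric primitives: RANSAC plane fitting, Rodrigues rotations,
Welzl's minimum enclosing circle, Heron's formula, and outlier removal.

These primitives back both the preprocessing stage (ground detection and
alignment) and the trait estimators (stem diameter, cotyledon inclination).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class PlaneModel:
    """Plane ``normal . p = d`` with RANSAC inlier statistics."""

    normal: np.ndarray
    d: float
    inlier_count: int
    inlier_fraction: float

    def distances(self, points: np.ndarray) -> np.ndarray:
        return np.abs(points @ self.normal - self.d)


class DegenerateGeometryError(ValueError):
    """Raised when the input has no well-defined fit (e.g. collinear points)."""


# ----------------------------------------------------------------------
# plane fitting
# ----------------------------------------------------------------------

def _orient(normal: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: positive z, then y, then x component."""
    for i in (2, 1, 0):
        if abs(normal[i]) > 1e-12:
            return normal if normal[i] > 0 else -normal
    return normal


def _pca_plane(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear; no unique plane")
    return vt[2]


def fit_plane_ransac(
    points: np.ndarray,
    iters: int = 1000,
    dist_threshold: float = 0.05,
    seed: int = 0,
    refine: bool = True,
) -> PlaneModel:
    """RANSAC plane fit: random 3-point hypotheses scored by inlier count.

    The winning hypothesis is optionally refined by a total-least-squares
    (PCA) fit on its inliers.  The returned normal is unit length and
    oriented with a non-negative z component.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    n = points.shape[0]
    if n < 3:
        raise ValueError("plane fitting needs at least 3 points")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(iters, 3))
    p0, p1, p2 = points[idx[:, 0]], points[idx[:, 1]], points[idx[:, 2]]
    normals = np.cross(p1 - p0, p2 - p0)
    norms = np.linalg.norm(normals, axis=1)
    valid = norms > 1e-12
    if not np.any(valid):
        raise DegenerateGeometryError("all sampled triplets were collinear")
    normals = normals[valid] / norms[valid, None]
    offsets = np.einsum("ij,ij->i", normals, p0[valid])

    best_count, best = -1, 0
    # score hypotheses in chunks to bound memory on large scenes
    chunk = max(1, int(5e6) // max(n, 1))
    for start in range(0, normals.shape[0], chunk):
        sl = slice(start, start + chunk)
        dist = np.abs(points @ normals[sl].T - offsets[sl])
        counts = np.sum(dist <= dist_threshold, axis=0)
        j = int(np.argmax(counts))
        if counts[j] > best_count:
            best_count = int(counts[j])
            best = start + j

    normal, d = normals[best], offsets[best]
    inlier = np.abs(points @ normal - d) <= dist_threshold
    if refine and int(inlier.sum()) >= 3:
        try:
            refined = _pca_plane(points[inlier])
            refined_d = float(points[inlier].mean(axis=0) @ refined)
            new_inlier = np.abs(points @ refined - refined_d) <= dist_threshold
            if int(new_inlier.sum()) >= best_count:
                normal, d, inlier = refined, refined_d, new_inlier
        except DegenerateGeometryError:
            pass
    normal = _orient(normal)
    d = float(points[inlier].mean(axis=0) @ normal) if inlier.any() else float(d)
    count = int(inlier.sum())
    return PlaneModel(normal=normal, d=d, inlier_count=count,
                      inlier_fraction=count / n)


# ----------------------------------------------------------------------
# rotations
# ----------------------------------------------------------------------

def rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for a unit axis and angle (Rodrigues' formula)."""
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix R with R @ a parallel to b (both unit vectors).

    The anti-parallel case is resolved by a 180-degree turn about a fixed
    perpendicular axis (x when possible, else y) for determinism.
    """
    a = np.asarray(a, np.float64) / np.linalg.norm(a)
    b = np.asarray(b, np.float64) / np.linalg.norm(b)
    c = float(np.dot(a, b))
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        perp = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(a, perp)) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        perp = perp - np.dot(perp, a) * a
        return rodrigues(perp, np.pi)
    return rodrigues(axis / s, float(np.arctan2(s, c)))


def rot_axis(axis: str, deg: float) -> np.ndarray:
    """Rotation about a coordinate axis, angle in degrees."""
    unit = {"x": (1, 0, 0), "y": (0, 1, 0), "z": (0, 0, 1)}[axis.lower()]
    return rodrigues(np.asarray(unit, dtype=np.float64), np.deg2rad(deg))


# ----------------------------------------------------------------------
# minimum enclosing circle (Welzl, move-to-front, expected linear)
# ----------------------------------------------------------------------

_MEC_EPS = 1e-9


def _circumcircle(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    det = 2.0 * ((bx - ax) * (cy - ay) - (by - ay) * (cx - ax))
    if abs(det) < 1e-14:
        return None
    b2 = (bx - ax) ** 2 + (by - ay) ** 2
    c2 = (cx - ax) ** 2 + (cy - ay) ** 2
    ux = ax + (b2 * (cy - ay) - c2 * (by - ay)) / det
    uy = ay + (c2 * (bx - ax) - b2 * (cx - ax)) / det
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(center - np.asarray(a)))


def _two_point(a, b):
    center = (np.asarray(a) + np.asarray(b)) / 2.0
    return center, float(np.linalg.norm(np.asarray(a) - center))


def _inside(circle, p, scale) -> bool:
    center, r = circle
    return float(np.linalg.norm(np.asarray(p) - center)) <= r + _MEC_EPS * scale


def min_enclosing_circle(points2d: np.ndarray, seed: int = 0):
    """Smallest circle enclosing all 2D points; returns ``(center, radius)``.

    Welzl's randomized incremental algorithm with move-to-front processing;
    expected linear time.  Every input point lies inside or on the returned
    circle to a relative 1e-9.
    """
    pts = np.asarray(points2d, dtype=np.float64).reshape(-1, 2)
    n = pts.shape[0]
    if n == 0:
        raise ValueError("minimum enclosing circle of an empty set")
    if n == 1:
        return pts[0].copy(), 0.0
    scale = max(1.0, float(np.abs(pts).max()))
    rng = np.random.default_rng(seed)
    pts = pts[rng.permutation(n)]

    circle = _two_point(pts[0], pts[1])
    for i in range(2, n):
        if _inside(circle, pts[i], scale):
            continue
        # pts[i] is on the boundary of the new circle
        circle = _two_point(pts[i], pts[0])
        for j in range(1, i):
            if _inside(circle, pts[j], scale):
                continue
            circle = _two_point(pts[i], pts[j])
            for k in range(j):
                if _inside(circle, pts[k], scale):
                    continue
                cc = _circumcircle(pts[i], pts[j], pts[k])
                if cc is None:
                    # collinear support: diameter circle of the farthest pair
                    trio = np.array([pts[i], pts[j], pts[k]])
                    d = np.linalg.norm(trio[:, None] - trio[None, :], axis=-1)
                    a, b = np.unravel_index(np.argmax(d), d.shape)
                    cc = _two_point(trio[a], trio[b])
                circle = cc
    return circle[0], circle[1]


# ----------------------------------------------------------------------
# Heron's formula
# ----------------------------------------------------------------------

def heron_area(a: float, b: float, c: float) -> float:
    """Triangle area from side lengths, numerically stabilized.

    Near-degenerate triangles return 0; a gross triangle-inequality
    violation (beyond 1e-6 relative) raises ``ValueError``.
    """
    a, b, c = float(a), float(b), float(c)
    if min(a, b, c) < 0:
        raise ValueError("side lengths must be non-negative")
    peri = a + b + c
    tol = 1e-6 * max(peri, 1e-300)
    if 2.0 * max(a, b, c) > peri + tol:
        raise ValueError(f"sides ({a}, {b}, {c}) violate the triangle inequality")
    s = 0.5 * peri
    return float(np.sqrt(max(0.0, s * (s - a) * (s - b) * (s - c))))


def triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Heron areas of an indexed triangle set (vectorized)."""
    v = np.asarray(vertices, dtype=np.float64)
    f = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    a = np.linalg.norm(v[f[:, 1]] - v[f[:, 0]], axis=1)
    b = np.linalg.norm(v[f[:, 2]] - v[f[:, 1]], axis=1)
    c = np.linalg.norm(v[f[:, 0]] - v[f[:, 2]], axis=1)
    s = 0.5 * (a + b + c)
    return np.sqrt(np.maximum(0.0, s * (s - a) * (s - b) * (s - c)))


# ----------------------------------------------------------------------
# statistical outlier removal
# ----------------------------------------------------------------------

def statistical_outlier_mask(
    points: np.ndarray, k: int = 8, std_ratio: float = 2.0
) -> np.ndarray:
    """Boolean mask of points whose mean k-NN distance is within
    ``mean + std_ratio * std`` of the population (True = keep)."""
    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    if n <= k:
        return np.ones(n, dtype=bool)
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=k + 1)
    mean_d = dist[:, 1:].mean(axis=1)
    return mean_d <= mean_d.mean() + std_ratio * mean_d.std()
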