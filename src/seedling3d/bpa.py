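"""Ball-pivoting surface reconstruction (BPA).

A virtual ball of fixed radius rolls over the point cloud: starting from a
seed triangle whose circumscribing ball of that radius contains no other
point, the ball pivots around each front edge until it touches a new
point, forming one triangle per contact.  The resulting triangle set (each
triangle counted once) feeds the surface-area estimator.

The implementation keeps an advancing front of directed edges, evaluates
all pivot candidates of an edge vectorized, picks the smallest rotation
angle whose ball is empty, and restarts from fresh seeds until no seed
triangle remains.  Vertex normals, when supplied, orient the seed balls to
the outer side of the surface.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


class MeshFailure(RuntimeError):
    """No seed triangle found (radius unsuited to the sampling density)."""


def _tri_key(i, j, k):
    return tuple(sorted((int(i), int(j), int(k))))


def _edge_key(i, j):
    return (int(i), int(j)) if i < j else (int(j), int(i))


def _candidate_centers(e0, e1, cand, radius):
    """Ball centers of radius ``radius`` through edge (e0, e1) and each
    candidate; returns (centers+, centers-, valid mask, triangle normals)."""
    u = e1 - e0
    uu = float(u @ u)
    v = cand - e0
    uv = v @ u
    vv = np.einsum("ij,ij->i", v, v)
    det = uu * vv - uv * uv
    valid = det > 1e-18
    det_safe = np.where(valid, det, 1.0)
    s = 0.5 * (uu * vv - vv * uv) / det_safe
    t = 0.5 * (uu * vv - uu * uv) / det_safe
    cc = e0 + s[:, None] * u + t[:, None] * v
    rc2 = np.einsum("ij,ij->i", cc - e0, cc - e0)
    h2 = radius * radius - rc2
    valid &= h2 >= 0.0
    n = np.empty_like(v)
    n[:, 0] = u[1] * v[:, 2] - u[2] * v[:, 1]
    n[:, 1] = u[2] * v[:, 0] - u[0] * v[:, 2]
    n[:, 2] = u[0] * v[:, 1] - u[1] * v[:, 0]
    nn = np.sqrt(np.einsum("ij,ij->i", n, n))
    valid &= nn > 1e-14
    n = n / np.where(nn > 1e-14, nn, 1.0)[:, None]
    h = np.sqrt(np.maximum(h2, 0.0))
    return cc + h[:, None] * n, cc - h[:, None] * n, valid, n


def _rotation_angles(axis_u, m, c_old, centers):
    """Signed rotation angle (0, 2pi) of each center around the edge axis."""
    v0 = c_old - m
    v0 = v0 - (v0 @ axis_u) * axis_u
    v = centers - m
    v = v - np.outer(v @ axis_u, axis_u)
    cross = np.empty_like(v)
    cross[:, 0] = v0[1] * v[:, 2] - v0[2] * v[:, 1]
    cross[:, 1] = v0[2] * v[:, 0] - v0[0] * v[:, 2]
    cross[:, 2] = v0[0] * v[:, 1] - v0[1] * v[:, 0]
    sin = cross @ axis_u
    cos = v @ v0
    ang = np.arctan2(sin, cos)
    ang = np.where(ang <= 1e-9, ang + 2.0 * np.pi, ang)
    return ang


class BallPivoter:
    """Advancing-front ball pivoting over one point cloud."""

    def __init__(self, points, normals=None, radius: float = 0.2):
        self.points = np.asarray(points, dtype=np.float64)
        if self.points.shape[0] < 3:
            raise ValueError("ball pivoting needs at least 3 points")
        self.normals = None if normals is None else np.asarray(normals, float)
        self.radius = float(radius)
        self.tree = cKDTree(self.points)
        n = self.points.shape[0]
        k = min(n, 48)
        dist, idx = self.tree.query(self.points, k=k)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        idx = idx.astype(np.int64)
        idx[dist > 2.0 * self.radius] = -1
        self._nbrs = idx                 # per-point candidates within 2r
        self.triangles: set = set()
        self.edge_count: dict = {}
        self.front: list = []            # (i, j, opposite, ball center)
        self.in_mesh = np.zeros(self.points.shape[0], dtype=bool)

    # -- geometry helpers -------------------------------------------------
    def _ball_empty(self, center, touching) -> bool:
        inside = self.tree.query_ball_point(center, self.radius * (1.0 - 1e-7))
        return all(i in touching for i in inside)

    def _side_ok(self, center, idx3) -> bool:
        """Require the ball on the outer (normal) side of the triangle.

        Keeps thin sheets single-sided: without this, the ball also rolls
        over the back face and doubles the estimated area.
        """
        if self.normals is None:
            return True
        tri = self.points[list(idx3)]
        ref = self.normals[list(idx3)].sum(axis=0)
        if np.linalg.norm(ref) < 1e-9:
            return True
        return float((center - tri.mean(axis=0)) @ ref) > 0.0

    # -- seeding ----------------------------------------------------------
    def _try_seed(self, i) -> bool:
        neigh = self._nbrs[i]
        neigh = neigh[(neigh >= 0) & (neigh != i)][:10]
        if neigh.size < 2:
            return False
        shrunk = self.radius * (1.0 - 1e-7)
        for a_pos, j in enumerate(neigh):
            cand = neigh[a_pos + 1:]
            if cand.size == 0:
                continue
            cp, cm, valid, n = _candidate_centers(
                self.points[i], self.points[j], self.points[cand], self.radius
            )
            if self.normals is not None:
                ref = self.normals[i] + self.normals[int(j)]
                centers = np.where(((n @ ref) >= 0)[:, None], cp, cm)
                both = (centers,)
            else:
                both = (cp, cm)
            for centers in both:
                sel = np.flatnonzero(valid)
                if sel.size == 0:
                    continue
                hits = self.tree.query_ball_point(centers[sel], shrunk)
                for k_pos, inside in zip(sel, hits):
                    k = int(cand[k_pos])
                    if set(inside) <= {int(i), int(j), k}:
                        self._add_triangle(int(i), int(j), k, centers[k_pos])
                        return True
        return False

    # -- front management --------------------------------------------------
    def _add_triangle(self, i, j, k, center) -> None:
        key = _tri_key(i, j, k)
        if key in self.triangles:
            return
        self.triangles.add(key)
        self.in_mesh[[i, j, k]] = True
        for a, b, opp in ((i, j, k), (j, k, i), (k, i, j)):
            ek = _edge_key(a, b)
            self.edge_count[ek] = self.edge_count.get(ek, 0) + 1
            if self.edge_count[ek] == 1:
                self.front.append((a, b, opp, center))

    def _pivot(self, a, b, opp, c_old):
        pa, pb = self.points[a], self.points[b]
        m = 0.5 * (pa + pb)
        axis = pb - pa
        axis_len = np.linalg.norm(axis)
        if axis_len < 1e-12:
            return None
        axis_u = axis / axis_len
        # roll away from the existing triangle: pick the rotation sense whose
        # initial center velocity points away from the opposite vertex
        v0 = c_old - m
        v0p = v0 - (v0 @ axis_u) * axis_u
        away = self.points[opp] - m
        if np.dot(np.cross(axis_u, v0p), away) > 0:
            axis_u = -axis_u
        cand = np.unique(np.concatenate([self._nbrs[a], self._nbrs[b]]))
        cand = cand[(cand >= 0) & (cand != a) & (cand != b) & (cand != opp)]
        if cand.size == 0:
            return None
        cp, cm, valid, _ = _candidate_centers(
            pa, pb, self.points[cand], self.radius
        )
        centers = np.concatenate([cp, cm])
        cand2 = np.concatenate([cand, cand])
        valid2 = np.concatenate([valid, valid])
        ang = _rotation_angles(axis_u, m, c_old, centers)
        ang[~valid2] = np.inf
        order = np.argsort(ang)
        # the first contact of the rolling ball is empty by construction;
        # the side test keeps thin sheets single-sided
        for pos in order[:8]:
            if not np.isfinite(ang[pos]):
                break
            x = int(cand2[pos])
            if _tri_key(a, b, x) in self.triangles:
                continue
            if self._side_ok(centers[pos], (a, b, x)):
                return x, centers[pos]
        return None

    # -- main loop ----------------------------------------------------------
    def run(self, max_triangles: int = 200000):
        pending = iter(range(self.points.shape[0]))
        while True:
            while self.front:
                a, b, opp, center = self.front.pop()
                if self.edge_count.get(_edge_key(a, b), 0) >= 2:
                    continue
                hit = self._pivot(a, b, opp, center)
                if hit is not None:
                    self._add_triangle(a, b, hit[0], hit[1])
                    if len(self.triangles) >= max_triangles:
                        return self._faces()
            seeded = False
            for i in pending:
                if not self.in_mesh[i] and self._try_seed(i):
                    seeded = True
                    break
            if not seeded:
                return self._faces()

    def _faces(self) -> np.ndarray:
        if not self.triangles:
            raise MeshFailure(
                f"no triangles at radius {self.radius} "
                f"(unsuited to sampling density)"
            )
        return np.array(sorted(self.triangles), dtype=np.int64)


def ball_pivot_mesh(points, normals=None, radius: float = 0.2,
                    max_points: int | None = None, seed: int = 0) -> np.ndarray:
    """Faces (T x 3 indices into ``points``) of the ball-pivoting mesh.

    ``max_points`` optionally subsamples dense clouds before meshing (a
    pure speed measure; the pivoting radius controls the geometry).
    """
    points = np.asarray(points, dtype=np.float64)
    index = np.arange(points.shape[0])
    if max_points is not None and points.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        index = np.sort(rng.choice(points.shape[0], max_points, replace=False))
        points = points[index]
        normals = None if normals is None else np.asarray(normals)[index]
    faces = BallPivoter(points, normals, radius).run()
    return index[faces]
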