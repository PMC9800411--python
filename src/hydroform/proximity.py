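"""Exact closest-point-on-surface queries for triangle meshes.

Correspondence search is exact: for every query point the returned point is
the true nearest point on the target surface, found by pruning candidate
triangles with a k-d tree and evaluating exact point-to-triangle distances
on the survivors.  Nearest-vertex snapping is deliberately avoided — at
scan-resolution meshes it biases distances upward by a sizeable fraction of
the edge length.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import MeshGeometryError

__all__ = ["ClosestPointQuery", "closest_point_on_triangles"]

# barycentric coordinates below this are treated as lying on the
# corresponding triangle boundary feature (edge or vertex)
_FEATURE_EPS = 1e-9


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray):
    """Exact closest point on each (point, triangle) pair.

    Parameters
    ----------
    points : (n, 3) float array
    triangles : (n, 3, 3) float array, one triangle per point

    Returns
    -------
    closest : (n, 3) closest points
    bary : (n, 3) barycentric coordinates of the closest points
    """
    points = np.asarray(points, dtype=np.float64)
    triangles = np.asarray(triangles, dtype=np.float64)
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]

    ab = b - a
    ac = c - a
    ap = points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)

    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)

    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    n = len(points)
    bary = np.empty((n, 3), dtype=np.float64)

    # face interior (lowest priority, overwritten by edge/vertex cases)
    denom = va + vb + vc
    safe = np.where(denom == 0.0, 1.0, denom)
    v = vb / safe
    w = vc / safe
    bary[:, 0] = 1.0 - v - w
    bary[:, 1] = v
    bary[:, 2] = w

    def _set(mask, u_, v_, w_):
        bary[mask, 0] = u_ if np.isscalar(u_) else u_[mask]
        bary[mask, 1] = v_ if np.isscalar(v_) else v_[mask]
        bary[mask, 2] = w_ if np.isscalar(w_) else w_[mask]

    # edge BC
    m = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    den = (d4 - d3) + (d5 - d6)
    t = np.where(den != 0, (d4 - d3) / np.where(den == 0, 1.0, den), 0.0)
    _set(m, 0.0, 1.0 - t, t)

    # edge AC
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    den = d2 - d6
    t = np.where(den != 0, d2 / np.where(den == 0, 1.0, den), 0.0)
    _set(m, 1.0 - t, 0.0, t)

    # edge AB
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    den = d1 - d3
    t = np.where(den != 0, d1 / np.where(den == 0, 1.0, den), 0.0)
    _set(m, 1.0 - t, t, 0.0)

    # vertices (highest priority)
    _set((d6 >= 0) & (d5 <= d6), 0.0, 0.0, 1.0)
    _set((d3 >= 0) & (d4 <= d3), 0.0, 1.0, 0.0)
    _set((d1 <= 0) & (d2 <= 0), 1.0, 0.0, 0.0)

    closest = np.einsum("ij,ijk->ik", bary, triangles)
    return closest, bary


class ClosestPointQuery:
    """Accelerated exact closest-point queries against one triangle mesh.

    Zero-area triangles are excluded from correspondence.  An optional
    ``face_ids`` restricts the target surface to a sub-patch; boundary
    features are then those of the sub-patch.
    """

    def __init__(self, mesh, face_ids=None):
        faces = np.asarray(mesh.faces)
        if face_ids is not None:
            face_ids = np.sort(np.asarray(face_ids, dtype=np.int64))
            faces = faces[face_ids]
        if len(faces) == 0:
            raise MeshGeometryError("target surface has no faces")
        vertices = np.asarray(mesh.vertices, dtype=np.float64)
        tri = vertices[faces]

        # drop degenerate (zero-area) triangles
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        keep = areas > 1e-14
        if not keep.any():
            raise MeshGeometryError("target surface has only degenerate faces")
        self._orig_ids = (
            np.flatnonzero(keep) if face_ids is None else face_ids[keep]
        )
        faces = faces[keep]
        tri = tri[keep]

        self._mesh = mesh
        self._faces = faces
        self.triangles = tri
        self.centroids = tri.mean(axis=1)
        self._radii = np.linalg.norm(tri - self.centroids[:, None, :], axis=2).max(axis=1)
        self._rmax = float(self._radii.max())
        self._ctree = cKDTree(self.centroids)
        self._vtree = cKDTree(tri.reshape(-1, 3))

        # boundary features of the (possibly restricted) target surface
        edges = np.sort(
            np.concatenate([faces[:, [1, 2]], faces[:, [2, 0]], faces[:, [0, 1]]]),
            axis=1,
        )
        uniq, inv, counts = np.unique(edges, axis=0, return_inverse=True, return_counts=True)
        # edge k of face f is the edge opposite local vertex k
        self._edge_is_boundary = (counts[inv] == 1).reshape(3, -1).T
        bnd_vertices = np.unique(uniq[counts == 1])
        self._vertex_is_boundary = np.zeros(len(vertices), dtype=bool)
        self._vertex_is_boundary[bnd_vertices] = True

    # ------------------------------------------------------------------
    def query(self, points, chunk_size=16384):
        """Exact nearest point on the surface for each query point.

        Returns ``(closest, distance, face_id, bary)`` where ``face_id``
        indexes the original mesh faces and ties (points equidistant from
        several triangles) resolve to the lowest face index.
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        n = len(points)
        closest = np.empty((n, 3))
        dist = np.empty(n)
        tri_id = np.empty(n, dtype=np.int64)
        bary = np.empty((n, 3))
        for lo in range(0, n, chunk_size):
            hi = min(lo + chunk_size, n)
            self._query_chunk(points[lo:hi], closest[lo:hi], dist[lo:hi],
                              tri_id[lo:hi], bary[lo:hi])
        return closest, dist, self._orig_ids[tri_id], bary

    def _query_chunk(self, pts, out_cp, out_d, out_tid, out_bary):
        # upper bound on the surface distance: distance to the nearest
        # triangle vertex (which lies on the surface)
        d_ub, _ = self._vtree.query(pts)
        # any triangle containing the true closest point has a point within
        # d_ub of the query, so its centroid is within d_ub + rmax
        lists = self._ctree.query_ball_point(pts, d_ub + self._rmax + 1e-12)
        counts = np.fromiter((len(l) for l in lists), dtype=np.int64, count=len(lists))
        flat_tri = np.concatenate([np.sort(l) for l in lists]) if len(lists) else np.empty(0, np.int64)
        flat_pt = np.repeat(np.arange(len(pts)), counts)

        cp, bc = closest_point_on_triangles(pts[flat_pt], self.triangles[flat_tri])
        d = np.linalg.norm(cp - pts[flat_pt], axis=1)

        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        dmin = np.minimum.reduceat(d, starts)
        is_min = d == dmin[flat_pt]
        cand = np.flatnonzero(is_min)
        # first (lowest face index, since each list is sorted) winner per point
        _, first = np.unique(flat_pt[cand], return_index=True)
        sel = cand[first]

        out_cp[:] = cp[sel]
        out_d[:] = d[sel]
        out_tid[:] = flat_tri[sel]
        out_bary[:] = bc[sel]

    # ------------------------------------------------------------------
    def on_boundary(self, tri_id, bary):
        """Whether closest points lie on a boundary feature of the surface.

        ``tri_id`` are original-mesh face ids as returned by :meth:`query`.
        """
        local = np.searchsorted(self._orig_ids, tri_id)
        # map through sorted original ids (orig ids are strictly increasing)
        near_zero = np.asarray(bary) <= _FEATURE_EPS
        n_zero = near_zero.sum(axis=1)
        out = np.zeros(len(local), dtype=bool)

        # on an edge: exactly one barycentric coordinate vanishes; the edge
        # is the one opposite that vertex
        on_edge = n_zero == 1
        if on_edge.any():
            k = np.argmax(near_zero[on_edge], axis=1)
            out[on_edge] = self._edge_is_boundary[local[on_edge], k]

        # at a vertex: two coordinates vanish
        on_vertex = n_zero == 2
        if on_vertex.any():
            k = np.argmin(near_zero[on_vertex], axis=1)  # the surviving vertex
            vids = self._faces[local[on_vertex], k]
            out[on_vertex] = self._vertex_is_boundary[vids]
        return out

    def interpolated_normals(self, tri_id, bary):
        """Area-weighted vertex normals of the target, interpolated at the
        closest points and renormalised; used for point-to-plane residuals."""
        local = np.searchsorted(self._orig_ids, tri_id)
        vn = np.asarray(self._mesh.vertex_normals, dtype=np.float64)
        normals = np.einsum("ij,ijk->ik", bary, vn[self._faces[local]])
        norm = np.linalg.norm(normals, axis=1, keepdims=True)
        degenerate = norm[:, 0] < 1e-12
        if degenerate.any():
            fn = np.asarray(self._mesh.face_normals, dtype=np.float64)
            normals[degenerate] = fn[np.asarray(tri_id)[degenerate]]
            norm = np.linalg.norm(normals, axis=1, keepdims=True)
        return normals / np.maximum(norm, 1e-300)
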