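"""Exact closest-point queries on triangle meshes.

The correspondence step of the robust ICP engine needs, for every sampled
point, the exact nearest point on the reference surface. Queries are
accelerated with two KD-trees (vertices for an upper bound, triangle
centroids for candidate gathering) but are guaranteed to return the same
face and distance as an exhaustive scan over all triangles: every triangle
whose minimum distance could beat the current bound has its centroid within
``bound + max_triangle_circumradius`` of the query and is therefore examined.

Ties (a query equidistant from several faces, e.g. on a shared edge) are
broken toward the lowest face id so results are deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["closest_point_on_triangles", "ClosestPointQuery"]


def closest_point_on_triangles(points, tri_a, tri_b, tri_c):
    """Closest point on each triangle (a, b, c) to each query point.

    All arguments are (n, 3) arrays (one triangle per query row). Returns the
    (n, 3) array of closest points. Vectorised form of the classic
    barycentric-region case analysis.
    """
    p = np.asarray(points, float)
    a = np.asarray(tri_a, float)
    b = np.asarray(tri_b, float)
    c = np.asarray(tri_c, float)

    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m

    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m

    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1[m] - d3[m]
    v = np.where(denom != 0, d1[m] / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = a[m] + v[:, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2[m] - d6[m]
    w = np.where(denom != 0, d2[m] / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = a[m] + w[:, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4[m] - d3[m]) + (d5[m] - d6[m])
    w = np.where(denom != 0, (d4[m] - d3[m]) / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = b[m] + w[:, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va[m] + vb[m] + vc[m]
    denom = np.where(denom == 0, 1.0, denom)
    v = vb[m] / denom
    w = vc[m] / denom
    out[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    return out


class ClosestPointQuery:
    """Accelerated exact point-to-mesh closest point queries.

    Parameters
    ----------
    vertices, faces : arrays
        Triangle mesh in mm. Face ids reported by :meth:`query` index into
        ``faces`` as given (useful when querying a submesh of a region mask).
    """

    def __init__(self, vertices, faces):
        self.vertices = np.asarray(vertices, float)
        self.faces = np.asarray(faces, int)
        if len(self.faces) == 0:
            raise ValueError("mesh has no faces")
        self._tri = self.vertices[self.faces]  # (m, 3, 3)
        self._centroids = self._tri.mean(axis=1)
        self._circum = np.linalg.norm(
            self._tri - self._centroids[:, None, :], axis=2
        ).max(axis=1)
        self._rmax = float(self._circum.max())
        # upper bound must come from vertices actually used by faces
        used = np.unique(self.faces)
        self._vtree = cKDTree(self.vertices[used])
        self._ctree = cKDTree(self._centroids)
        self._boundary_faces = self._find_boundary_faces()

    def _find_boundary_faces(self) -> np.ndarray:
        f = self.faces
        edges = np.sort(
            np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
        )
        _, inv, counts = np.unique(
            edges, axis=0, return_inverse=True, return_counts=True
        )
        # records are ordered [all e01, all e12, all e20]
        edge_is_boundary = counts[inv] == 1
        e01, e12, e20 = np.split(edge_is_boundary, 3)
        return e01 | e12 | e20

    @property
    def boundary_faces(self) -> np.ndarray:
        """Boolean mask: face has at least one boundary (unshared) edge."""
        return self._boundary_faces

    def query(self, points, batch: int = 8192):
        """Return (closest points, face ids, distances) for each query point."""
        pts = np.atleast_2d(np.asarray(points, float))
        n = len(pts)
        out_pts = np.empty((n, 3))
        out_fid = np.empty(n, dtype=int)
        out_dist = np.empty(n)
        for s in range(0, n, batch):
            sl = slice(s, min(s + batch, n))
            self._query_batch(pts[sl], out_pts[sl], out_fid[sl], out_dist[sl])
        if np.asarray(points).ndim == 1:
            return out_pts[0], int(out_fid[0]), float(out_dist[0])
        return out_pts, out_fid, out_dist

    def _query_batch(self, pts, out_pts, out_fid, out_dist):
        # upper bound: nearest vertex, tightened with a few nearest centroids
        d_ub, _ = self._vtree.query(pts)
        k = min(8, len(self._centroids))
        _, cid = self._ctree.query(pts, k=k)
        cid = np.atleast_2d(cid)
        qi = np.repeat(np.arange(len(pts)), cid.shape[1])
        fi = cid.ravel()
        cp = closest_point_on_triangles(
            pts[qi], self._tri[fi, 0], self._tri[fi, 1], self._tri[fi, 2]
        )
        d = np.linalg.norm(pts[qi] - cp, axis=1)
        np.minimum.at(d_ub, qi, d)

        # gather all triangles that could possibly be closer than the bound
        radii = d_ub + self._rmax + 1e-12
        cand = self._ctree.query_ball_point(pts, radii)
        lens = np.fromiter((len(c) for c in cand), dtype=int, count=len(pts))
        qi = np.repeat(np.arange(len(pts)), lens)
        fi = np.fromiter(
            (f for sub in cand for f in sub), dtype=int, count=int(lens.sum())
        )
        cp = closest_point_on_triangles(
            pts[qi], self._tri[fi, 0], self._tri[fi, 1], self._tri[fi, 2]
        )
        d = np.linalg.norm(pts[qi] - cp, axis=1)

        # per-query argmin with lowest-face-id tie break
        order = np.lexsort((fi, d, qi))
        qi_s = qi[order]
        first = np.ones(len(qi_s), dtype=bool)
        first[1:] = qi_s[1:] != qi_s[:-1]
        sel = order[first]
        which = qi_s[first]
        out_pts[which] = cp[sel]
        out_fid[which] = fi[sel]
        out_dist[which] = d[sel]
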