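"""Exact closest-point-on-surface queries for triangle meshes.

A cKDTree over vertices (plus one over triangle centroids) proposes candidate
triangles; the exact closest point on each candidate is then computed with the
standard barycentric region classification, fully vectorised.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["SurfaceQuery", "closest_point_on_triangles"]


def closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point to ``p[i]`` on triangle ``tri[i]`` for every i.

    Parameters: ``p`` (n, 3) query points, ``tri`` (n, 3, 3) triangle corners.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
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

    def assign(mask, value):
        m = mask & ~done
        if m.any():
            out[m] = value[m] if value.ndim == 2 else value
            done[m] = True

    # vertex regions
    assign((d1 <= 0) & (d2 <= 0), a)
    assign((d3 >= 0) & (d4 <= d3), b)
    assign((d6 >= 0) & (d5 <= d6), c)

    # edge AB
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)

    # edge AC
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)

    # edge BC
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))

    # interior
    if not done.all():
        denom = va + vb + vc
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(denom != 0, vb / denom, 1.0 / 3.0)
            w = np.where(denom != 0, vc / denom, 1.0 / 3.0)
        inner = a + v[:, None] * ab + w[:, None] * ac
        out[~done] = inner[~done]
    return out


class SurfaceQuery:
    """Closest point on a triangle mesh for batches of query points."""

    def __init__(self, mesh, n_vertex_candidates: int = 6, n_face_candidates: int = 6):
        self.vertices = np.asarray(mesh.vertices, dtype=float)
        self.faces = np.asarray(mesh.faces, dtype=np.int64)
        if len(self.faces) == 0:
            raise ValueError("mesh has no faces")
        self.triangles = self.vertices[self.faces]
        self._kv = min(n_vertex_candidates, len(self.vertices))
        self._kf = min(n_face_candidates, len(self.faces))
        self._vtree = cKDTree(self.vertices)
        self._ftree = cKDTree(self.triangles.mean(axis=1))
        # vertex -> incident faces, padded to fixed width for vectorised lookup
        counts = np.bincount(self.faces.ravel(), minlength=len(self.vertices))
        order = np.argsort(self.faces.ravel(), kind="stable")
        adj_faces = order // 3
        starts = np.concatenate([[0], np.cumsum(counts)])
        width = int(counts.max())
        padded = np.zeros((len(self.vertices), width), dtype=np.int64)
        for v in range(len(self.vertices)):
            row = adj_faces[starts[v]:starts[v + 1]]
            padded[v, :len(row)] = row
            padded[v, len(row):] = row[0] if len(row) else 0
        self._vertex_faces = padded

    def candidate_faces(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (query_index, face_index) candidate pairs (may repeat)."""
        _, vidx = self._vtree.query(points, k=self._kv)
        vidx = np.atleast_2d(vidx)
        _, fidx = self._ftree.query(points, k=self._kf)
        fidx = np.atleast_2d(fidx)
        cand = np.concatenate(
            [self._vertex_faces[vidx].reshape(len(points), -1), fidx], axis=1)
        n, width = cand.shape
        q_idx = np.repeat(np.arange(n), width)
        return q_idx, cand.ravel()

    def closest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Closest surface points and distances for ``points`` (m, 3)."""
        P = np.asarray(points, dtype=float)
        single = P.ndim == 1
        P = np.atleast_2d(P)
        q_idx, f_idx = self.candidate_faces(P)
        cand = closest_point_on_triangles(P[q_idx], self.triangles[f_idx])
        d2 = ((cand - P[q_idx]) ** 2).sum(axis=1)
        order = np.lexsort((d2, q_idx))
        _, first = np.unique(q_idx[order], return_index=True)
        best = order[first]
        closest = cand[best]
        dist = np.sqrt(d2[best])
        if single:
            return closest[0], dist[0]
        return closest, dist

    def closest_with_faces(self, points: np.ndarray):
        """As :meth:`closest` but also return the supporting face index and
        barycentric weights of each closest point (used for sliding landmarks)."""
        P = np.atleast_2d(np.asarray(points, dtype=float))
        q_idx, f_idx = self.candidate_faces(P)
        cand = closest_point_on_triangles(P[q_idx], self.triangles[f_idx])
        d2 = ((cand - P[q_idx]) ** 2).sum(axis=1)
        order = np.lexsort((d2, q_idx))
        _, first = np.unique(q_idx[order], return_index=True)
        best = order[first]
        faces = f_idx[best]
        pts = cand[best]
        bary = _barycentric(pts, self.triangles[faces])
        return pts, np.sqrt(d2[best]), faces, bary


def _barycentric(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    v0, v1, v2 = b - a, c - a, p - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    u = 1.0 - v - w
    out = np.stack([u, v, w], axis=1)
    return np.clip(out, 0.0, 1.0) / np.clip(out, 0.0, 1.0).sum(axis=1, keepdims=True)
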