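"""Segment/triangle intersection and point-in-mesh queries.

Vectorized Möller–Trumbore over all triangles; meshes in this pipeline
are small (thousands of faces), so brute-force vectorization beats the
bookkeeping of a spatial index.
"""

from __future__ import annotations

import numpy as np

from .core import TriangleMesh

__all__ = ["MeshIntersector", "contains_points"]


class MeshIntersector:
    """Ray and segment queries against a fixed triangle soup."""

    def __init__(self, mesh: TriangleMesh):
        tri = mesh.vertices[mesh.triangles]
        self.v0 = tri[:, 0]
        self.e1 = tri[:, 1] - tri[:, 0]
        self.e2 = tri[:, 2] - tri[:, 0]

    def _hit_params(self, origin: np.ndarray, direction: np.ndarray):
        pvec = np.cross(direction, self.e2)
        det = np.einsum("ij,ij->i", self.e1, pvec)
        ok = np.abs(det) > 1e-12
        inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = origin - self.v0
        u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
        qvec = np.cross(tvec, self.e1)
        v = (qvec @ direction) * inv_det
        t = np.einsum("ij,ij->i", self.e2, qvec) * inv_det
        inside = ok & (u >= 0) & (v >= 0) & (u + v <= 1)
        return t, inside

    def first_hit(self, origin, direction, length, eps=1e-9):
        """Distance to the first triangle hit in (eps, length], or None."""
        t, inside = self._hit_params(np.asarray(origin), np.asarray(direction))
        hit = inside & (t > eps) & (t <= length)
        if not hit.any():
            return None
        return float(t[hit].min())

    def count_hits(self, origin, direction, eps=1e-9) -> int:
        t, inside = self._hit_params(np.asarray(origin), np.asarray(direction))
        return int(np.count_nonzero(inside & (t > eps)))


def contains_points(mesh: TriangleMesh, points: np.ndarray) -> np.ndarray:
    """Ray-parity inside test for a closed mesh (odd crossings = inside).

    A fixed irrational ray direction avoids edge/vertex grazing for the
    lattice-aligned meshes produced by marching cubes.
    """
    intersector = MeshIntersector(mesh)
    direction = np.array([0.57735027, 0.68041382, 0.45141874])
    direction /= np.linalg.norm(direction)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return np.array(
        [intersector.count_hits(p, direction) % 2 == 1 for p in pts]
    )
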