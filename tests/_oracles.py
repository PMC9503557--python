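"""Independent brute-force oracles used only by the test suite.

The point-to-triangle distance here is derived differently from the
package's Voronoi-region implementation: project onto the triangle
plane and test barycentric feasibility, else fall back to the minimum
over the three edge segments.  The surface distance oracle then simply
scans every triangle.
"""

import numpy as np


def _segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    d = b - a
    denom = float(d @ d)
    t = 0.0 if denom == 0 else np.clip(float((p - a) @ d) / denom, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * d)))


def point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> float:
    a, b, c = tri
    e1, e2 = b - a, c - a
    n = np.cross(e1, e2)
    nn = float(n @ n)
    if nn > 0:
        # barycentric coordinates of the in-plane projection
        w = p - a
        g11, g12, g22 = float(e1 @ e1), float(e1 @ e2), float(e2 @ e2)
        r1, r2 = float(w @ e1), float(w @ e2)
        det = g11 * g22 - g12 * g12
        if det > 0:
            u = (g22 * r1 - g12 * r2) / det
            v = (g11 * r2 - g12 * r1) / det
            if u >= 0 and v >= 0 and u + v <= 1:
                return abs(float(w @ n)) / np.sqrt(nn)
    return min(
        _segment_distance(p, a, b),
        _segment_distance(p, b, c),
        _segment_distance(p, c, a),
    )


def unsigned_surface_distance(points: np.ndarray, mesh) -> np.ndarray:
    """Exhaustive min-over-all-triangles unsigned distance per point."""
    tri = mesh.vertices[mesh.faces]
    out = np.empty(len(points))
    for i, p in enumerate(points):
        out[i] = min(point_triangle_distance(p, t) for t in tri)
    return out
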