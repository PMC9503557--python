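"""Signed inter-surface distance maps.

The map lives on the vertices of the query surface (in this pipeline:
the pre-operative simulation) and records, per vertex, the exact
Euclidean distance to the closest point anywhere on the reference
triangle set (the post-operative scan) — face interior, edge or vertex,
never a nearest-vertex shortcut.  Sign follows the angle-weighted
pseudo-normal of the closest feature: positive means the query vertex
lies on the outward-normal side of the reference surface.

Vertices whose closest reference point falls on an open boundary of the
reference (the ~200-degree scan rim) are flagged invalid, as are
vertices removed later by artifact trimming; invalid vertices are
excluded from every downstream statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._closest import TriangleSetDistance
from .mesh_io import TriangleMesh

logger = logging.getLogger(__name__)


class EmptyRegionError(ValueError):
    """No valid values remain for a statistic."""


@dataclass
class DistanceMap:
    """Per-vertex signed distances (mm) on a host mesh, with validity."""

    mesh: TriangleMesh
    distances: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64).reshape(-1)
        self.valid = np.asarray(self.valid, dtype=bool).reshape(-1)
        if len(self.distances) != self.mesh.n_vertices or len(self.valid) != len(
            self.distances
        ):
            raise ValueError("distance/validity arrays must match the host mesh")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def values(self) -> np.ndarray:
        """The valid signed distances."""
        return self.distances[self.valid]

    def flipped(self) -> "DistanceMap":
        """Same map with the sign convention reversed."""
        return DistanceMap(self.mesh, -self.distances, self.valid.copy())


def signed_distance_map(
    query: TriangleMesh,
    reference: TriangleMesh,
    invalidate_boundary: bool = True,
    flip_sign: bool = False,
) -> DistanceMap:
    """Signed distance from each ``query`` vertex to the ``reference`` surface.

    Both meshes must already be co-registered.  ``flip_sign`` reverses
    the convention (useful to report "actual tissue beyond prediction"
    as positive when the reference is the scan).
    """
    reference.check()
    query.check()
    engine = TriangleSetDistance(reference.vertices, reference.faces)
    signed, _, on_boundary = engine.query(query.vertices)
    valid = ~on_boundary if invalidate_boundary else np.ones(len(signed), dtype=bool)
    if flip_sign:
        signed = -signed
    n_rim = int(on_boundary.sum())
    if invalidate_boundary and n_rim:
        logger.info("flagged %d vertex(es) projecting onto the reference rim", n_rim)
    return DistanceMap(query, signed, valid)


def densify(mesh: TriangleMesh) -> TriangleMesh:
    """One round of midpoint (1-to-4) subdivision, for coarse query meshes."""
    v, f = mesh.vertices, mesh.faces
    edge_mid: dict = {}
    new_v = [v]
    next_idx = len(v)

    def mid(i: int, j: int) -> int:
        nonlocal next_idx
        key = (min(i, j), max(i, j))
        if key not in edge_mid:
            edge_mid[key] = next_idx
            new_v.append(((v[key[0]] + v[key[1]]) / 2.0).reshape(1, 3))
            next_idx += 1
        return edge_mid[key]

    faces = []
    for a, b, c in f:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
    return TriangleMesh(np.vstack(new_v), np.array(faces, dtype=np.int64))


def trim_artifacts(
    dmap: DistanceMap, method: str = "robust", k_or_cut: float = 6.0
) -> DistanceMap:
    """Mask out artifact vertices (stand-in for manual artifact removal).

    ``robust``: invalidate where ``|d - median| > k * MAD`` (median and
    MAD over the currently valid values; default k = 6).
    ``absolute``: invalidate where ``|d| > cut`` (mm).

    Distance values are retained; only the validity mask changes.
    """
    if dmap.n_valid == 0:
        raise EmptyRegionError("distance map has no valid vertices to trim")
    d = dmap.distances
    valid = dmap.valid.copy()
    if method == "robust":
        vals = d[valid]
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        outlier = np.abs(d - med) > k_or_cut * mad
    elif method == "absolute":
        outlier = np.abs(d) > k_or_cut
    else:
        raise ValueError(f"unknown trim method {method!r}")
    trimmed = valid & outlier
    n = int(trimmed.sum())
    if n:
        logger.info("trimmed %d artifact vertex(es) (%s rule)", n, method)
    valid &= ~outlier
    if not valid.any():
        raise EmptyRegionError("artifact trimming removed every valid vertex")
    return DistanceMap(dmap.mesh, d.copy(), valid)


def _diverging_colours(values: np.ndarray, scale: tuple[float, float]) -> np.ndarray:
    """Map signed values to RGB via a diverging colour map centred at 0."""
    from matplotlib import colormaps
    from matplotlib.colors import TwoSlopeNorm

    lo, hi = scale
    if not (lo < 0.0 < hi):
        raise ValueError("colour scale must straddle 0 (diverging map)")
    norm = TwoSlopeNorm(vmin=lo, vcenter=0.0, vmax=hi)
    rgba = colormaps["coolwarm"](norm(np.clip(values, lo, hi)))
    return (rgba[:, :3] * 255).astype(np.uint8)


def export_colour_map(
    dmap: DistanceMap, path, scale: tuple[float, float] = (-2.0, 2.0)
) -> None:
    """Write a colour-coded error map as ASCII PLY.

    Each vertex carries its RGB colour (diverging map centred at zero),
    the raw signed distance as a float property and its validity flag,
    so viewers show the error map and the scalars survive a round trip.
    """
    mesh, d = dmap.mesh, dmap.distances
    rgb = _diverging_colours(d, scale)
    lines = [
        "ply",
        "format ascii 1.0",
        "comment signed inter-surface distance map (mm)",
        f"element vertex {mesh.n_vertices}",
        "property float x",
        "property float y",
        "property float z",
        "property uchar red",
        "property uchar green",
        "property uchar blue",
        "property float signed_distance",
        "property uchar valid",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v, c, dist, ok in zip(mesh.vertices, rgb, d, dmap.valid):
        lines.append(
            f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {c[0]} {c[1]} {c[2]} "
            f"{dist:.9g} {int(ok)}"
        )
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_colour_map(path) -> DistanceMap:
    """Re-read a PLY written by :func:`export_colour_map`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != "ply":
        raise ValueError(f"{path}: not a PLY file")
    n_v = n_f = 0
    header_end = 0
    for i, line in enumerate(lines):
        if line.startswith("element vertex"):
            n_v = int(line.split()[-1])
        elif line.startswith("element face"):
            n_f = int(line.split()[-1])
        elif line == "end_header":
            header_end = i + 1
            break
    verts = np.empty((n_v, 3))
    dists = np.empty(n_v)
    valid = np.empty(n_v, dtype=bool)
    for i in range(n_v):
        parts = lines[header_end + i].split()
        verts[i] = [float(x) for x in parts[:3]]
        dists[i] = float(parts[6])
        valid[i] = bool(int(parts[7]))
    faces = np.empty((n_f, 3), dtype=np.int64)
    for i in range(n_f):
        faces[i] = [int(x) for x in lines[header_end + n_v + i].split()[1:4]]
    return DistanceMap(TriangleMesh(verts, faces), dists, valid)
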