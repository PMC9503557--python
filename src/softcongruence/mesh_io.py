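"""Triangle-mesh and landmark I/O.

Surfaces travel as STL files (the export format of both the planning
software and the stereophotogrammetry scanner).  STL stores independent
triangles, so every read welds duplicate vertices back into a shared
vertex set; all downstream geometry assumes welded meshes.  Landmarks
travel in a JSON sidecar because STL cannot carry points.

Units are millimetres throughout the package.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import trimesh

logger = logging.getLogger(__name__)

#: Vertices closer than this (mm) are merged when welding STL soup.
WELD_TOLERANCE = 1e-6
#: Faces with area below this (mm^2) are reported/dropped as degenerate.
DEGENERATE_AREA_FLOOR = 1e-12

#: Landmark roles.  The three RPS roles carry the axis each point group
#: chiefly controls during superimposition; ANCHOR marks segmentation
#: anchors that take no part in the rigid fit.
ROLE_ANTERO_POSTERIOR = "ANTERO_POSTERIOR"
ROLE_ZYGOMATIC = "ZYGOMATIC"
ROLE_ORBITAL = "ORBITAL"
ROLE_ANCHOR = "ANCHOR"
LANDMARK_ROLES = frozenset(
    {ROLE_ANTERO_POSTERIOR, ROLE_ZYGOMATIC, ROLE_ORBITAL, ROLE_ANCHOR}
)

#: Required multiplicities for a reference-point-system set: 3 antero-
#: posterior (glabella/nasion/cranial nose), 4 zygomatic, 8 orbital-rim.
RPS_ROLE_COUNTS = {
    ROLE_ANTERO_POSTERIOR: 3,
    ROLE_ZYGOMATIC: 4,
    ROLE_ORBITAL: 8,
}
RPS_SIZE = 15


class MeshFormatError(ValueError):
    """Malformed STL or landmark file."""


class MeshValidationError(ValueError):
    """Mesh violates a geometric invariant."""


class LandmarkError(ValueError):
    """Landmark set violates naming/role/coordinate invariants."""


@dataclass
class TriangleMesh:
    """A welded triangle surface in millimetres.

    Attributes
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    normals : optional (n, 3) per-vertex unit normals
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def check(self) -> None:
        """Raise :class:`MeshValidationError` on broken invariants."""
        if self.n_vertices == 0 or self.n_faces == 0:
            raise MeshValidationError("mesh is empty")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshValidationError("non-finite vertex coordinates")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= self.n_vertices:
            raise MeshValidationError("face index out of range")

    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.normals is None else self.normals.copy(),
        )


@dataclass
class Landmark:
    name: str
    role: str
    point: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=np.float64).reshape(3)


@dataclass
class LandmarkSet:
    """Ordered, named, role-tagged 3D points on one surface."""

    entries: list[Landmark] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise LandmarkError(f"duplicate landmark names: {dupes}")
        for e in self.entries:
            if e.role not in LANDMARK_ROLES:
                raise LandmarkError(f"unknown role {e.role!r} for landmark {e.name!r}")
            if not np.all(np.isfinite(e.point)):
                raise LandmarkError(f"non-finite coordinate for landmark {e.name!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def points(self) -> np.ndarray:
        return np.array([e.point for e in self.entries], dtype=np.float64).reshape(-1, 3)

    def get(self, name: str) -> np.ndarray:
        for e in self.entries:
            if e.name == name:
                return e.point
        raise LandmarkError(f"missing landmark {name!r}")

    def has(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    def subset_by_role(self, roles: Iterable[str]) -> "LandmarkSet":
        roles = set(roles)
        return LandmarkSet([e for e in self.entries if e.role in roles])

    def rps_subset(self) -> "LandmarkSet":
        """The 15-point reference-point-system subset, validated."""
        sub = self.subset_by_role(RPS_ROLE_COUNTS)
        sub.check_rps()
        return sub

    def check_rps(self) -> None:
        """Validate as a reference-point-system set: 15 points, 3/4/8 roles."""
        counts = {r: 0 for r in RPS_ROLE_COUNTS}
        for e in self.entries:
            if e.role not in RPS_ROLE_COUNTS:
                raise LandmarkError(
                    f"role {e.role!r} not allowed in an RPS set ({e.name!r})"
                )
            counts[e.role] += 1
        if len(self) != RPS_SIZE or counts != RPS_ROLE_COUNTS:
            raise LandmarkError(
                "an RPS set needs exactly 15 landmarks "
                f"(3 antero-posterior, 4 zygomatic, 8 orbital); got {len(self)} "
                f"with role counts {counts}"
            )

    def check_paired(self, other: "LandmarkSet") -> None:
        if self.names != other.names:
            raise LandmarkError(
                "landmark sets used together must share an identical ordered "
                f"name list; got {self.names} vs {other.names}"
            )


@dataclass
class ValidationReport:
    """Findings from :func:`validate_mesh`."""

    nonfinite_vertices: np.ndarray
    out_of_range_faces: np.ndarray
    degenerate_faces: np.ndarray

    @property
    def clean(self) -> bool:
        return (
            len(self.nonfinite_vertices) == 0
            and len(self.out_of_range_faces) == 0
            and len(self.degenerate_faces) == 0
        )


def _weld(mesh: trimesh.Trimesh) -> TriangleMesh:
    mesh.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=9)
    return TriangleMesh(np.asarray(mesh.vertices), np.asarray(mesh.faces))


def read_stl(path: str | Path) -> TriangleMesh:
    """Read a binary or ASCII STL file into a welded :class:`TriangleMesh`.

    STL stores each triangle with its own three vertex records; vertices
    that coincide within the weld tolerance are merged so faces share
    vertices.  The triangle count is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = trimesh.load_mesh(path, file_type="stl", process=False)
    except Exception as exc:  # trimesh raises a zoo of types on bad input
        size = path.stat().st_size
        raise MeshFormatError(
            f"{path}: malformed STL (file size {size} bytes): {exc}"
        ) from exc
    if not isinstance(raw, trimesh.Trimesh) or len(raw.faces) == 0:
        raise MeshFormatError(f"{path}: STL contains no triangles")
    out = _weld(raw)
    out.check()
    return out


def write_stl(mesh: TriangleMesh, path: str | Path, dialect: str = "binary") -> None:
    """Write ``mesh`` as STL; ``dialect`` is ``"binary"`` or ``"ascii"``."""
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    mesh.check()
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    file_type = "stl" if dialect == "binary" else "stl_ascii"
    data = trimesh.exchange.export.export_mesh(tm, None, file_type=file_type)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def binary_stl_triangle_count(path: str | Path) -> int:
    """The triangle-count field of a binary STL header (bytes 80..84)."""
    with open(path, "rb") as fh:
        header = fh.read(84)
    if len(header) < 84:
        raise MeshFormatError(f"{path}: binary STL truncated at byte {len(header)}")
    return struct.unpack("<I", header[80:84])[0]


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark sidecar: ``{"landmarks": [{"name", "role", "xyz"}]}``."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise MeshFormatError(f"{path}: malformed landmark JSON: {exc}") from exc
    if not isinstance(doc, dict) or "landmarks" not in doc:
        raise MeshFormatError(f"{path}: missing top-level 'landmarks' array")
    entries = []
    for i, rec in enumerate(doc["landmarks"]):
        try:
            entries.append(Landmark(rec["name"], rec["role"], np.array(rec["xyz"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise MeshFormatError(f"{path}: bad landmark record {i}: {exc}") from exc
    return LandmarkSet(entries)


def write_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    doc = {
        "landmarks": [
            {"name": e.name, "role": e.role, "xyz": [float(v) for v in e.point]}
            for e in lms
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def validate_mesh(
    mesh: TriangleMesh, clean: bool = False
) -> ValidationReport | tuple[ValidationReport, TriangleMesh]:
    """Report non-finite vertices, bad face indices and degenerate faces.

    With ``clean=True`` also return a copy with degenerate faces dropped
    (logged, not an error; zero-area slivers are an STL fact of life).
    """
    bad_vertices = np.where(~np.isfinite(mesh.vertices).all(axis=1))[0]
    oob = np.where((mesh.faces < 0).any(axis=1) | (mesh.faces >= mesh.n_vertices).any(axis=1))[0]
    if len(oob) or len(bad_vertices):
        # areas are meaningless for broken faces; only test valid ones
        ok = np.setdiff1d(np.arange(mesh.n_faces), oob)
    else:
        ok = np.arange(mesh.n_faces)
    areas = np.full(mesh.n_faces, np.inf)
    if len(ok):
        sub = TriangleMesh(mesh.vertices, mesh.faces[ok])
        with np.errstate(invalid="ignore"):
            areas[ok] = sub.face_areas()
    degenerate = np.where(~(areas >= DEGENERATE_AREA_FLOOR) | np.isnan(areas))[0]
    degenerate = np.setdiff1d(degenerate, oob)
    report = ValidationReport(bad_vertices, oob, degenerate)
    if not clean:
        return report
    if len(degenerate):
        logger.warning("dropping %d degenerate face(s)", len(degenerate))
    keep = np.setdiff1d(np.arange(mesh.n_faces), degenerate)
    return report, TriangleMesh(mesh.vertices.copy(), mesh.faces[keep].copy())
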