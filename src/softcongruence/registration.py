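"""Rigid superimposition of the post-operative scan onto the simulation.

The pose is established in two stages, mirroring the measurement
protocol: a coarse "basic alignment" without reference points (centroid
plus principal-axes alignment), then the reference-point-system (RPS)
alignment — an unweighted least-squares rigid fit (Kabsch) over the 15
paired cranial landmarks, accepted only when every per-pair residual is
below a threshold (default 0.1 mm).  No scaling and no ICP refinement:
surgery does not rescale heads, and iterating over surgically changed
regions would bias the distance map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mesh_io import LandmarkSet, Landmark, TriangleMesh

#: Default per-pair acceptance threshold for the RPS alignment (mm),
#: compared strictly (residual < epsilon).
DEFAULT_EPSILON = 0.1

_ORTHO_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Point set too flat/collinear to define a rigid alignment."""


@dataclass
class RigidTransform:
    """Proper rigid motion x -> rotation @ x + translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)

    def check(self) -> None:
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """The transform equal to applying ``first`` then ``self``."""
        return RigidTransform(
            self.rotation @ first.rotation,
            self.rotation @ first.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"matrix": self.to_matrix().tolist()}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RigidTransform":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_matrix(np.array(json.loads(text)["matrix"]))


@dataclass
class AlignmentResult:
    """Outcome of the RPS landmark alignment."""

    transform: RigidTransform
    residuals: np.ndarray  # per-pair distances after transform, mm
    names: list[str] = field(default_factory=list)
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=np.float64).reshape(-1)

    @property
    def rms_residual(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2)))

    @property
    def max_residual(self) -> float:
        return float(self.residuals.max())

    @property
    def accepted(self) -> bool:
        # strict comparison: accepted iff every deviation is < epsilon
        return bool(self.max_residual < self.epsilon)


def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping ``source`` onto ``target``.

    Minimises sum ||R s_i + t - t_i||^2 over rotations R (det +1) and
    translations t, via SVD of the cross-covariance with the usual sign
    correction that excludes reflections.
    """
    source = np.asarray(source, dtype=np.float64).reshape(-1, 3)
    target = np.asarray(target, dtype=np.float64).reshape(-1, 3)
    if source.shape != target.shape or len(source) < 3:
        raise ValueError("need two equal point sets with at least 3 points")
    cs, ct = source.mean(axis=0), target.mean(axis=0)
    a, b = source - cs, target - ct
    if np.linalg.matrix_rank(a, tol=1e-9 * max(1.0, np.abs(a).max())) < 2:
        raise DegenerateGeometryError("landmarks are collinear; pose underdetermined")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, ct - r @ cs)


def _principal_axes(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and a deterministic principal-axis frame of a vertex cloud.

    Axis signs are disambiguated by the third central moment along each
    axis (an intrinsic, rotation-equivariant property), falling back to
    the largest-magnitude component when the skew is negligible.
    """
    c = vertices.mean(axis=0)
    x = vertices - c
    cov = x.T @ x / len(x)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = float(np.sqrt(max(evals[0], 1e-30)))
    if evals[1] < 1e-12 * max(evals[0], 1.0):
        raise DegenerateGeometryError(
            "vertex covariance is rank-deficient (collinear geometry)"
        )
    for k in range(3):
        axis = evecs[:, k]
        proj = x @ axis
        skew = float(np.mean(proj**3))
        if abs(skew) > 1e-9 * scale**3:
            sign = np.sign(skew)
        else:
            j = int(np.argmax(np.abs(axis)))
            sign = np.sign(axis[j]) or 1.0
        evecs[:, k] = sign * axis
    return c, evecs


def basic_alignment(source: TriangleMesh, target: TriangleMesh) -> RigidTransform:
    """Coarse landmark-free pre-alignment (centroid + principal axes).

    Deterministic for fixed inputs; serves only as an initialiser — the
    RPS alignment alone fixes the final pose when landmarks exist.
    """
    source.check()
    target.check()
    cs, us = _principal_axes(source.vertices)
    ct, ut = _principal_axes(target.vertices)
    r = ut @ us.T
    if np.linalg.det(r) < 0:  # mirror-ambiguous skew pattern; flip weakest axis
        us[:, 2] = -us[:, 2]
        r = ut @ us.T
    return RigidTransform(r, ct - r @ cs)


def rps_alignment(
    source_lm: LandmarkSet,
    target_lm: LandmarkSet,
    epsilon: float = DEFAULT_EPSILON,
) -> AlignmentResult:
    """RPS alignment: unweighted Kabsch over the 15 paired landmarks.

    The axis roles of the point groups are metadata only; all pairs enter
    the least-squares fit with equal weight.  The result is flagged
    ``accepted`` iff every per-pair residual is strictly below
    ``epsilon`` (default 0.1 mm).
    """
    src = source_lm.rps_subset()
    dst = target_lm.rps_subset()
    src.check_paired(dst)
    t = kabsch(src.points(), dst.points())
    residuals = np.linalg.norm(t.apply(src.points()) - dst.points(), axis=1)
    return AlignmentResult(t, residuals, names=src.names, epsilon=epsilon)


def apply_transform(mesh: TriangleMesh, t: RigidTransform) -> TriangleMesh:
    """Return ``mesh`` rigidly moved by ``t`` (normals rotated, faces kept)."""
    normals = None if mesh.normals is None else mesh.normals @ t.rotation.T
    return TriangleMesh(t.apply(mesh.vertices), mesh.faces.copy(), normals)


def transform_landmarks(lms: LandmarkSet, t: RigidTransform) -> LandmarkSet:
    return LandmarkSet([Landmark(e.name, e.role, t.apply(e.point)) for e in lms])
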