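"""Synthetic face pairs and cohorts with ground truth.

No patient surfaces accompany the study this pipeline operationalises,
so every stage is exercised against generated data instead: a smooth
analytic height-field face (half-ellipsoid base + nose ridge + lip
rolls + chin boss) with all landmarks at known parametric positions and
every vertex labelled with its true aesthetic unit; a known rigid
mis-pose; a regionally concentrated soft-tissue deformation of
controllable amplitude; and scanner noise (default SD 0.1 mm, half the
stated <0.2 mm RMS accuracy of the stereophotogrammetry camera).

The deformation engine mirrors — deliberately loosely — the mass-tensor
style of the commercial predictor: "join" vertices are constrained
(bone-following region moves rigidly with the planned displacement, the
far field stays put) and "free" vertices relax to the discrete harmonic
(uniform graph Laplacian) interpolant, solved with an iterative polish
that stops once the largest update falls below a dynamic threshold.
It is a surface solver with no tissue-specific stiffness; it provides
controllable ground truth, not a reimplementation of any commercial
algorithm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from ._closest import _build_pseudo_normals
from .distance import signed_distance_map
from .mesh_io import (
    Landmark,
    LandmarkSet,
    ROLE_ANCHOR,
    ROLE_ANTERO_POSTERIOR,
    ROLE_ORBITAL,
    ROLE_ZYGOMATIC,
    TriangleMesh,
    write_landmarks,
    write_stl,
)
from .metrics import CongruenceReport, case_report
from .regions import ELEMENTARY_UNITS, UNIT_LABELS, build_fences, masks_from_labels
from .registration import RigidTransform, transform_landmarks, apply_transform

#: Minimum vertices per elementary unit for a usable resolution.
MIN_UNIT_VERTICES = 50

#: Study factor levels (and the 20-patient marginal counts they default to).
FACTOR_LEVELS = {
    "angle_class": ("II", "III"),
    "displacement": ("lt5mm", "gt5mm"),
    "bite": ("deep", "neutral", "open"),
    "age_group": ("lt30", "30to40", "gt40"),
    "gender": ("male", "female"),
}
DEFAULT_MARGINALS = {
    "angle_class": (9, 11),
    "displacement": (10, 10),
    "bite": (8, 7, 5),
    "age_group": (11, 5, 4),
    "gender": (10, 10),
}

#: Default per-region congruence baseline (IO%, percent) for the fast
#: cohort generator, graded cranial-to-caudal like real predictions.
DEFAULT_IO_BASE = {
    "face_total": 85.0,
    "nose": 92.0,
    "upper_cheek": 90.0,
    "lower_cheek": 80.0,
    "upper_lip": 88.0,
    "lower_lip": 75.0,
    "both_lips": 80.0,
    "chin": 82.0,
}


@dataclass(frozen=True)
class FaceSpec:
    """Parameters of the analytic face (mm; z cranio-caudal, y lateral)."""

    height: float = 160.0
    width: float = 140.0
    depth: float = 55.0
    nose_height: float = 12.0
    lip_protrusion: float = 3.0
    chin_projection: float = 5.0
    ny: int = 61
    nz: int = 75
    seed: int = 0


@dataclass
class FaceBundle:
    mesh: TriangleMesh
    landmarks: LandmarkSet
    labels: np.ndarray  # per-vertex true elementary-unit labels (0 = outside)
    spec: FaceSpec

    def masks(self):
        return masks_from_labels(self.labels)


def _surface_height(spec: FaceSpec, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Closed-form depth x = f(y, z) of the face surface."""
    h, w = spec.height, spec.width
    e = 1.0 - (2.0 * y / w) ** 2 - ((z - h / 2.0) / (h / 2.0)) ** 2
    x = spec.depth * np.sqrt(np.clip(e, 0.0, None))
    # nose: dorsum ridge up toward the nasion plus a tip bump
    x = x + spec.nose_height * np.exp(-((y / 9.0) ** 2)) * np.exp(
        -(((z - 0.36 * h) / (0.07 * h)) ** 2)
    )
    x = x + 0.45 * spec.nose_height * np.exp(-((y / 7.0) ** 2)) * np.exp(
        -(((z - 0.47 * h) / (0.10 * h)) ** 2)
    )
    # lip rolls
    lipy = np.exp(-((y / 16.0) ** 2))
    x = x + spec.lip_protrusion * lipy * np.exp(
        -(((z - 0.235 * h) / (0.022 * h)) ** 2)
    )
    x = x + spec.lip_protrusion * lipy * np.exp(
        -(((z - 0.165 * h) / (0.022 * h)) ** 2)
    )
    # chin boss
    x = x + spec.chin_projection * np.exp(-((y / 15.0) ** 2)) * np.exp(
        -(((z - 0.09 * h) / (0.05 * h)) ** 2)
    )
    return x


def _landmark_table(spec: FaceSpec) -> list[tuple[str, str, float, float]]:
    """(name, role, y, z) for every landmark; x follows from the surface."""
    h, w = spec.height, spec.width
    ap = ROLE_ANTERO_POSTERIOR
    zy = ROLE_ZYGOMATIC
    orb = ROLE_ORBITAL
    an = ROLE_ANCHOR
    out = [
        ("glabella", ap, 0.0, 0.66 * h),
        ("nasion", ap, 0.0, 0.58 * h),
        ("nose_cranial", ap, 0.0, 0.51 * h),
        ("zygomatic_anterior_l", zy, +0.36 * w, 0.54 * h),
        ("zygomatic_anterior_r", zy, -0.36 * w, 0.54 * h),
        ("zygomatic_posterior_l", zy, +0.44 * w, 0.50 * h),
        ("zygomatic_posterior_r", zy, -0.44 * w, 0.50 * h),
        ("orbital_sup_med_l", orb, +0.10 * w, 0.63 * h),
        ("orbital_sup_med_r", orb, -0.10 * w, 0.63 * h),
        ("orbital_sup_lat_l", orb, +0.22 * w, 0.64 * h),
        ("orbital_sup_lat_r", orb, -0.22 * w, 0.64 * h),
        ("orbital_inf_med_l", orb, +0.10 * w, 0.555 * h),
        ("orbital_inf_med_r", orb, -0.10 * w, 0.555 * h),
        ("orbital_inf_lat_l", orb, +0.22 * w, 0.55 * h),
        ("orbital_inf_lat_r", orb, -0.22 * w, 0.55 * h),
        # segmentation anchors
        ("exocanthion_l", an, +0.30 * w, 0.56 * h),
        ("exocanthion_r", an, -0.30 * w, 0.56 * h),
        ("zygion_l", an, +0.46 * w, 0.52 * h),
        ("zygion_r", an, -0.46 * w, 0.52 * h),
        ("alare_l", an, +11.0, 0.29 * h),
        ("alare_r", an, -11.0, 0.29 * h),
        ("subnasale", an, 0.0, 0.27 * h),
        ("labiale_superius", an, 0.0, 0.235 * h),
        ("stomion", an, 0.0, 0.20 * h),
        ("cheilion_l", an, +24.0, 0.20 * h),
        ("cheilion_r", an, -24.0, 0.20 * h),
        ("labiale_inferius", an, 0.0, 0.165 * h),
        ("sublabiale", an, 0.0, 0.13 * h),
        ("menton", an, 0.0, 0.06 * h),
    ]
    return out


def generate_face(spec: FaceSpec = FaceSpec()) -> FaceBundle:
    """Build the analytic face mesh, its landmarks and true unit labels.

    Deterministic: identical specs yield bit-identical bundles.  Raises
    if any elementary unit would contain fewer than
    :data:`MIN_UNIT_VERTICES` vertices (resolution too low).
    """
    if spec.ny < 2 or spec.nz < 2:
        raise ValueError("grid resolution must be at least 2x2")
    ys = np.linspace(-spec.width / 2.0, spec.width / 2.0, spec.ny)
    zs = np.linspace(0.0, spec.height, spec.nz)
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    xx = _surface_height(spec, yy, zz)
    vertices = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def vid(i: int, j: int) -> int:
        return i * spec.nz + j

    faces = []
    for i in range(spec.ny - 1):
        for j in range(spec.nz - 1):
            v00, v10 = vid(i, j), vid(i + 1, j)
            v01, v11 = vid(i, j + 1), vid(i + 1, j + 1)
            faces.append([v00, v10, v01])
            faces.append([v10, v11, v01])
    mesh = TriangleMesh(vertices, np.array(faces, dtype=np.int64))

    entries = []
    for name, role, y, z in _landmark_table(spec):
        x = float(_surface_height(spec, np.array(y), np.array(z)))
        entries.append(Landmark(name, role, np.array([x, y, z])))
    landmarks = LandmarkSet(entries)

    fences = build_fences(landmarks)
    labels = fences.classify(mesh.vertices)
    for unit, code in UNIT_LABELS.items():
        count = int((labels == code).sum())
        if count < MIN_UNIT_VERTICES:
            raise ValueError(
                f"resolution too low: unit {unit!r} has {count} < "
                f"{MIN_UNIT_VERTICES} vertices"
            )
    return FaceBundle(mesh, landmarks, labels, spec)


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Outward unit vertex normals (angle-weighted)."""
    pn = _build_pseudo_normals(mesh.vertices, mesh.faces)
    n = pn.vertex
    norms = np.linalg.norm(n, axis=1)
    norms[norms == 0] = 1.0
    return n / norms[:, None]


# ---------------------------------------------------------------------------
# harmonic (join/free) deformation
# ---------------------------------------------------------------------------


def mesh_edges(mesh: TriangleMesh) -> np.ndarray:
    """Unique undirected edges of the triangulation, as an (e, 2) array."""
    f = mesh.faces
    e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def harmonic_field(
    n_vertices: int,
    edges: np.ndarray,
    constraints: dict,
    tol: float = 1e-8,
) -> np.ndarray:
    """Discrete harmonic interpolation of Dirichlet displacement data.

    Free vertices solve the uniform-graph-Laplacian equation (each free
    value is the mean of its neighbours), each Cartesian component
    independently.  A sparse factorisation supplies the solution, then
    Jacobi sweeps polish it until the largest update drops below the
    dynamic threshold ``tol`` (mm), guaranteeing the mean-of-neighbours
    stationarity holds to that tolerance.
    """
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    c_idx = np.array(sorted(constraints), dtype=np.int64)
    if len(c_idx) == 0:
        raise ValueError("at least one join (constrained) vertex is required")
    c_val = np.array([np.asarray(constraints[i], dtype=np.float64) for i in c_idx])
    c_val = c_val.reshape(len(c_idx), -1)
    dim = c_val.shape[1]

    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_vertices, n_vertices)
    )

    out = np.zeros((n_vertices, dim))
    out[c_idx] = c_val
    free = np.setdiff1d(np.arange(n_vertices), c_idx)
    if len(free) == 0:
        return out

    a_ff = adj[free][:, free]
    a_fc = adj[free][:, c_idx]
    deg = np.asarray(adj.sum(axis=1)).ravel()[free]
    if (deg == 0).any() or (a_fc.sum() == 0 and len(c_idx) > 0):
        pass  # caught by the component check below
    n_comp, comp = connected_components(a_ff, directed=False)
    touched = np.zeros(n_comp, dtype=bool)
    link_counts = np.asarray(a_fc.sum(axis=1)).ravel()
    for k in range(n_comp):
        if link_counts[comp == k].sum() > 0:
            touched[k] = True
    if not touched.all():
        raise ValueError(
            "free vertices form a component with no join-point constraint; "
            "the harmonic problem is underdetermined"
        )

    lap = sp.diags(deg) - a_ff
    rhs = a_fc @ c_val
    x = spsolve(lap.tocsc(), rhs)
    x = np.atleast_2d(x.reshape(len(free), dim))
    # Jacobi polish with dynamic stopping: each sweep replaces every free
    # value by the mean of its neighbours; stop when nothing moves > tol.
    for _ in range(1000):
        x_new = (a_ff @ x + a_fc @ c_val) / deg[:, None]
        delta = np.abs(x_new - x).max() if len(x) else 0.0
        x = x_new
        if delta < tol:
            break
    out[free] = x
    return out


def harmonic_displacement(mesh: TriangleMesh, constraints: dict, tol: float = 1e-8):
    """Mesh wrapper over :func:`harmonic_field` (see there for semantics)."""
    return harmonic_field(mesh.n_vertices, mesh_edges(mesh), constraints, tol=tol)


def _dilate(adj: sp.csr_matrix, mask: np.ndarray, rings: int) -> np.ndarray:
    out = mask.copy()
    for _ in range(rings):
        out = out | (adj @ out.astype(np.float64) > 0)
    return out


# ---------------------------------------------------------------------------
# case construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionDisplacement:
    """One deformation target: push ``region`` by ``amplitude`` mm."""

    region: str = "chin"
    amplitude: float = 3.0
    mode: str = "harmonic"  # harmonic | gaussian-bump | rigid-follow
    direction: str | tuple = "normal"  # "normal" or a fixed 3-vector
    collar_rings: int = 6  # free-tissue collar width for harmonic mode


@dataclass(frozen=True)
class DeformationSpec:
    """Deformation + acquisition model for one synthetic case."""

    targets: tuple = (RegionDisplacement(),)
    noise_sd: float = 0.1  # mm, along-normal scanner noise
    mispose: bool = True
    rot_deg: float = 6.0
    trans_mm: float = 10.0
    landmark_sd: float = 0.0  # optional landmark-picking noise
    seed: int = 0


@dataclass
class CaseBundle:
    """A simulation/scan pair with full ground truth."""

    simulation: TriangleMesh
    scan: TriangleMesh
    sim_landmarks: LandmarkSet
    scan_landmarks: LandmarkSet
    displacement: np.ndarray  # true per-vertex field, pre-noise (n, 3)
    truth: CongruenceReport  # regional summary of the noise-free field
    mispose: RigidTransform
    labels: np.ndarray
    face_spec: FaceSpec
    deformation_spec: DeformationSpec


def _direction_field(mesh: TriangleMesh, direction) -> np.ndarray:
    if isinstance(direction, str):
        if direction != "normal":
            raise ValueError(f"unknown direction {direction!r}")
        return vertex_normals(mesh)
    vec = np.asarray(direction, dtype=np.float64).reshape(3)
    return np.tile(vec, (mesh.n_vertices, 1))


def displacement_field(face: FaceBundle, dspec: DeformationSpec) -> np.ndarray:
    """The true per-vertex soft-tissue displacement (n, 3), noise-free."""
    mesh = face.mesh
    disp = np.zeros((mesh.n_vertices, 3))
    harmonic_constraints: dict = {}
    need_harmonic = False
    edges = None
    for target in dspec.targets:
        if target.region not in UNIT_LABELS:
            raise ValueError(f"unknown region {target.region!r}")
        idx = np.where(face.labels == UNIT_LABELS[target.region])[0]
        dirs = _direction_field(mesh, target.direction)
        if target.mode == "rigid-follow":
            disp[idx] += target.amplitude * dirs[idx]
        elif target.mode == "gaussian-bump":
            y, z = mesh.vertices[:, 1], mesh.vertices[:, 2]
            y0, z0 = y[idx].mean(), z[idx].mean()
            sy = max(y[idx].std(), 1.0) * 1.2
            sz = max(z[idx].std(), 1.0) * 1.2
            r2 = ((y - y0) / sy) ** 2 + ((z - z0) / sz) ** 2
            g = np.exp(-(r2**2))  # super-Gaussian: flat core, fast falloff
            disp += target.amplitude * g[:, None] * dirs
        elif target.mode == "harmonic":
            need_harmonic = True
            for i in idx:
                harmonic_constraints[int(i)] = target.amplitude * dirs[i]
        else:
            raise ValueError(f"unknown deformation mode {target.mode!r}")
    if need_harmonic:
        if edges is None:
            edges = mesh_edges(mesh)
        adj = sp.csr_matrix(
            (
                np.ones(2 * len(edges)),
                (
                    np.concatenate([edges[:, 0], edges[:, 1]]),
                    np.concatenate([edges[:, 1], edges[:, 0]]),
                ),
            ),
            shape=(mesh.n_vertices, mesh.n_vertices),
        )
        joined = np.zeros(mesh.n_vertices, dtype=bool)
        joined[list(harmonic_constraints)] = True
        collar = max(t.collar_rings for t in dspec.targets if t.mode == "harmonic")
        near = _dilate(adj, joined, collar)
        # everything outside the free collar is anchored at rest
        for i in np.where(~near)[0]:
            harmonic_constraints.setdefault(int(i), np.zeros(3))
        disp += harmonic_field(mesh.n_vertices, edges, harmonic_constraints)
    return disp


def _random_rigid(rng: np.random.Generator, rot_deg: float, trans_mm: float):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.2 * rot_deg, rot_deg))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    r = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    t = rng.normal(size=3)
    t *= trans_mm / np.linalg.norm(t)
    return RigidTransform(r, t)


def make_case(face: FaceBundle, dspec: DeformationSpec = DeformationSpec()) -> CaseBundle:
    """Deform, noise and mis-pose the face into a simulation/scan pair.

    The simulation is the base face.  The "post-operative" scan is the
    face plus the deformation field, plus iid along-normal noise, moved
    by a known rigid mis-pose.  The regional truth summary is computed
    from the noise-free, un-posed deformed surface.
    """
    rng = np.random.default_rng(dspec.seed)
    sim = face.mesh
    disp = displacement_field(face, dspec)
    clean = TriangleMesh(sim.vertices + disp, sim.faces.copy())

    dmap_true = signed_distance_map(sim, clean, flip_sign=True)
    truth = case_report(dmap_true, face.masks())

    scan_v = clean.vertices.copy()
    if dspec.noise_sd > 0:
        normals = vertex_normals(clean)
        scan_v = scan_v + rng.normal(0.0, dspec.noise_sd, sim.n_vertices)[:, None] * normals
    noisy = TriangleMesh(scan_v, sim.faces.copy())

    pose = (
        _random_rigid(rng, dspec.rot_deg, dspec.trans_mm)
        if dspec.mispose
        else RigidTransform.identity()
    )
    scan = apply_transform(noisy, pose)

    # scan-side landmarks follow the anatomy: base position + the true
    # displacement of the nearest vertex, then the mis-pose (plus optional
    # picking noise).
    from scipy.spatial import cKDTree

    tree = cKDTree(sim.vertices)
    entries = []
    for e in face.landmarks:
        _, nearest = tree.query(e.point)
        p = e.point + disp[nearest]
        if dspec.landmark_sd > 0:
            p = p + rng.normal(0.0, dspec.landmark_sd, 3)
        entries.append(Landmark(e.name, e.role, p))
    scan_landmarks = transform_landmarks(LandmarkSet(entries), pose)

    return CaseBundle(
        simulation=sim,
        scan=scan,
        sim_landmarks=face.landmarks,
        scan_landmarks=scan_landmarks,
        displacement=disp,
        truth=truth,
        mispose=pose,
        labels=face.labels,
        face_spec=face.spec,
        deformation_spec=dspec,
    )


def write_case(bundle: CaseBundle, out_dir: str | Path) -> None:
    """Emit the standard case bundle (STL pair, sidecars, truth, manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stl(bundle.simulation, out / "simulation.stl")
    write_stl(bundle.scan, out / "scan.stl")
    write_landmarks(bundle.sim_landmarks, out / "simulation.landmarks.json")
    write_landmarks(bundle.scan_landmarks, out / "scan.landmarks.json")
    truth = {
        "regional": json.loads(bundle.truth.table.to_json(orient="index")),
        "mispose": json.loads(bundle.mispose.to_json()),
        "face_spec": asdict(bundle.face_spec),
        "deformation_spec": {
            "targets": [asdict(t) for t in bundle.deformation_spec.targets],
            "noise_sd": bundle.deformation_spec.noise_sd,
            "mispose": bundle.deformation_spec.mispose,
            "rot_deg": bundle.deformation_spec.rot_deg,
            "trans_mm": bundle.deformation_spec.trans_mm,
            "landmark_sd": bundle.deformation_spec.landmark_sd,
            "seed": bundle.deformation_spec.seed,
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def _level_counts(n: int, marginal: tuple) -> list[int]:
    """Scale marginal counts to n patients by largest remainder."""
    total = sum(marginal)
    exact = [n * m / total for m in marginal]
    counts = [int(np.floor(v)) for v in exact]
    rem = n - sum(counts)
    order = np.argsort([c - e for c, e in zip(counts, exact)])
    for k in range(rem):
        counts[order[k]] += 1
    return counts


def generate_cohort(
    n: int = 20,
    seed: int = 0,
    effects: dict | None = None,
    noise_sd: float = 5.0,
    base: dict | None = None,
    marginals: dict | None = None,
) -> pd.DataFrame:
    """A synthetic study table: factors + per-region IO% for n patients.

    Factor levels are assigned with marginal counts proportional to the
    default 20-patient composition (9/11, 10/10, 8/7/5, 11/5/4, 10/10),
    independently shuffled per factor.  IO% for each region is its
    baseline plus any configured factor effects plus iid Gaussian noise
    (this is the mesh-free "fast mode"; use :func:`make_case` when full
    surface pairs are wanted).

    ``effects`` maps ``(factor, level, region) -> shift in IO% points``.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 patients")
    rng = np.random.default_rng(seed)
    base = dict(DEFAULT_IO_BASE if base is None else base)
    marginals = dict(DEFAULT_MARGINALS if marginals is None else marginals)
    effects = effects or {}

    data = {"patient_id": [f"P{i + 1:03d}" for i in range(n)]}
    for factor, levels in FACTOR_LEVELS.items():
        counts = _level_counts(n, marginals[factor])
        if min(counts) < 1:
            raise ValueError(f"infeasible marginal counts for {factor}: {counts}")
        col = np.repeat(levels, counts)
        rng.shuffle(col)
        data[factor] = col
    df = pd.DataFrame(data)

    for region, b in base.items():
        vals = np.full(n, float(b))
        for (factor, level, reg), shift in effects.items():
            if reg == region:
                vals = vals + shift * (df[factor] == level).to_numpy(dtype=float)
        vals = vals + rng.normal(0.0, noise_sd, n)
        df[region] = np.clip(vals, 0.0, 100.0)
    return df
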