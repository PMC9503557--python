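import numpy as np
import pytest

from softcongruence.mesh_io import TriangleMesh
from softcongruence.regions import ELEMENTARY_UNITS, UNIT_LABELS, masks_from_labels
from softcongruence.synthetic_data import (
    DEFAULT_MARGINALS,
    DeformationSpec,
    FaceSpec,
    RegionDisplacement,
    displacement_field,
    generate_cohort,
    generate_face,
    harmonic_displacement,
    harmonic_field,
    make_case,
    write_case,
)


# --- face generation ---------------------------------------------------------


def test_face_is_deterministic():
    a = generate_face(FaceSpec(ny=49, nz=61))
    b = generate_face(FaceSpec(ny=49, nz=61))
    assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
    assert np.array_equal(a.mesh.faces, b.mesh.faces)
    assert np.array_equal(a.labels, b.labels)
    assert a.landmarks.names == b.landmarks.names


def test_face_labels_form_partition(small_face):
    masks = small_face.masks()
    masks.check()
    assert all(len(masks[u]) > 0 for u in ELEMENTARY_UNITS)


def test_face_landmarks_lie_on_surface(small_face):
    """Landmarks are analytic surface points: near-zero distance to the mesh."""
    from softcongruence.distance import signed_distance_map

    pts = small_face.landmarks.points()
    qmesh = TriangleMesh(pts, np.array([[0, 1, 2]]))
    dmap = signed_distance_map(qmesh, small_face.mesh, invalidate_boundary=False)
    # mesh is a chordal approximation of the analytic surface
    assert np.abs(dmap.distances).max() < 0.5


def test_face_rps_set_valid(small_face):
    small_face.landmarks.rps_subset().check_rps()


def test_low_resolution_rejected():
    with pytest.raises(ValueError, match="resolution too low"):
        generate_face(FaceSpec(ny=21, nz=25))


def test_label_proportions_stable_under_refinement():
    coarse = generate_face(FaceSpec(ny=49, nz=61))
    fine = generate_face(FaceSpec(ny=97, nz=121))

    def props(face):
        counts = {
            u: (face.labels == c).sum() for u, c in UNIT_LABELS.items()
        }
        total = sum(counts.values())
        return {u: n / total for u, n in counts.items()}

    pc, pf = props(coarse), props(fine)
    for u in ELEMENTARY_UNITS:
        assert abs(pc[u] - pf[u]) < 0.02


# --- harmonic deformation ----------------------------------------------------


def test_harmonic_all_constrained_equals_constraints(tetra):
    constraints = {i: np.array([0.1 * i, 0.0, 0.0]) for i in range(4)}
    field = harmonic_displacement(tetra, constraints)
    for i, v in constraints.items():
        assert np.array_equal(field[i], v)


def test_harmonic_constant_constraints_give_constant_field(small_face):
    mesh = small_face.mesh
    d = np.array([0.0, 0.0, 2.5])
    idx = np.arange(0, mesh.n_vertices, 7)  # scattered joins
    field = harmonic_displacement(mesh, {int(i): d for i in idx})
    assert np.abs(field - d).max() < 1e-7


def test_harmonic_path_graph_matches_linear_closed_form():
    """Endpoints 0 and 1 on a path: interior is linear in graph position."""
    n = 21
    edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    field = harmonic_field(n, edges, {0: [0.0], n - 1: [1.0]})
    expected = np.linspace(0.0, 1.0, n)[:, None]
    assert np.abs(field - expected).max() < 1e-7


def test_harmonic_maximum_principle(small_face):
    rng = np.random.default_rng(0)
    mesh = small_face.mesh
    idx = rng.choice(mesh.n_vertices, 60, replace=False)
    constraints = {int(i): rng.uniform(-2, 3, 3) for i in idx}
    field = harmonic_displacement(mesh, constraints)
    cvals = np.array(list(constraints.values()))
    for k in range(3):
        assert field[:, k].min() >= cvals[:, k].min()
        assert field[:, k].max() <= cvals[:, k].max()


def test_harmonic_linearity(small_face):
    rng = np.random.default_rng(1)
    mesh = small_face.mesh
    idx = [int(i) for i in rng.choice(mesh.n_vertices, 40, replace=False)]
    c1 = {i: rng.normal(size=3) for i in idx}
    c2 = {i: rng.normal(size=3) for i in idx}
    a, b = 2.0, -0.5
    f1 = harmonic_displacement(mesh, c1)
    f2 = harmonic_displacement(mesh, c2)
    f12 = harmonic_displacement(mesh, {i: a * c1[i] + b * c2[i] for i in idx})
    assert np.abs(f12 - (a * f1 + b * f2)).max() < 1e-6


def test_harmonic_unconstrained_component_rejected():
    # two disjoint edges; only one touches a constraint
    edges = np.array([[0, 1], [2, 3]])
    with pytest.raises(ValueError, match="component"):
        harmonic_field(4, edges, {0: [1.0]})


# --- case construction -------------------------------------------------------


def test_zero_deformation_zero_noise_identity_pose(small_face):
    spec = DeformationSpec(
        targets=(RegionDisplacement(amplitude=0.0),), noise_sd=0.0, mispose=False
    )
    bundle = make_case(small_face, spec)
    assert np.abs(bundle.displacement).max() == 0.0
    assert np.array_equal(bundle.scan.vertices, bundle.simulation.vertices)
    assert (bundle.truth.table["io_pct"].dropna() == 100.0).all()


def test_rigid_follow_chin_truth(small_face):
    """+3 mm outward chin displacement: chin truth ~= +3, nose untouched."""
    spec = DeformationSpec(
        targets=(RegionDisplacement("chin", 3.0, mode="rigid-follow"),),
        noise_sd=0.0,
        mispose=False,
    )
    bundle = make_case(small_face, spec)
    chin_idx = np.where(small_face.labels == UNIT_LABELS["chin"])[0]
    assert np.allclose(
        np.linalg.norm(bundle.displacement[chin_idx], axis=1), 3.0, atol=1e-9
    )
    # the unit's interior sits on the 3 mm plateau; the boundary ring sees
    # the sharp step to the unmoved surround, pulling the mean below 3
    chin = bundle.truth.table.loc["chin"]
    assert 2.0 < chin["mtl"] <= 3.0 + 1e-9
    assert abs(chin["max"] - 3.0) < 0.1
    assert abs(bundle.truth.table.loc["nose", "mtl"]) < 1e-9


def test_harmonic_case_confines_deformation(small_face):
    spec = DeformationSpec(
        targets=(RegionDisplacement("chin", 3.0, mode="harmonic"),),
        noise_sd=0.0,
        mispose=False,
    )
    bundle = make_case(small_face, spec)
    # RPS landmarks live in the unchanged cranial face: scan landmarks equal
    # sim landmarks exactly (identity pose, no deformation there)
    rps = bundle.sim_landmarks.rps_subset()
    rps_scan = bundle.scan_landmarks.rps_subset()
    assert np.abs(rps.points() - rps_scan.points()).max() < 1e-12
    nose_idx = np.where(small_face.labels == UNIT_LABELS["nose"])[0]
    assert np.abs(bundle.displacement[nose_idx]).max() < 1e-9


def test_gaussian_bump_mode_smooth(small_face):
    spec = DeformationSpec(
        targets=(RegionDisplacement("chin", 2.0, mode="gaussian-bump"),),
        noise_sd=0.0,
        mispose=False,
    )
    field = displacement_field(small_face, spec)
    mags = np.linalg.norm(field, axis=1)
    assert mags.max() <= 2.0 + 1e-9
    chin_idx = np.where(small_face.labels == UNIT_LABELS["chin"])[0]
    assert mags[chin_idx].max() > 1.5  # core of the bump reaches the target


def test_case_determinism_and_noise_seeding(small_face):
    spec = DeformationSpec(seed=5)
    b1 = make_case(small_face, spec)
    b2 = make_case(small_face, spec)
    assert np.array_equal(b1.scan.vertices, b2.scan.vertices)
    assert np.array_equal(
        b1.scan_landmarks.points(), b2.scan_landmarks.points()
    )
    b3 = make_case(small_face, DeformationSpec(seed=6))
    assert not np.array_equal(b1.scan.vertices, b3.scan.vertices)


def test_write_case_bundle(tmp_path, small_face):
    bundle = make_case(small_face, DeformationSpec(noise_sd=0.0, seed=2))
    write_case(bundle, tmp_path)
    for name in (
        "simulation.stl",
        "scan.stl",
        "simulation.landmarks.json",
        "scan.landmarks.json",
        "truth.json",
    ):
        assert (tmp_path / name).exists()


# --- cohorts -----------------------------------------------------------------


def test_cohort_marginals_match_study_composition():
    table = generate_cohort(n=20, seed=3)
    assert len(table) == 20
    for factor, counts in DEFAULT_MARGINALS.items():
        observed = table[factor].value_counts()
        from softcongruence.synthetic_data import FACTOR_LEVELS

        expected = dict(zip(FACTOR_LEVELS[factor], counts))
        assert observed.to_dict() == expected


def test_cohort_deterministic_and_in_range():
    t1 = generate_cohort(n=20, seed=4)
    t2 = generate_cohort(n=20, seed=4)
    assert t1.equals(t2)
    from softcongruence.regions import REGION_NAMES

    for region in REGION_NAMES:
        assert t1[region].between(0, 100).all()


def test_cohort_effect_shifts_target_cell():
    t = generate_cohort(
        n=200, seed=5, noise_sd=1.0, effects={("gender", "female", "chin"): -10.0}
    )
    male = t.loc[t.gender == "male", "chin"].mean()
    female = t.loc[t.gender == "female", "chin"].mean()
    assert male - female > 8.0


def test_cohort_too_small_rejected():
    with pytest.raises(ValueError):
        generate_cohort(n=1)
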