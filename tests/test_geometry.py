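"""Torsion, circular-mean, puckering, superposition and RMSD math."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from galkit.errors import DegenerateGeometryError, UndefinedAverageError
from galkit.geometry import (
    SuperpositionResult,
    assign_ring_conformation,
    circular_mean,
    dihedral,
    glycosidic_torsions,
    psi_shift,
    rmsd_subset,
    superpose,
)
from galkit.structure_io import AtomRecord, Structure, find_glycan
from galkit.synthetic import chair_template


def reference_dihedral(p1, p2, p3, p4):
    """Independent formula: atan2 on cross products of the plane normals."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, n2)
    y = np.dot(m, b2) / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    return np.degrees(np.arctan2(y, x))


coord = st.floats(-50, 50, allow_nan=False, width=32)
point = st.tuples(coord, coord, coord).map(np.array)


def test_planar_cis_is_zero_and_trans_is_180():
    assert dihedral([1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]) == pytest.approx(0.0)
    assert dihedral([-1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]) == pytest.approx(180.0)


def test_dihedral_errors_on_degenerate_geometry():
    with pytest.raises(DegenerateGeometryError):
        dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])  # collinear p1p2p3
    with pytest.raises(DegenerateGeometryError):
        dihedral([0, 1, 0], [1, 0, 0], [1, 0, 0], [2, 1, 0])  # p2 == p3


@given(p1=point, p2=point, p3=point, p4=point)
def test_dihedral_matches_oracle_with_reversal_and_mirror_symmetry(p1, p2, p3, p4):
    """Torsions are invariant under chain reversal and change sign under
    mirror reflection."""
    try:
        forward = dihedral(p1, p2, p3, p4)
    except DegenerateGeometryError:
        return
    assert forward == pytest.approx(reference_dihedral(p1, p2, p3, p4), abs=1e-9)
    backward = dihedral(p4, p3, p2, p1)
    assert abs(((forward - backward) + 180.0) % 360.0 - 180.0) < 1e-9
    mirror = dihedral(*(p * np.array([1.0, 1.0, -1.0]) for p in (p1, p2, p3, p4)))
    assert abs(((forward + mirror) + 180.0) % 360.0 - 180.0) < 1e-9


@given(p1=point, p2=point, p3=point, p4=point, shift=point)
def test_dihedral_invariant_under_rigid_motion(p1, p2, p3, p4, shift):
    rot = _rotation_from_seed(7)
    try:
        before = dihedral(p1, p2, p3, p4)
    except DegenerateGeometryError:
        return
    after = dihedral(*(rot @ p + shift for p in (p1, p2, p3, p4)))
    assert after == pytest.approx(before, abs=1e-6)


def _rotation_from_seed(seed):
    q = np.random.default_rng(seed).normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


# ---------------------------------------------------------------------------
# circular mean


def test_circular_mean_basics():
    assert circular_mean([135, 135, 135]) == pytest.approx(135.0)
    assert circular_mean([179, -179]) == pytest.approx(180.0)
    with pytest.raises(UndefinedAverageError):
        circular_mean([])
    with pytest.raises(UndefinedAverageError):
        circular_mean([0.0, 180.0])


@given(st.floats(-179.9, 180, allow_nan=False), st.integers(1, 8))
def test_circular_mean_of_identical_angles_is_identity(angle, n):
    assert circular_mean([angle] * n) == pytest.approx(angle, abs=1e-9)


def test_circular_mean_minimizes_summed_angular_distance(rng):
    """The circular mean minimizes sum of squared angular deviations."""
    for _ in range(20):
        angles = rng.uniform(-180, 180, size=rng.integers(2, 9))
        try:
            mean = circular_mean(angles)
        except UndefinedAverageError:
            continue

        def cost(m):
            d = (angles - m + 180.0) % 360.0 - 180.0
            return np.sum(1 - np.cos(np.radians(d)))

        grid = np.linspace(-180, 180, 720001)
        d = (angles[None, :] - grid[:, None] + 180.0) % 360.0 - 180.0
        costs = np.sum(1 - np.cos(np.radians(d)), axis=1)
        brute = grid[np.argmin(costs)]
        assert abs(((mean - brute) + 180.0) % 360.0 - 180.0) < 1e-3


# ---------------------------------------------------------------------------
# ring pucker


def test_ideal_chair_and_flat_hexagon():
    ring = np.array(list(chair_template().values()))
    pucker = assign_ring_conformation(ring)
    assert pucker.label == "chair"
    assert pucker.theta < 1e-6 or pucker.theta > 180 - 1e-6
    hexagon = np.array(
        [[np.cos(np.pi / 3 * j), np.sin(np.pi / 3 * j), 0.0] for j in range(6)]
    )
    assert assign_ring_conformation(hexagon).label == "planar"
    with pytest.raises(DegenerateGeometryError):
        assign_ring_conformation(np.zeros((5, 3)))


def test_fixture_rings_are_chairs(ln1_site):
    structure, _ = ln1_site
    glycan = find_glycan(structure)
    assert assign_ring_conformation(glycan.gal_ring_coords()).label == "chair"
    assert assign_ring_conformation(glycan.glcnac_ring_coords()).label == "chair"


# ---------------------------------------------------------------------------
# superposition


def quaternion_rmsd(x, y):
    """Independent minimum-RMSD via the Kearsley quaternion eigenproblem."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    sm, sp = x - y, x + y
    K = np.zeros((4, 4))
    K[0, 0] = np.sum(sm**2)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        K[0, i + 1] = K[i + 1, 0] = np.sum(sp[:, j] * sm[:, k] - sm[:, j] * sp[:, k])
        K[i + 1, i + 1] = np.sum(sp[:, j] ** 2 + sp[:, k] ** 2 + sm[:, i] ** 2)
        K[i + 1, j + 1] = K[j + 1, i + 1] = np.sum(
            sm[:, i] * sm[:, j] - sp[:, i] * sp[:, j]
        )
    lam = np.linalg.eigvalsh(K)[0]
    return np.sqrt(max(lam, 0.0) / len(x))


def test_self_superposition_is_identity(rng):
    pts = rng.normal(size=(10, 3))
    res = superpose(pts, pts)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)
    assert res.fit_rmsd == pytest.approx(0.0, abs=1e-12)


def test_superpose_recovers_known_transform(rng):
    pts = rng.normal(size=(12, 3)) * 5
    R = _rotation_from_seed(3)
    t = np.array([1.0, -2.0, 3.5])
    moved = pts @ R.T + t
    res = superpose(pts, moved)
    assert res.fit_rmsd < 1e-9
    np.testing.assert_allclose(res.rotation, R, atol=1e-9)
    np.testing.assert_allclose(res.translation, t, atol=1e-9)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0)


def test_superpose_matches_quaternion_oracle(rng):
    for _ in range(50):
        n = rng.integers(4, 30)
        x, y = rng.normal(size=(n, 3)), rng.normal(size=(n, 3))
        assert superpose(x, y).fit_rmsd == pytest.approx(
            quaternion_rmsd(x, y), abs=1e-9
        )


def test_superpose_is_a_minimum(rng):
    x, y = rng.normal(size=(15, 3)), rng.normal(size=(15, 3))
    res = superpose(x, y)
    base = res.fit_rmsd
    xc, yc = x - x.mean(axis=0), y - y.mean(axis=0)
    for _ in range(25):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(0.01, 0.3)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        perturb = (
            np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K
        ) @ res.rotation
        rmsd = np.sqrt(np.mean(np.sum((xc @ perturb.T - yc) ** 2, axis=1)))
        assert rmsd >= base - 1e-12


def test_superpose_input_validation(rng):
    with pytest.raises(DegenerateGeometryError):
        superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
    line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
    with pytest.raises(DegenerateGeometryError):
        superpose(line, line + 1.0)


# ---------------------------------------------------------------------------
# subset RMSD


def _ca_structure(name, coords):
    atoms = [
        AtomRecord("A", "ALA", i + 1, "CA", "C", tuple(map(float, xyz)))
        for i, xyz in enumerate(coords)
    ]
    return Structure(id=name, atoms=atoms)


def test_rmsd_subset_identity_and_closed_form(rng):
    coords = rng.normal(size=(8, 3)) * 4
    a = _ca_structure("a", coords)
    identity = SuperpositionResult(np.eye(3), np.zeros(3), 0.0, 8)
    assert rmsd_subset(a, a, identity, range(1, 9), atom_mode="CA") == 0.0
    displaced = coords.copy()
    d = 1.7
    displaced[2] += [d, 0, 0]
    b = _ca_structure("b", displaced)
    got = rmsd_subset(a, b, identity, range(1, 9), atom_mode="CA")
    assert got == pytest.approx(d / np.sqrt(8))
    with pytest.raises(DegenerateGeometryError):
        rmsd_subset(a, b, identity, [99], atom_mode="CA")


# ---------------------------------------------------------------------------
# glycosidic torsions and the family shift


def test_torsions_of_both_linkage_families(ln1_site, ln2_site):
    tp1 = glycosidic_torsions(find_glycan(ln1_site[0]))
    tp2 = glycosidic_torsions(find_glycan(ln2_site[0]))
    assert (tp1.phi, tp1.psi) == (pytest.approx(-60.0, abs=1e-6),
                                  pytest.approx(135.0, abs=1e-6))
    assert (tp2.phi, tp2.psi) == (pytest.approx(-66.0, abs=1e-6),
                                  pytest.approx(-108.0, abs=1e-6))
    shift = psi_shift(tp1.psi, tp2.psi)
    assert 230.0 <= shift <= 255.0  # the ~240 degree family shift
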