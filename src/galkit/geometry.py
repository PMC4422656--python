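"""Glycosidic torsions, ring puckering, superposition and subset RMSDs.

The two glycosidic torsion angles fix the orientation of the GlcNAc ring
relative to the galactose:

* type-1 (beta1-3) linkage:
  phi = O5(Gal)-C1(Gal)-O3(GlcNAc)-C3(GlcNAc),
  psi = C1(Gal)-O3(GlcNAc)-C3(GlcNAc)-C4(GlcNAc)
* type-2 (beta1-4) linkage:
  phi = O5(Gal)-C1(Gal)-O4(GlcNAc)-C4(GlcNAc),
  psi = C1(Gal)-O4(GlcNAc)-C4(GlcNAc)-C5(GlcNAc)

Angles follow the IUPAC sign convention and live in (-180, 180].
Ring conformation is assigned from Cremer-Pople puckering coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, MissingAtomError, UndefinedAverageError
from .structure_io import GlycanLigand, Structure

_EPS = 1e-10


def _wrap_degrees(angle: float) -> float:
    """Map an angle in degrees into (-180, 180]."""
    a = float(np.remainder(angle, 360.0))
    if a > 180.0:
        a -= 360.0
    if a <= -180.0:
        a += 360.0
    return a


def dihedral(p1, p2, p3, p4) -> float:
    """Dihedral angle p1-p2-p3-p4 in degrees, IUPAC sign, in (-180, 180].

    Looking along p2->p3, the angle is positive when p4 is rotated
    clockwise relative to p1.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < _EPS:
        raise DegenerateGeometryError("central atoms p2 and p3 coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise DegenerateGeometryError(
            "collinear atoms: dihedral is undefined"
        )
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return _wrap_degrees(-np.degrees(np.arctan2(y, x)))


def circular_mean(angles_deg) -> float:
    """Circular mean of angles in degrees, result in (-180, 180].

    Computed as atan2 of the mean sine and cosine; raises if the resultant
    vector is (numerically) zero, in which case no mean direction exists.
    """
    angles = np.asarray(list(angles_deg), dtype=float)
    if angles.size == 0:
        raise UndefinedAverageError("circular mean of an empty set")
    rad = np.radians(angles)
    s, c = np.mean(np.sin(rad)), np.mean(np.cos(rad))
    if np.hypot(s, c) < 1e-8:
        raise UndefinedAverageError(
            "resultant vector is zero; circular mean undefined"
        )
    return _wrap_degrees(np.degrees(np.arctan2(s, c)))


@dataclass(frozen=True)
class TorsionPair:
    """Glycosidic (phi, psi) of one bound disaccharide copy."""

    phi: float
    psi: float
    linkage: str
    source: str = ""


# atom quadruples per linkage: (moiety, atom name) with moieties G=Gal, N=GlcNAc
_TORSION_ATOMS = {
    "beta1_3": {
        "phi": (("GAL", "O5"), ("GAL", "C1"), ("GlcNAc", "O3"), ("GlcNAc", "C3")),
        "psi": (("GAL", "C1"), ("GlcNAc", "O3"), ("GlcNAc", "C3"), ("GlcNAc", "C4")),
    },
    "beta1_4": {
        "phi": (("GAL", "O5"), ("GAL", "C1"), ("GlcNAc", "O4"), ("GlcNAc", "C4")),
        "psi": (("GAL", "C1"), ("GlcNAc", "O4"), ("GlcNAc", "C4"), ("GlcNAc", "C5")),
    },
}


def glycosidic_torsions(g: GlycanLigand) -> TorsionPair:
    """Compute (phi, psi) of a bound disaccharide using the linkage-specific
    atom quadruples."""
    quads = _TORSION_ATOMS[g.linkage]
    values = {}
    for name, quad in quads.items():
        try:
            pts = [g.atom(moiety, atom).xyz for moiety, atom in quad]
        except MissingAtomError as exc:
            raise MissingAtomError(f"{name} torsion: {exc}") from None
        values[name] = dihedral(*pts)
    return TorsionPair(
        phi=values["phi"], psi=values["psi"], linkage=g.linkage, source=g.source_id
    )


def psi_shift(psi_ln1: float, psi_ln2: float) -> float:
    """|psi_LN1 - psi_LN2| reduced mod 360 into [0, 360).

    The two bound-ligand families differ by roughly 240 degrees in psi; this
    helper reports the shift on that scale (135 - (-108) -> 243).
    """
    return float(np.remainder(psi_ln1 - psi_ln2, 360.0))


# ---------------------------------------------------------------------------
# ring puckering (Cremer-Pople)


@dataclass(frozen=True)
class RingPucker:
    label: str  # "chair", "non-chair" or "planar"
    Q: float  # total puckering amplitude, A
    theta: float  # polar puckering angle, degrees in [0, 180]
    phi: float  # azimuthal puckering phase, degrees in [0, 360)


def assign_ring_conformation(
    ring_xyz, chair_theta: float = 45.0, planar_q: float = 0.1
) -> RingPucker:
    """Classify a six-membered ring via Cremer-Pople puckering coordinates.

    ``ring_xyz`` must hold the six ring atoms in ring order (for a
    pyranose: O5, C1, C2, C3, C4, C5). Chair iff theta < chair_theta or
    theta > 180 - chair_theta, provided the amplitude Q exceeds
    ``planar_q`` (below which the ring is reported planar/non-chair).
    """
    xyz = np.asarray(ring_xyz, dtype=float)
    if xyz.shape != (6, 3):
        raise DegenerateGeometryError("need exactly six ring atoms in order")
    center = xyz.mean(axis=0)
    r = xyz - center
    j = np.arange(6)
    rp = (r * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    normal = np.cross(rp, rpp)
    norm = np.linalg.norm(normal)
    if norm < _EPS:
        raise DegenerateGeometryError("degenerate (non-cyclic) ring geometry")
    normal /= norm
    z = r @ normal
    q2c = np.sqrt(2 / 6) * np.sum(z * np.cos(2 * np.pi * 2 * j / 6))
    q2s = -np.sqrt(2 / 6) * np.sum(z * np.sin(2 * np.pi * 2 * j / 6))
    q2 = np.hypot(q2c, q2s)
    phi2 = float(np.degrees(np.arctan2(q2s, q2c))) % 360.0
    q3 = np.sqrt(1 / 6) * np.sum(((-1) ** j) * z)
    Q = float(np.hypot(q2, q3))
    if Q < planar_q:
        return RingPucker("planar", Q, 90.0, phi2)
    theta = float(np.degrees(np.arccos(np.clip(q3 / Q, -1.0, 1.0))))
    label = "chair" if (theta < chair_theta or theta > 180.0 - chair_theta) else "non-chair"
    return RingPucker(label, Q, theta, phi2)


# ---------------------------------------------------------------------------
# superposition


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid fit mapping mobile coordinates onto a reference:
    y ~ rotation @ x + translation."""

    rotation: np.ndarray  # (3, 3) proper orthonormal
    translation: np.ndarray  # (3,)
    fit_rmsd: float
    n_fit_atoms: int

    def apply(self, xyz) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.rotation.T + self.translation


def superpose(mobile_xyz, reference_xyz) -> SuperpositionResult:
    """Kabsch least-squares rigid-body superposition (proper rotation only).

    Both inputs are (n, 3) arrays of paired atom positions, n >= 3 and not
    collinear.
    """
    x = np.asarray(mobile_xyz, dtype=float)
    y = np.asarray(reference_xyz, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise DegenerateGeometryError("paired (n, 3) coordinate arrays required")
    n = x.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 atom pairs")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2:
        raise DegenerateGeometryError("fitting atoms are collinear")
    rot, _ = Rotation.align_vectors(y0, x0)
    R = rot.as_matrix()
    t = yc - R @ xc
    fitted = x0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y0) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, fit_rmsd=rmsd, n_fit_atoms=n)


def pair_atoms(
    mobile: Structure,
    reference: Structure,
    atom_mode: str = "CA",
    residues=None,
    offset: int = 0,
):
    """Pair atoms of two structures by (residue number, atom name).

    ``atom_mode`` is ``"CA"`` (alpha carbons) or ``"all-heavy"``;
    ``residues`` optionally restricts to a set of residue numbers (of the
    reference); ``offset`` is added to mobile residue numbers before
    matching (sequence-offset reconciliation between constructs).
    Returns (mobile_atoms, reference_atoms) as equal-length lists.
    """
    if atom_mode not in ("CA", "all-heavy"):
        raise ValueError("atom_mode must be 'CA' or 'all-heavy'")

    def index(struct: Structure, shift: int):
        table = {}
        for a in struct.protein_atoms:
            if atom_mode == "CA" and a.atom_name != "CA":
                continue
            table[(a.residue_seq + shift, a.atom_name)] = a
        return table

    mob = index(mobile, offset)
    ref = index(reference, 0)
    keys = sorted(set(mob) & set(ref))
    if residues is not None:
        residues = set(residues)
        keys = [k for k in keys if k[0] in residues]
    return [mob[k] for k in keys], [ref[k] for k in keys]


def superpose_structures(
    mobile: Structure,
    reference: Structure,
    atom_mode: str = "CA",
    residues=None,
    offset: int = 0,
) -> SuperpositionResult:
    """Superpose two structures on atoms paired by residue number/name."""
    ma, ra = pair_atoms(mobile, reference, atom_mode, residues, offset)
    if len(ma) < 3:
        raise DegenerateGeometryError(
            f"only {len(ma)} paired atoms between '{mobile.id}' and "
            f"'{reference.id}'"
        )
    return superpose([a.position for a in ma], [a.position for a in ra])


def rmsd_subset(
    mobile: Structure,
    reference: Structure,
    transform: SuperpositionResult,
    residues,
    atom_mode: str = "all-heavy",
    offset: int = 0,
) -> float:
    """RMSD over a residue selection after applying an existing transform.

    Atoms are paired by (residue number, atom name); the transform is the
    one obtained from a (typically larger) fitting selection, so this
    reports how much the selected residues deviate in the common frame.
    """
    ma, ra = pair_atoms(mobile, reference, atom_mode, residues, offset)
    if not ma:
        raise DegenerateGeometryError("selection pairs no atoms")
    mx = transform.apply([a.position for a in ma])
    rx = np.array([a.position for a in ra], dtype=float)
    return float(np.sqrt(np.mean(np.sum((mx - rx) ** 2, axis=1))))
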