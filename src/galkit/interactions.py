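"""Polar protein-ligand contacts, water bridges, stacking, table diffing.

The hydrogen-bond criterion is purely distance based: any ligand N/O atom
within ``cutoff`` (default 3.5 A) of a protein N/O atom counts as a polar
contact, with no angular term and no donor/acceptor typing by default.
This mirrors the distance tables produced by interactive viewers on
~2 A crystal structures; a ``strict`` mode restricting contacts to
chemically plausible donor/acceptor pairs is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    DegenerateGeometryError,
    GalkitError,
    MissingAtomError,
    UndefinedAverageError,
)
from .structure_io import (
    AtomRecord,
    CorrespondenceMap,
    GlycanLigand,
    Structure,
)

DEFAULT_HBOND_CUTOFF = 3.5
STACKING_CUTOFF = 5.5

# carbon-bound oxygens that cannot donate: used only in strict mode
_CARBONYL_ONLY = {("ASN", "OD1"), ("GLN", "OE1"), ("ASP", "OD1"), ("ASP", "OD2"),
                  ("GLU", "OE1"), ("GLU", "OE2")}


def _round2(x: float) -> float:
    """Round half-up to 2 decimals, the table-output convention."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class PolarContact:
    ligand_moiety: str  # "GAL" or "GlcNAc"
    ligand_atom: str
    residue_name: str
    residue_seq: int
    protein_atom: str
    distance: float  # A, rounded half-up to 0.01
    via_water: bool = False
    water_id: int | None = None


@dataclass
class ContactTable:
    """Table-style summary of polar contacts for one complex."""

    complex_id: str
    contacts: list[PolarContact]
    linkage: str | None = None
    galectin: str | None = None

    def moiety_contacts(self, moiety: str) -> list[PolarContact]:
        return [c for c in self.contacts if c.ligand_moiety == moiety and not c.via_water]

    @property
    def avg_gal(self) -> float | None:
        try:
            return average_moiety_distance(self, "GAL")
        except UndefinedAverageError:
            return None

    @property
    def avg_glcnac(self) -> float | None:
        try:
            return average_moiety_distance(self, "GlcNAc")
        except UndefinedAverageError:
            return None

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "complex_id": self.complex_id,
                "linkage": self.linkage or "",
                "galectin": self.galectin or "",
                "ligand_moiety": c.ligand_moiety,
                "ligand_atom": c.ligand_atom,
                "residue_name": c.residue_name,
                "residue_seq": c.residue_seq,
                "protein_atom": c.protein_atom,
                "distance_A": c.distance,
                "via_water": c.via_water,
                "water_id": "" if c.water_id is None else c.water_id,
            }
            for c in self.contacts
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ContactTable":
        contacts = [
            PolarContact(
                ligand_moiety=r.ligand_moiety,
                ligand_atom=r.ligand_atom,
                residue_name=r.residue_name,
                residue_seq=int(r.residue_seq),
                protein_atom=r.protein_atom,
                distance=float(r.distance_A),
                via_water=bool(r.via_water),
                water_id=None if r.water_id in ("", None) or pd.isna(r.water_id)
                else int(r.water_id),
            )
            for r in df.itertuples()
        ]
        first = df.iloc[0] if len(df) else {}
        return cls(
            complex_id=str(first.get("complex_id", "")),
            contacts=contacts,
            linkage=str(first.get("linkage", "")) or None,
            galectin=str(first.get("galectin", "")) or None,
        )


def find_polar_contacts(
    protein: Structure,
    ligand: GlycanLigand,
    cutoff: float = DEFAULT_HBOND_CUTOFF,
    strict: bool = False,
    galectin: str | None = None,
) -> ContactTable:
    """Enumerate ligand N/O <-> protein N/O pairs within ``cutoff``.

    Waters are excluded (see :func:`find_water_bridges` for bridges) and so
    are the ligand residues themselves. Distances are reported rounded
    half-up to 0.01 A.
    """
    if not (2.2 < cutoff <= 4.5):
        raise ValueError(f"cutoff {cutoff} outside the sane range (2.2, 4.5]")
    lig_polar = ligand.polar_atoms()
    if not lig_polar:
        raise GalkitError("ligand has no polar (N/O) atoms")
    prot_polar = [
        a
        for a in protein.protein_atoms
        if a.is_polar and not a.is_water
    ]
    contacts: list[PolarContact] = []
    if prot_polar:
        tree = cKDTree(np.array([a.position for a in prot_polar]))
        for moiety, la in lig_polar:
            for j in tree.query_ball_point(la.xyz, cutoff):
                pa = prot_polar[j]
                if strict and not _plausible_pair(la, pa):
                    continue
                d = float(np.linalg.norm(la.xyz - pa.xyz))
                if d <= cutoff:
                    contacts.append(
                        PolarContact(
                            ligand_moiety=moiety,
                            ligand_atom=la.atom_name,
                            residue_name=pa.residue_name,
                            residue_seq=pa.residue_seq,
                            protein_atom=pa.atom_name,
                            distance=_round2(d),
                        )
                    )
    contacts.sort(
        key=lambda c: (c.ligand_moiety, c.ligand_atom, c.residue_seq, c.protein_atom)
    )
    return ContactTable(
        complex_id=protein.id,
        contacts=contacts,
        linkage=ligand.linkage,
        galectin=galectin,
    )


def _plausible_pair(la: AtomRecord, pa: AtomRecord) -> bool:
    """Strict mode: reject carbonyl-O/carboxylate-O pairs where neither
    side can donate (both oxygens carbon-bound without hydroxyl H)."""
    lig_can_donate = la.element == "O" or la.element == "N"  # sugar OH/NH
    prot_carbonyl = (pa.residue_name, pa.atom_name) in _CARBONYL_ONLY or (
        pa.atom_name == "O"
    )
    if la.element == "O" and prot_carbonyl:
        # sugar hydroxyl can still donate to a carbonyl
        return lig_can_donate
    return True


def average_moiety_distance(t: ContactTable, moiety: str) -> float:
    """Arithmetic mean of the direct (non-water) contact distances of one
    sugar moiety, reported to 0.01 A."""
    if moiety not in ("GAL", "GlcNAc"):
        raise ValueError("moiety must be 'GAL' or 'GlcNAc'")
    dists = [c.distance for c in t.moiety_contacts(moiety)]
    if not dists:
        raise UndefinedAverageError(f"no direct contacts for moiety {moiety}")
    return _round2(float(np.mean(dists)))


# ---------------------------------------------------------------------------
# water bridges


@dataclass(frozen=True)
class WaterBridge:
    water_chain: str
    water_seq: int
    ligand_contacts: tuple[tuple[str, str, float], ...]  # (moiety, atom, dist)
    protein_contacts: tuple[tuple[str, int, str, float], ...]  # (res, seq, atom, dist)


def find_water_bridges(
    s: Structure, ligand: GlycanLigand, cutoff: float = DEFAULT_HBOND_CUTOFF
) -> list[WaterBridge]:
    """Waters hydrogen-bonded simultaneously to the ligand and the protein.

    A bridge requires the water oxygen within ``cutoff`` of at least one
    ligand polar atom and at least one protein polar atom. Structures
    without waters yield an empty list.
    """
    waters = [a for a in s.water_atoms if a.element == "O"]
    if not waters:
        return []
    lig_polar = ligand.polar_atoms()
    prot_polar = [a for a in s.protein_atoms if a.is_polar]
    bridges = []
    for w in waters:
        lc = []
        for moiety, la in lig_polar:
            d = float(np.linalg.norm(w.xyz - la.xyz))
            if d <= cutoff:
                lc.append((moiety, la.atom_name, _round2(d)))
        if not lc:
            continue
        pc = []
        for pa in prot_polar:
            d = float(np.linalg.norm(w.xyz - pa.xyz))
            if d <= cutoff:
                pc.append((pa.residue_name, pa.residue_seq, pa.atom_name, _round2(d)))
        if not pc:
            continue
        bridges.append(
            WaterBridge(
                water_chain=w.chain_id,
                water_seq=w.residue_seq,
                ligand_contacts=tuple(sorted(lc)),
                protein_contacts=tuple(sorted(pc)),
            )
        )
    bridges.sort(key=lambda b: (b.water_chain, b.water_seq))
    return bridges


def steric_clash_distance(probe_xyz, target_xyz) -> float:
    """Minimum heavy-atom distance from a (transformed) probe atom to a set
    of target atoms.

    Used to test whether the C6-hydroxymethyl oxygen of a superposed
    type-1 ligand would collide with the ordered water of a type-2
    complex.
    """
    targets = np.atleast_2d(np.asarray(target_xyz, dtype=float))
    if targets.size == 0:
        raise GalkitError("empty target atom set")
    probe = np.asarray(probe_xyz, dtype=float)
    return float(np.min(np.linalg.norm(targets - probe, axis=1)))


# ---------------------------------------------------------------------------
# aromatic stacking

TRP_RING_ATOMS = ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2")


@dataclass(frozen=True)
class StackingContact:
    present: bool
    centroid_distance: float
    interplanar_angle: float  # degrees in [0, 90]


def _plane_normal(xyz: np.ndarray) -> np.ndarray:
    centered = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def stacking_contact(
    trp_atoms: list[AtomRecord] | dict[str, AtomRecord],
    ring_xyz,
    cutoff: float = STACKING_CUTOFF,
) -> StackingContact:
    """Tryptophan indole vs sugar-ring stacking, by ring-centroid distance.

    ``present`` iff the centroid separation is at most ``cutoff``
    (default 5.5 A); the interplanar angle between the two best-fit ring
    planes is reported alongside.
    """
    if isinstance(trp_atoms, dict):
        table = trp_atoms
    else:
        table = {a.atom_name: a for a in trp_atoms}
    missing = [n for n in TRP_RING_ATOMS if n not in table]
    if missing:
        raise MissingAtomError(f"Trp ring atoms missing: {missing}")
    trp_xyz = np.array([table[n].position for n in TRP_RING_ATOMS], dtype=float)
    sugar = np.asarray(ring_xyz, dtype=float)
    if sugar.ndim != 2 or sugar.shape[0] < 4:
        raise MissingAtomError("sugar ring needs >= 4 atoms")
    d = float(np.linalg.norm(trp_xyz.mean(axis=0) - sugar.mean(axis=0)))
    cosang = abs(float(np.dot(_plane_normal(trp_xyz), _plane_normal(sugar))))
    angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    return StackingContact(present=d <= cutoff, centroid_distance=d,
                           interplanar_angle=angle)


# ---------------------------------------------------------------------------
# table diffing across complexes

# GlcNAc atom equivalence between linkage types: the free 4-OH of a type-1
# ligand sits where the free 3-OH of a type-2 ligand sits (psi-shift
# mapping); the acetamido N2 and the 6-OH are positionally conserved; the
# type-1 O3 / type-2 O4 are the glycosidic oxygens and map to each other.
_GLCNAC_CANONICAL = {
    "beta1_3": {"O4": "O4~O3", "N2": "N2", "O6": "O6", "O3": "glycosidic"},
    "beta1_4": {"O3": "O4~O3", "N2": "N2", "O6": "O6", "O4": "glycosidic"},
}

# acidic sidechain oxygens align across Asp/Glu
_PROTEIN_ATOM_CANONICAL = {"OD1": "OE1", "OD2": "OE2", "ND1": "NE1"}


@dataclass(frozen=True)
class ContactDelta:
    ligand_key: str
    protein_role: str
    protein_atom: str
    distance_a: float
    distance_b: float
    delta: float


@dataclass
class ContactTableDiff:
    paired: list[ContactDelta]
    only_a: list[PolarContact]
    only_b: list[PolarContact]

    def mean_delta(self, moiety_prefix: str | None = None) -> float:
        rows = self.paired
        if moiety_prefix is not None:
            rows = [r for r in rows if r.ligand_key.startswith(moiety_prefix)]
        if not rows:
            raise UndefinedAverageError("no paired rows")
        return float(np.mean([r.delta for r in rows]))


def _canonical_key(c: PolarContact, linkage: str, cmap: CorrespondenceMap):
    if c.ligand_moiety == "GAL":
        lig = f"GAL:{c.ligand_atom}"
    else:
        mapped = _GLCNAC_CANONICAL.get(linkage, {}).get(c.ligand_atom, c.ligand_atom)
        lig = f"GlcNAc:{mapped}"
    try:
        entry = cmap.lookup_any(c.residue_seq)
        role = entry.role
    except Exception:
        role = f"{c.residue_name}{c.residue_seq}"
    atom = _PROTEIN_ATOM_CANONICAL.get(c.protein_atom, c.protein_atom)
    return (lig, role, atom)


def diff_contact_tables(
    a: ContactTable, b: ContactTable, cmap: CorrespondenceMap
) -> ContactTableDiff:
    """Pair two contact tables across complexes and report distance deltas.

    Rows are matched on (equivalent ligand atom, protein residue role via
    the correspondence map, canonicalized protein atom name); deltas are
    a minus b. Unmatched rows are listed separately.
    """
    if not a.contacts or not b.contacts:
        raise GalkitError("both contact tables must be non-empty")
    la = a.linkage or "beta1_3"
    lb = b.linkage or "beta1_4"
    index_a = {}
    for c in a.contacts:
        if c.via_water:
            continue
        index_a.setdefault(_canonical_key(c, la, cmap), c)
    index_b = {}
    for c in b.contacts:
        if c.via_water:
            continue
        index_b.setdefault(_canonical_key(c, lb, cmap), c)
    paired = []
    for key in sorted(set(index_a) & set(index_b)):
        ca, cb = index_a[key], index_b[key]
        paired.append(
            ContactDelta(
                ligand_key=key[0],
                protein_role=key[1],
                protein_atom=key[2],
                distance_a=ca.distance,
                distance_b=cb.distance,
                delta=round(ca.distance - cb.distance, 2),
            )
        )
    only_a = [index_a[k] for k in sorted(set(index_a) - set(index_b))]
    only_b = [index_b[k] for k in sorted(set(index_b) - set(index_a))]
    return ContactTableDiff(paired=paired, only_a=only_a, only_b=only_b)
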