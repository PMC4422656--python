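"""Coordinate I/O and binding-site bookkeeping for galectin-glycan complexes.

Reads PDB / PDBx-mmCIF files (via gemmi) into a flat atom-record model,
selects single protomers out of crystallographic dimers, identifies the
bound LacNAc disaccharide and its glycosidic linkage type, and provides the
built-in residue-correspondence map between human galectin-1, the
galectin-3 CRD and galectin-7 binding sites.

Conventions
-----------
* Hydrogens are ignored everywhere; all downstream criteria are
  heavy-atom based (crystal structures at ~2 A carry no hydrogens).
* Alternate locations are resolved to a single conformer per atom:
  highest occupancy wins, ties go to altloc 'A' (alphabetically first).
* Residue numbers are taken verbatim from the coordinate file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import (
    AmbiguousLinkageError,
    ChainNotFoundError,
    EmptyStructureError,
    GlycanNotFoundError,
    MissingAtomError,
    ParseError,
    ResidueLookupError,
)

# wwPDB chemical-component codes accepted for the two sugar moieties;
# overridable through the residue_names= argument of find_glycan().
DEFAULT_SUGAR_NAMES = {
    "GAL": frozenset({"GAL", "GLA"}),
    "GlcNAc": frozenset({"NAG", "NDG"}),
}

WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD"})

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL MSE".split()
)

# C1(Gal)-O(GlcNAc) separations below this are treated as a covalent
# glycosidic bond.
ANOMERIC_BOND_CUTOFF = 1.8


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a coordinate file after altloc resolution."""

    chain_id: str
    residue_name: str
    residue_seq: int
    atom_name: str
    element: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    is_water: bool = False
    het: bool = False

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    @property
    def is_polar(self) -> bool:
        return self.element in ("N", "O")

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.residue_name, self.residue_seq)


@dataclass
class Structure:
    """A parsed coordinate set: a flat list of heavy-atom records."""

    id: str
    atoms: list[AtomRecord]
    source_format: str = "pdb"

    def __post_init__(self):
        if not self.atoms:
            raise EmptyStructureError(f"structure '{self.id}' has no atoms")
        seen = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_seq, a.atom_name, a.altloc)
            if key in seen:
                raise ParseError(f"duplicate atom record {key} in '{self.id}'")
            seen.add(key)

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def coords(self, atoms: Sequence[AtomRecord] | None = None) -> np.ndarray:
        src = self.atoms if atoms is None else atoms
        return np.array([a.position for a in src], dtype=float)

    def select(self, predicate) -> list[AtomRecord]:
        return [a for a in self.atoms if predicate(a)]

    @property
    def protein_atoms(self) -> list[AtomRecord]:
        return self.select(lambda a: a.residue_name in STANDARD_AMINO_ACIDS)

    @property
    def water_atoms(self) -> list[AtomRecord]:
        return self.select(lambda a: a.is_water)

    def residue_atoms(self, chain_id: str, residue_seq: int) -> list[AtomRecord]:
        out = [
            a
            for a in self.atoms
            if a.chain_id == chain_id and a.residue_seq == residue_seq
        ]
        if not out:
            raise ResidueLookupError(
                f"residue {chain_id}:{residue_seq} not in '{self.id}'"
            )
        return out

    def get_atom(
        self, chain_id: str, residue_seq: int, atom_name: str
    ) -> AtomRecord:
        for a in self.atoms:
            if (
                a.chain_id == chain_id
                and a.residue_seq == residue_seq
                and a.atom_name == atom_name
            ):
                return a
        raise MissingAtomError(
            f"atom {chain_id}:{residue_seq}:{atom_name} not in '{self.id}'"
        )

    def residues(self) -> list[tuple[str, str, int]]:
        """Ordered unique (chain, residue_name, residue_seq) triples."""
        seen: dict[tuple[str, str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_name, a.residue_seq), None)
        return list(seen)


@dataclass(frozen=True)
class ResidueRef:
    """Lightweight reference to a residue inside a Structure."""

    chain_id: str
    residue_name: str
    residue_seq: int


@dataclass
class GlycanLigand:
    """The bound disaccharide: galactose ring + GlcNAc ring + linkage.

    ``linkage`` is ``"beta1_3"`` when C1 of Gal bonds O3 of GlcNAc (type-1
    LacNAc) and ``"beta1_4"`` when it bonds O4 (type-2 LacNAc).
    Atom dictionaries map atom name -> AtomRecord for each residue.
    """

    gal: ResidueRef
    glcnac: ResidueRef
    gal_atoms: dict[str, AtomRecord]
    glcnac_atoms: dict[str, AtomRecord]
    linkage: str
    anomeric_bond: tuple[str, str, float]  # (C1 name, GlcNAc O name, dist A)
    source_id: str = ""

    RING_ORDER = ("O5", "C1", "C2", "C3", "C4", "C5")

    def gal_ring_coords(self) -> np.ndarray:
        return _ring_coords(self.gal_atoms, self.gal)

    def glcnac_ring_coords(self) -> np.ndarray:
        return _ring_coords(self.glcnac_atoms, self.glcnac)

    def atom(self, moiety: str, name: str) -> AtomRecord:
        table = self.gal_atoms if moiety == "GAL" else self.glcnac_atoms
        try:
            return table[name]
        except KeyError:
            raise MissingAtomError(f"{moiety} atom '{name}' missing") from None

    def polar_atoms(self) -> list[tuple[str, AtomRecord]]:
        out = []
        for moiety, table in (("GAL", self.gal_atoms), ("GlcNAc", self.glcnac_atoms)):
            for a in table.values():
                if a.is_polar:
                    out.append((moiety, a))
        return out


def _ring_coords(atoms: dict[str, AtomRecord], ref: ResidueRef) -> np.ndarray:
    missing = [n for n in GlycanLigand.RING_ORDER if n not in atoms]
    if missing:
        raise MissingAtomError(
            f"ring atoms {missing} missing from {ref.residue_name} {ref.residue_seq}"
        )
    return np.array(
        [atoms[n].position for n in GlycanLigand.RING_ORDER], dtype=float
    )


# ---------------------------------------------------------------------------
# reading / writing


def _guess_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt not in ("pdb", "mmcif", "cif"):
            raise ParseError(f"unknown format '{format}'")
        return "mmcif" if fmt == "cif" else fmt
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def load_structure(
    path: str | Path, format: str | None = None, id: str | None = None
) -> Structure:
    """Read a PDB or PDBx/mmCIF file into a :class:`Structure`.

    All ATOM/HETATM heavy-atom records of the first model are retained;
    waters are flagged; alternate locations are resolved to the
    highest-occupancy conformer (ties break to the alphabetically first
    altloc).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    fmt = _guess_format(path, format)
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no model")

    model = st[0]
    records: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            is_water = res.name in WATER_NAMES or res.is_water()
            het = res.het_flag == "H" or res.name not in STANDARD_AMINO_ACIDS
            # altloc resolution: per atom name keep best conformer
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                alt = atom.altloc if atom.altloc not in ("\x00", "") else ""
                prev = by_name.get(atom.name)
                if prev is None:
                    by_name[atom.name] = atom
                    continue
                prev_alt = prev.altloc if prev.altloc not in ("\x00", "") else ""
                if (atom.occ, _alt_rank(alt)) > (prev.occ, _alt_rank(prev_alt)):
                    by_name[atom.name] = atom
            for atom in by_name.values():
                alt = atom.altloc if atom.altloc not in ("\x00", "") else ""
                records.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        atom_name=atom.name,
                        element=atom.element.name,
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=float(atom.occ),
                        altloc=alt,
                        is_water=is_water,
                        het=het,
                    )
                )
    if not records:
        raise EmptyStructureError(f"{path} contains no heavy atoms")
    return Structure(id=id or (st.name or path.stem), atoms=records, source_format=fmt)


def _alt_rank(alt: str) -> float:
    """Tie-break so that smaller altloc letters win at equal occupancy."""
    if alt == "":
        return 0.0
    return -ord(alt)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a normalized PDB file (used for fixtures and round-trips)."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for rec in structure.atoms:
        if rec.chain_id not in chains:
            chains[rec.chain_id] = gemmi.Chain(rec.chain_id)
        chain = chains[rec.chain_id]
        res = None
        if len(chain) > 0:
            last = chain[len(chain) - 1]
            if last.seqid.num == rec.residue_seq and last.name == rec.residue_name:
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = rec.residue_name
            res.seqid = gemmi.SeqId(rec.residue_seq, " ")
            res.het_flag = "H" if (rec.het or rec.is_water) else "A"
            chain.add_residue(res)
            res = chain[len(chain) - 1]
        atom = gemmi.Atom()
        atom.name = rec.atom_name
        atom.element = gemmi.Element(rec.element)
        atom.pos = gemmi.Position(*rec.position)
        atom.occ = rec.occupancy
        atom.altloc = rec.altloc if rec.altloc else "\x00"
        res.add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# protomer selection


def select_protomer(s: Structure, chain: str) -> Structure:
    """Extract one protomer: the chain's protein atoms plus the ligand and
    water residues whose nearest protein atom belongs to that chain.

    Hetero/water residues are assigned to the chain owning the nearest
    protein atom, following the one-ligand-per-protomer layout of the
    crystal dimers.
    """
    if chain not in s.chains:
        raise ChainNotFoundError(f"chain '{chain}' not in structure '{s.id}'")
    protein = s.protein_atoms
    if not protein:
        raise EmptyStructureError(f"structure '{s.id}' has no protein atoms")
    prot_xyz = np.array([a.position for a in protein])
    prot_chain = np.array([a.chain_id for a in protein])

    kept: list[AtomRecord] = [
        a
        for a in protein
        if a.chain_id == chain
    ]
    # group non-protein residues and assign each to its nearest chain
    hetero: dict[tuple[str, str, int], list[AtomRecord]] = {}
    for a in s.atoms:
        if a.residue_name in STANDARD_AMINO_ACIDS:
            continue
        hetero.setdefault((a.chain_id, a.residue_name, a.residue_seq), []).append(a)
    for _, atoms in hetero.items():
        xyz = np.array([a.position for a in atoms])
        d = np.linalg.norm(prot_xyz[None, :, :] - xyz[:, None, :], axis=2)
        owner = prot_chain[np.unravel_index(np.argmin(d), d.shape)[1]]
        if owner == chain:
            kept.extend(atoms)
    return Structure(id=f"{s.id}:{chain}", atoms=kept, source_format=s.source_format)


# ---------------------------------------------------------------------------
# glycan identification


def find_glycans(
    s: Structure, residue_names: dict[str, Iterable[str]] | None = None
) -> list[GlycanLigand]:
    """Find all bound Gal-GlcNAc disaccharides and their linkage types."""
    names = dict(DEFAULT_SUGAR_NAMES)
    if residue_names:
        names.update({k: frozenset(v) for k, v in residue_names.items()})

    residues: dict[tuple[str, str, int], dict[str, AtomRecord]] = {}
    for a in s.atoms:
        residues.setdefault((a.chain_id, a.residue_name, a.residue_seq), {})[
            a.atom_name
        ] = a

    gals = {k: v for k, v in residues.items() if k[1] in names["GAL"]}
    nags = {k: v for k, v in residues.items() if k[1] in names["GlcNAc"]}
    if not gals or not nags:
        raise GlycanNotFoundError(
            f"no candidate sugar residues in '{s.id}' "
            f"(looked for GAL in {sorted(names['GAL'])}, "
            f"GlcNAc in {sorted(names['GlcNAc'])})"
        )

    ligands = []
    for gkey, gatoms in gals.items():
        if "C1" not in gatoms:
            continue
        c1 = gatoms["C1"].xyz
        for nkey, natoms in nags.items():
            bonded = {}
            for oxy in ("O3", "O4"):
                if oxy in natoms:
                    d = float(np.linalg.norm(natoms[oxy].xyz - c1))
                    if d < ANOMERIC_BOND_CUTOFF:
                        bonded[oxy] = d
            if not bonded:
                continue
            if len(bonded) == 2:
                raise AmbiguousLinkageError(
                    f"both O3 ({bonded['O3']:.2f} A) and O4 ({bonded['O4']:.2f} A) "
                    f"of {nkey} are within bond distance of C1 of {gkey}"
                )
            oxy, dist = next(iter(bonded.items()))
            ligands.append(
                GlycanLigand(
                    gal=ResidueRef(gkey[0], gkey[1], gkey[2]),
                    glcnac=ResidueRef(nkey[0], nkey[1], nkey[2]),
                    gal_atoms=dict(gatoms),
                    glcnac_atoms=dict(natoms),
                    linkage="beta1_3" if oxy == "O3" else "beta1_4",
                    anomeric_bond=("C1", oxy, round(dist, 3)),
                    source_id=s.id,
                )
            )
    if not ligands:
        raise GlycanNotFoundError(
            f"sugar residues present in '{s.id}' but no C1(Gal)-O3/O4(GlcNAc) "
            f"bond under {ANOMERIC_BOND_CUTOFF} A"
        )
    # deterministic order, independent of atom-record order
    ligands.sort(key=lambda g: (g.gal.chain_id, g.gal.residue_seq))
    return ligands


def find_glycan(
    s: Structure, residue_names: dict[str, Iterable[str]] | None = None
) -> GlycanLigand:
    """Find the single bound disaccharide (use after select_protomer)."""
    ligands = find_glycans(s, residue_names)
    if len(ligands) > 1:
        raise AmbiguousLinkageError(
            f"{len(ligands)} disaccharides found in '{s.id}'; "
            "select a protomer first or use find_glycans()"
        )
    return ligands[0]


# ---------------------------------------------------------------------------
# cross-galectin residue correspondence


@dataclass(frozen=True)
class CorrespondenceEntry:
    hGal1: tuple[str, int]
    hGal3: tuple[str, int]
    hGal7: tuple[str, int]
    role: str


GALECTINS = ("hGal1", "hGal3", "hGal7")

_CORRESPONDENCE = (
    CorrespondenceEntry(("HIS", 44), ("HIS", 158), ("HIS", 49), "Gal O4 hydrogen bond"),
    CorrespondenceEntry(("ASN", 46), ("ASN", 160), ("ASN", 51), "Gal O4 hydrogen bond"),
    CorrespondenceEntry(
        ("ARG", 48), ("ARG", 162), ("ARG", 53),
        "central arginine; Gal O4/O5 and GlcNAc hydroxyl contacts; first "
        "basic residue of the salt-bridge quartet",
    ),
    CorrespondenceEntry(
        ("ASP", 54), ("GLU", 165), ("GLU", 58),
        "L4-loop acidic residue of the salt-bridge quartet (no direct sugar "
        "contact)",
    ),
    CorrespondenceEntry(("VAL", 59), ("VAL", 172), ("VAL", 60), "conserved contact"),
    CorrespondenceEntry(("ASN", 61), ("ASN", 174), ("ASN", 62), "Gal O6 hydrogen bond"),
    CorrespondenceEntry(
        ("TRP", 68), ("TRP", 181), ("TRP", 69), "galactose stacking (van der Waals)"
    ),
    CorrespondenceEntry(
        ("GLU", 71), ("GLU", 184), ("GLU", 72),
        "glutamate hydrogen-bonding GlcNAc/Gal hydroxyls; acidic member of "
        "the quartet's second pair",
    ),
    CorrespondenceEntry(
        ("ARG", 73), ("ARG", 186), ("ARG", 74),
        "second basic residue of the salt-bridge quartet",
    ),
)


@dataclass(frozen=True)
class CorrespondenceMap:
    """Built-in equivalences between hGal1 / hGal3-CRD / hGal7 residues."""

    entries: tuple[CorrespondenceEntry, ...] = _CORRESPONDENCE

    def lookup(self, galectin: str, residue_seq: int) -> CorrespondenceEntry:
        """Return the full triple containing the queried residue."""
        if galectin not in GALECTINS:
            raise ResidueLookupError(f"unknown galectin '{galectin}'")
        for e in self.entries:
            if getattr(e, galectin)[1] == residue_seq:
                return e
        raise ResidueLookupError(f"{galectin} residue {residue_seq} not in map")

    def lookup_any(self, residue_seq: int) -> CorrespondenceEntry:
        """Look a residue number up in any of the three galectins.

        The three numbering ranges are disjoint, so the number alone
        identifies the entry.
        """
        for e in self.entries:
            for g in GALECTINS:
                if getattr(e, g)[1] == residue_seq:
                    return e
        raise ResidueLookupError(f"residue {residue_seq} not in map")

    def galectin_of(self, residue_seq: int) -> str:
        for e in self.entries:
            for g in GALECTINS:
                if getattr(e, g)[1] == residue_seq:
                    return g
        raise ResidueLookupError(f"residue {residue_seq} not in map")

    def network_quartet(self, galectin: str) -> list[tuple[str, int]]:
        """The Arg-Asp/Glu-Glu-Arg quartet, in sequence order."""
        if galectin not in GALECTINS:
            raise ResidueLookupError(f"unknown galectin '{galectin}'")
        roles = [2, 3, 7, 8]  # Arg48-, Asp54/Glu-, Glu71-, Arg73-equivalents
        return [getattr(_CORRESPONDENCE[i], galectin) for i in roles]


def correspondence_map() -> CorrespondenceMap:
    """Return the built-in cross-galectin residue-correspondence table."""
    return CorrespondenceMap()
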