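"""Synthetic fixtures with exactly known geometry and binding truth.

Coordinate fixtures emulate a galectin binding site: a beta-linked
Gal-GlcNAc disaccharide built from ideal chair-ring templates by
internal-coordinate (NeRF) placement — so the requested glycosidic
torsions are achieved exactly — surrounded by protein sidechain
fragments (imidazole, guanidinium, carboxylate, amide, indole) and
ordered waters placed at requested distances. A random rigid transform
is applied last, so no analysis quantity may depend on the absolute
frame. Everything the generator decides is recorded in a manifest that
predicts the analysis outputs on the fixture.

Binding fixtures draw titration and competition data from the 1:1 and
coupled two-ligand equilibrium models at known dissociation constants,
with additive Gaussian noise.

Fixtures are geometric, not physical: rings use idealized bond lengths
(C-C 1.52 A, C-O 1.43 A) and fragments carry sidechain tips only.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .binding import (
    ASSAY_PRESETS,
    CompetitionMeasurement,
    TitrationData,
    simulate_equilibrium_competition,
)
from .errors import FixtureError
from .structure_io import AtomRecord, Structure

# covalent radii (A) used to reject unsatisfiable contact requests
_COVALENT_RADIUS = {"C": 0.76, "N": 0.71, "O": 0.66}

_RING_ORDER = ("O5", "C1", "C2", "C3", "C4", "C5")

# ideal chair constants (fixture-internal, declared in the manifest)
_CHAIR_RADIUS = 1.46
_CHAIR_Z = 0.25
_BOND_CO = 1.43
_BOND_CC = 1.52
_BOND_CN = 1.45
_ANGLE_TET = 109.5
_ANGLE_GLYCOSIDIC = 116.5


def _norm(v):
    return v / np.linalg.norm(v)


def nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d bonded to c with |cd| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (same sign convention as geometry.dihedral)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = _norm(c - b)
    n = _norm(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(tor),
         bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def chair_template() -> dict[str, np.ndarray]:
    """Ideal 4C1-like pyranose ring: six atoms on a puckered hexagon."""
    tmpl = {}
    for j, name in enumerate(_RING_ORDER):
        theta = math.pi / 3 * j
        tmpl[name] = np.array(
            [_CHAIR_RADIUS * math.cos(theta), _CHAIR_RADIUS * math.sin(theta),
             _CHAIR_Z * (-1) ** j]
        )
    return tmpl


def _tmpl_geometry(tmpl, names):
    """(bond, angle, torsion) of the last atom of a 4-name chain."""
    from .geometry import dihedral  # local import to avoid cycles

    a, b, c, d = (tmpl[n] for n in names)
    bond = float(np.linalg.norm(d - c))
    v1, v2 = b - c, d - c
    angle = math.degrees(
        math.acos(np.clip(np.dot(_norm(v1), _norm(v2)), -1, 1))
    )
    return bond, angle, dihedral(a, b, c, d)


def _ring_chain(start: str) -> list[str]:
    i = _RING_ORDER.index(start)
    return [_RING_ORDER[(i + k) % 6] for k in range(6)]


# ---------------------------------------------------------------------------
# fixture specs


@dataclass(frozen=True)
class ContactSpec:
    """Request one engineered ligand-protein polar contact."""

    moiety: str  # "GAL" | "GlcNAc"
    ligand_atom: str
    residue_name: str  # HIS / ARG / GLU / ASP / ASN / TRP
    residue_seq: int
    protein_atom: str  # the fragment atom placed at `distance`
    distance: float


@dataclass(frozen=True)
class WaterBridgeSpec:
    """Request a water bridging a ligand atom and a protein fragment."""

    moiety: str
    ligand_atom: str
    d_ligand: float
    residue_name: str
    residue_seq: int
    protein_atom: str
    d_protein: float
    water_seq: int = 301


@dataclass(frozen=True)
class SaltBridgeSpec:
    """Request an isolated basic-acidic pair of a given geometry class."""

    basic_name: str  # ARG
    basic_seq: int
    acidic_name: str  # GLU | ASP
    acidic_seq: int
    distance: float
    geometry: str  # "monodentate" | "bidentate"


@dataclass
class FixtureManifest:
    """Everything needed to predict the analysis outputs of a fixture."""

    seed: int
    linkage: str
    phi: float
    psi: float
    contacts: list[dict] = field(default_factory=list)
    water_bridges: list[dict] = field(default_factory=list)
    salt_bridges: list[dict] = field(default_factory=list)
    rotation: list = field(default_factory=list)
    translation: list = field(default_factory=list)
    n_atoms: int = 0
    constants: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "FixtureManifest":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# disaccharide construction


def build_disaccharide(linkage: str, phi: float, psi: float):
    """Build Gal + GlcNAc atom dictionaries achieving (phi, psi) exactly.

    Returns (gal_atoms, glcnac_atoms) as name -> position dicts. The
    galactose ring sits in the template frame; the GlcNAc ring is grown
    from the glycosidic oxygen by NeRF using the chair template's own
    internal coordinates, so the ring closes exactly and stays a chair.
    """
    if linkage not in ("beta1_3", "beta1_4"):
        raise FixtureError(f"unknown linkage '{linkage}'")
    tmpl = chair_template()
    gal = {k: v.copy() for k, v in tmpl.items()}

    def substituent(atoms, ring, idx, name, bond, offset=120.0):
        """Attach an exocyclic atom to ring position idx of a ring chain."""
        a, b, c = atoms[ring[idx - 2]], atoms[ring[idx - 1]], atoms[ring[idx]]
        _, _, tor_ring = _tmpl_geometry(
            {0: a, 1: b, 2: c, 3: atoms[ring[(idx + 1) % 6]]}, (0, 1, 2, 3)
        )
        atoms[name] = nerf(a, b, c, bond, _ANGLE_TET, tor_ring + offset)

    ring_g = list(_RING_ORDER)
    substituent(gal, ring_g, 2, "O2", _BOND_CO)
    substituent(gal, ring_g, 3, "O3", _BOND_CO)
    substituent(gal, ring_g, 4, "O4", _BOND_CO, offset=-120.0)  # axial-ish
    substituent(gal, ring_g, 5, "C6", _BOND_CC)
    gal["O6"] = nerf(gal["C4"], gal["C5"], gal["C6"], _BOND_CO, _ANGLE_TET, 180.0)

    glcnac: dict[str, np.ndarray] = {}
    o_link = "O3" if linkage == "beta1_3" else "O4"
    c_link = "C3" if linkage == "beta1_3" else "C4"
    # glycosidic oxygen off the galactose anomeric carbon (beta-ish spin)
    glcnac[o_link] = nerf(gal["C5"], gal["O5"], gal["C1"], 1.40, 108.0, -60.0)
    # phi places the linked GlcNAc carbon; psi the next ring carbon
    glcnac[c_link] = nerf(
        gal["O5"], gal["C1"], glcnac[o_link], _BOND_CO, _ANGLE_GLYCOSIDIC, phi
    )
    ring_n = _ring_chain(c_link)  # e.g. C3,C4,C5,O5,C1,C2
    nxt = ring_n[1]
    glcnac[nxt] = nerf(
        gal["C1"], glcnac[o_link], glcnac[c_link],
        float(np.linalg.norm(tmpl[nxt] - tmpl[ring_n[0]])), _ANGLE_TET, psi,
    )
    # continue around the ring with template internal coordinates; the
    # first torsion is referenced to the glycosidic oxygen with a fixed
    # tetrahedral offset, which only spins the ring about the first bond
    prev4 = [tmpl[ring_n[-1]], tmpl[ring_n[0]], tmpl[ring_n[1]], tmpl[ring_n[2]]]
    bond, angle, tor = _tmpl_geometry(
        {0: prev4[0], 1: prev4[1], 2: prev4[2], 3: prev4[3]}, (0, 1, 2, 3)
    )
    glcnac[ring_n[2]] = nerf(
        glcnac[o_link], glcnac[ring_n[0]], glcnac[ring_n[1]], bond, angle,
        tor - 120.0,
    )
    for k in range(3, 6):
        names = (ring_n[k - 3], ring_n[k - 2], ring_n[k - 1], ring_n[k])
        bond, angle, tor = _tmpl_geometry(tmpl, names)
        glcnac[ring_n[k]] = nerf(
            glcnac[names[0]], glcnac[names[1]], glcnac[names[2]], bond, angle, tor
        )
    # substituents: acetamido nitrogen, free hydroxyl, hydroxymethyl arm
    ring_std = list(_RING_ORDER)
    substituent(glcnac, ring_std, 2, "N2", _BOND_CN)
    if linkage == "beta1_3":
        substituent(glcnac, ring_std, 4, "O4", _BOND_CO)
    else:
        substituent(glcnac, ring_std, 3, "O3", _BOND_CO)
    substituent(glcnac, ring_std, 5, "C6", _BOND_CC)
    glcnac["O6"] = nerf(
        glcnac["C4"], glcnac["C5"], glcnac["C6"], _BOND_CO, _ANGLE_TET, 180.0
    )
    return gal, glcnac


# ---------------------------------------------------------------------------
# sidechain fragment templates (anchor atom at the origin, body toward -x)


def _his_fragment() -> dict[str, np.ndarray]:
    # planar imidazole pentagon, anchor NE2 at origin
    order = ("NE2", "CD2", "CG", "ND1", "CE1")
    radius = 1.37 / (2 * math.sin(math.pi / 5))
    center = np.array([-radius, 0.0, 0.0])
    return {
        name: center + radius * np.array(
            [math.cos(2 * math.pi * k / 5), math.sin(2 * math.pi * k / 5), 0.0]
        )
        for k, name in enumerate(order)
    }


def _guanidinium_fragment() -> dict[str, np.ndarray]:
    # anchor NH1 at origin, CZ on -x, NH2/NE fanning out at 120 degrees
    cz = np.array([-1.33, 0.0, 0.0])
    out = {"NH1": np.zeros(3), "CZ": cz}
    for name, sign in (("NH2", 1.0), ("NE", -1.0)):
        ang = math.radians(120.0) * sign
        out[name] = cz + 1.33 * np.array([math.cos(ang), math.sin(ang), 0.0])
    return out


def _carboxylate_fragment(cname: str, o1: str, o2: str, tail: str):
    # anchor O1 at origin, carboxyl C on -x, O2 and the tail carbon beyond
    cd = np.array([-1.25, 0.0, 0.0])
    ang2 = math.radians(180.0 - 126.0)
    o2pos = cd + 1.25 * np.array([-math.cos(ang2), math.sin(ang2), 0.0])
    tailpos = cd + 1.52 * np.array([-math.cos(math.radians(63.0)),
                                    -math.sin(math.radians(63.0)), 0.0])
    return {o1: np.zeros(3), cname: cd, o2: o2pos, tail: tailpos}


def _asn_fragment() -> dict[str, np.ndarray]:
    cg = np.array([-1.23, 0.0, 0.0])
    ang = math.radians(180.0 - 122.0)
    nd2 = cg + 1.33 * np.array([-math.cos(ang), math.sin(ang), 0.0])
    cb = cg + 1.52 * np.array([-math.cos(math.radians(60.0)),
                               -math.sin(math.radians(60.0)), 0.0])
    return {"OD1": np.zeros(3), "CG": cg, "ND2": nd2, "CB": cb}


def trp_indole_template() -> dict[str, np.ndarray]:
    """Planar indole ring (nine heavy atoms) centered at the origin."""
    hexa = {}
    for k, name in enumerate(("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")):
        ang = math.pi / 3 * k
        hexa[name] = 1.40 * np.array([math.cos(ang), math.sin(ang), 0.0])
    mid = (hexa["CD2"] + hexa["CE2"]) / 2
    out_dir = _norm(mid)  # pentagon fused on the CD2-CE2 edge
    perp = _norm(hexa["CE2"] - hexa["CD2"])
    hexa["NE1"] = mid + 1.15 * out_dir + 0.55 * perp
    hexa["CG"] = mid + 1.15 * out_dir - 0.55 * perp
    hexa["CD1"] = mid + 1.95 * out_dir
    centroid = np.mean(list(hexa.values()), axis=0)
    return {k: v - centroid for k, v in hexa.items()}


_FRAGMENTS = {
    "HIS": (_his_fragment, ("NE2", "ND1")),
    "ARG": (_guanidinium_fragment, ("NH1", "NH2", "NE")),
    "GLU": (lambda: _carboxylate_fragment("CD", "OE1", "OE2", "CG"),
            ("OE1", "OE2")),
    "ASP": (lambda: _carboxylate_fragment("CG", "OD1", "OD2", "CB"),
            ("OD1", "OD2")),
    "ASN": (_asn_fragment, ("OD1", "ND2")),
    "TRP": (trp_indole_template, ("NE1",)),
}


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def _rotation_to(direction: np.ndarray, spin: float) -> np.ndarray:
    """Rotation sending local +x to `direction`, then spinning about it."""
    x = np.array([1.0, 0.0, 0.0])
    d = _norm(direction)
    v = np.cross(x, d)
    c = float(np.dot(x, d))
    if np.linalg.norm(v) < 1e-12:
        base = np.eye(3) if c > 0 else np.diag([-1.0, 1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        base = np.eye(3) + vx + vx @ vx / (1 + c)
    ca, sa = math.cos(spin), math.sin(spin)
    k = d
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    spin_m = np.eye(3) * ca + sa * kx + (1 - ca) * np.outer(k, k)
    return spin_m @ base


def _place_fragment(residue_name, anchor_atom, target, away_dir, spin):
    builder, _ = _FRAGMENTS[residue_name]
    local = builder()
    if anchor_atom not in local:
        raise FixtureError(
            f"{residue_name} fragment has no atom '{anchor_atom}'"
        )
    # fragment bodies extend toward local -x; map that onto away_dir so
    # the body points away from whatever the anchor is contacting
    R = _rotation_to(-np.asarray(away_dir, dtype=float), spin)
    shift = local[anchor_atom]
    return {k: target + R @ (v - shift) for k, v in local.items()}


# ---------------------------------------------------------------------------
# the toy complex


def make_toy_complex(
    linkage: str = "beta1_3",
    phi: float = -60.0,
    psi: float = 135.0,
    contacts: tuple[ContactSpec, ...] = (),
    salt_bridges: tuple[SaltBridgeSpec, ...] = (),
    waters: tuple[WaterBridgeSpec, ...] = (),
    seed: int = 0,
    chain: str = "A",
    apply_transform: bool = True,
    structure_id: str | None = None,
    contact_cutoff: float = 3.5,
) -> tuple[Structure, FixtureManifest]:
    """Build a coordinate fixture with exactly known analysis outputs.

    The disaccharide achieves the requested (phi, psi) to well below
    0.01 degrees; each requested contact/water/salt bridge is placed at
    its exact distance, and placements are re-spun (seeded) until no
    unintended polar pair falls inside ``contact_cutoff``. A random rigid
    transform (recorded in the manifest) is applied last unless
    ``apply_transform`` is false.
    """
    if not (-180.0 < phi <= 180.0 and -180.0 < psi <= 180.0):
        raise FixtureError("phi and psi must lie in (-180, 180]")
    rng = np.random.default_rng(seed)
    gal, glcnac = build_disaccharide(linkage, phi, psi)
    ligand_atoms = {("GAL", k): v for k, v in gal.items()}
    ligand_atoms.update({("GlcNAc", k): v for k, v in glcnac.items()})
    centroid = np.mean(list(ligand_atoms.values()), axis=0)

    lig_polar = {
        key: pos for key, pos in ligand_atoms.items()
        if _element_of(key[1]) in ("N", "O")
    }

    manifest = FixtureManifest(
        seed=seed, linkage=linkage, phi=phi, psi=psi,
        constants={"C-C": _BOND_CC, "C-O": _BOND_CO,
                   "chair_radius": _CHAIR_RADIUS, "chair_z": _CHAIR_Z},
    )

    placed_fragments: list[tuple[str, int, dict[str, np.ndarray]]] = []

    def polar_ok(frag_atoms, intended):
        """No unintended fragment-N/O within contact_cutoff of ligand N/O."""
        for aname, pos in frag_atoms.items():
            if _element_of(aname) not in ("N", "O"):
                continue
            for key, lpos in lig_polar.items():
                d = float(np.linalg.norm(pos - lpos))
                if (aname, key) in intended:
                    continue
                if d <= contact_cutoff + 0.15:
                    return False
        return True

    for spec in contacts:
        if spec.residue_name not in _FRAGMENTS:
            raise FixtureError(f"no fragment template for {spec.residue_name}")
        lig_key = (spec.moiety, spec.ligand_atom)
        if lig_key not in ligand_atoms:
            raise FixtureError(f"ligand atom {lig_key} does not exist")
        rmin = (_COVALENT_RADIUS.get(_element_of(spec.ligand_atom), 0.7)
                + _COVALENT_RADIUS.get(_element_of(spec.protein_atom), 0.7))
        if spec.distance < rmin:
            raise FixtureError(
                f"contact distance {spec.distance} below covalent limit {rmin:.2f}"
            )
        lpos = ligand_atoms[lig_key]
        base_dir = _norm(lpos - centroid)
        ok = False
        for _try in range(60):
            jitter = rng.normal(scale=0.25, size=3)
            u = _norm(base_dir + jitter)
            target = lpos + spec.distance * u
            frag = _place_fragment(
                spec.residue_name, spec.protein_atom, target, u,
                rng.uniform(0, 2 * math.pi),
            )
            if polar_ok(frag, {(spec.protein_atom, lig_key)}):
                ok = True
                break
        if not ok:
            raise FixtureError(f"could not satisfy contact spec {spec}")
        placed_fragments.append((spec.residue_name, spec.residue_seq, frag))
        manifest.contacts.append(asdict(spec))

    water_records: list[tuple[int, np.ndarray]] = []
    for spec in waters:
        lig_key = (spec.moiety, spec.ligand_atom)
        if lig_key not in ligand_atoms:
            raise FixtureError(f"ligand atom {lig_key} does not exist")
        lpos = ligand_atoms[lig_key]
        base_dir = _norm(lpos - centroid)
        ok = False
        for _try in range(60):
            u = _norm(base_dir + rng.normal(scale=0.25, size=3))
            wpos = lpos + spec.d_ligand * u
            # avoid clashes with the rest of the ligand (incidental extra
            # hydrogen bonds are fine -- the water still forms one bridge)
            if any(
                np.linalg.norm(wpos - p) < 2.4
                for key, p in ligand_atoms.items() if key != lig_key
            ):
                continue
            # protein anchor off at ~105 degrees so it stays clear of the
            # ligand while staying within d_protein of the water
            perp = _norm(np.cross(u, rng.normal(size=3)))
            w_dir = _norm(
                math.cos(math.radians(105.0)) * (-u)
                + math.sin(math.radians(105.0)) * perp
            )
            target = wpos + spec.d_protein * w_dir
            frag = _place_fragment(
                spec.residue_name, spec.protein_atom, target, w_dir,
                rng.uniform(0, 2 * math.pi),
            )
            if not polar_ok(frag, set()):
                continue
            ok = True
            break
        if not ok:
            raise FixtureError(f"could not satisfy water spec {spec}")
        placed_fragments.append((spec.residue_name, spec.residue_seq, frag))
        water_records.append((spec.water_seq, wpos))
        manifest.water_bridges.append(asdict(spec))

    # isolated salt-bridge assemblies in well-separated zones
    zone_dirs = [np.array(v, dtype=float) for v in
                 ((0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1), (1, 0, 0))]
    if len(salt_bridges) > len(zone_dirs):
        raise FixtureError("at most five salt-bridge specs per fixture")
    for spec, zdir in zip(salt_bridges, zone_dirs):
        basic, acidic = _build_salt_bridge_pair(spec, rng)
        offset = centroid + 18.0 * zdir
        spin = _random_rotation(rng)
        basic = {k: offset + spin @ v for k, v in basic.items()}
        acidic = {k: offset + spin @ v for k, v in acidic.items()}
        placed_fragments.append((spec.basic_name, spec.basic_seq, basic))
        placed_fragments.append((spec.acidic_name, spec.acidic_seq, acidic))
        manifest.salt_bridges.append(asdict(spec))

    # assemble records
    records: list[AtomRecord] = []

    def add_residue(resname, resseq, atoms, het, is_water=False):
        for aname in sorted(atoms):
            pos = atoms[aname]
            records.append(
                AtomRecord(
                    chain_id=chain, residue_name=resname, residue_seq=resseq,
                    atom_name=aname, element=_element_of(aname),
                    position=(float(pos[0]), float(pos[1]), float(pos[2])),
                    het=het, is_water=is_water,
                )
            )

    for resname, resseq, frag in placed_fragments:
        add_residue(resname, resseq, frag, het=False)
    add_residue("GAL", 201, gal, het=True)
    add_residue("NAG", 202, glcnac, het=True)
    for wseq, wpos in water_records:
        add_residue("HOH", wseq, {"O": wpos}, het=True, is_water=True)

    R = np.eye(3)
    t = np.zeros(3)
    if apply_transform:
        R = _random_rotation(rng)
        t = rng.uniform(-20.0, 20.0, size=3)
        records = [
            _moved(a, R, t) for a in records
        ]
    manifest.rotation = np.round(R, 12).tolist()
    manifest.translation = np.round(t, 12).tolist()
    manifest.n_atoms = len(records)

    sid = structure_id or f"toy-{linkage}-{seed}"
    return Structure(id=sid, atoms=records, source_format="pdb"), manifest


def _moved(a: AtomRecord, R: np.ndarray, t: np.ndarray) -> AtomRecord:
    p = R @ np.asarray(a.position) + t
    return AtomRecord(
        chain_id=a.chain_id, residue_name=a.residue_name,
        residue_seq=a.residue_seq, atom_name=a.atom_name, element=a.element,
        position=(float(p[0]), float(p[1]), float(p[2])),
        occupancy=a.occupancy, altloc=a.altloc, is_water=a.is_water, het=a.het,
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _build_salt_bridge_pair(spec: SaltBridgeSpec, rng):
    """Local-frame construction of one basic-acidic pair.

    Monodentate: head-on single N-O contact, every other N-O pair beyond
    the 4.0 A detection cutoff. Bidentate: fork-fork, both designed N-O
    pairs at the requested distance.
    """
    if spec.basic_name != "ARG":
        raise FixtureError("only ARG basic fragments are supported")
    if spec.acidic_name not in ("GLU", "ASP"):
        raise FixtureError("acidic fragment must be GLU or ASP")
    o1, o2 = ("OE1", "OE2") if spec.acidic_name == "GLU" else ("OD1", "OD2")
    cname = "CD" if spec.acidic_name == "GLU" else "CG"
    tail = "CG" if spec.acidic_name == "GLU" else "CB"
    d = spec.distance
    if d < 2.2:
        raise FixtureError(f"salt-bridge distance {d} too short")
    if spec.geometry == "monodentate":
        basic = _guanidinium_fragment()  # NH1 at origin, body toward -x
        acidic = _place_fragment(
            spec.acidic_name, o1, np.array([d, 0.0, 0.0]),
            np.array([1.0, 0.0, 0.0]), 0.0,
        )
    elif spec.geometry == "bidentate":
        w_n = 1.33 * math.sin(math.radians(60.0))
        w_o = 1.25 * math.sin(math.radians(63.0))
        h = math.sqrt(max(d * d - (w_n - w_o) ** 2, 0.01))
        acidic = {
            o1: np.array([-w_o, 0.0, 0.0]),
            o2: np.array([w_o, 0.0, 0.0]),
            cname: np.array([0.0, -1.25 * math.cos(math.radians(63.0)), 0.0]),
        }
        acidic[tail] = acidic[cname] + np.array([0.0, -1.52, 0.0])
        cz_y = h + 1.33 * math.cos(math.radians(60.0))
        basic = {
            "NH1": np.array([-w_n, h, 0.0]),
            "NH2": np.array([w_n, h, 0.0]),
            "CZ": np.array([0.0, cz_y, 0.0]),
            "NE": np.array([0.0, cz_y + 1.33, 0.0]),
        }
    else:
        raise FixtureError(f"unknown geometry class '{spec.geometry}'")
    # verify the design achieves the class it claims
    from .saltbridge import classify_pairs

    pairs = []
    for nn in ("NE", "NH1", "NH2"):
        for oo in (o1, o2):
            dist = float(np.linalg.norm(basic[nn] - acidic[oo]))
            if dist <= 4.0:
                pairs.append((nn, oo, dist))
    if not pairs or classify_pairs(pairs) != spec.geometry:
        raise FixtureError(
            f"salt-bridge construction failed to realize {spec.geometry}"
        )
    return basic, acidic


def make_dimer_fixture(seed: int = 0):
    """Two protein chains plus one ligand sited nearer chain B.

    Used to exercise protomer selection: the disaccharide and a contact
    fragment sit in chain B's zone; chain A holds a distant fragment.
    """
    s, manifest = make_toy_complex(
        contacts=(ContactSpec("GAL", "O4", "HIS", 49, "NE2", 2.87),),
        seed=seed, chain="B", apply_transform=False,
    )
    far = _place_fragment(
        "ASN", "OD1", np.array([40.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]), 0.0
    )
    atoms = list(s.atoms)
    for aname in sorted(far):
        atoms.append(
            AtomRecord(
                chain_id="A", residue_name="ASN", residue_seq=10,
                atom_name=aname, element=_element_of(aname),
                position=tuple(map(float, far[aname])), het=False,
            )
        )
    return Structure(id=f"dimer-{seed}", atoms=atoms), manifest


# ---------------------------------------------------------------------------
# binding datasets


def make_binding_dataset(
    kd: float,
    amax: float = 1.0,
    a0: float = 0.0,
    n: int = 8,
    dilution_factor: float = 3.0,
    top_concentration: float = 3000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    response_type: str = "bli",
):
    """A dilution-series titration drawn from the 1:1 model plus noise.

    Defaults mirror the assay layout: eight 3-fold dilutions from a top
    concentration of 3 mM (3000 uM). Returns (TitrationData, truth dict).
    """
    if n < 4:
        raise FixtureError("need at least 4 points")
    if noise_sd < 0:
        raise FixtureError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    conc = top_concentration / dilution_factor ** np.arange(n)
    clean = a0 + amax * conc / (kd + conc)
    responses = clean + rng.normal(scale=noise_sd, size=n)
    truth = {
        "kd": kd, "amax": amax, "a0": a0, "noise_sd": noise_sd, "seed": seed,
        "concentrations": conc.tolist(),
    }
    return TitrationData(conc, responses, response_type), truth


def make_competition_dataset(
    kd_probe: float,
    kd_comp: float,
    stoichiometry="hGal3",
    noise_sd: float = 0.0,
    seed: int = 0,
    a0: float = 0.05,
    a_max: float = 0.25,
):
    """One competition measurement from the exact two-ligand equilibrium.

    ``stoichiometry`` is a preset name (hGal1/hGal3/hGal7, mirroring the
    assay concentrations: probe 0.1 uM; galectin 120/3/120 uM; competitor
    300/6/300 uM) or a dict with p_total/g_total/c_total. Returns
    (CompetitionMeasurement, truth dict); the truth flags near-saturated
    measurements where competition is barely detectable.
    """
    stoich = (
        dict(ASSAY_PRESETS[stoichiometry])
        if isinstance(stoichiometry, str)
        else dict(stoichiometry)
    )
    rng = np.random.default_rng(seed)
    state = simulate_equilibrium_competition(
        kd_probe, kd_comp, a0=a0, a_max=a_max, **stoich
    )
    a_comp = state.anisotropy + rng.normal(scale=noise_sd)
    a_comp = float(np.clip(a_comp, a0 + 1e-9, a_max - 1e-9))
    measurement = CompetitionMeasurement(
        a_competitor=a_comp, a0=a0, a_max=a_max, kd_probe=kd_probe, **stoich
    )
    truth = {
        "kd_comp": kd_comp, "kd_probe": kd_probe, "noise_sd": noise_sd,
        "seed": seed, "anisotropy_clean": state.anisotropy,
        "cg": state.cg,
        "weak_competition": bool(state.cg < 0.01 * stoich["g_total"]),
        **stoich,
    }
    return measurement, truth
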