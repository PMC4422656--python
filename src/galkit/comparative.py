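"""Comparative analysis of the deposited galectin-LacNAc crystal structures.

These routines reproduce the published structural comparison between the
type-1-LacNAc complexes (PDB 4XBL: hGal1, 4XBN: hGal3-CRD, 4XBQ: hGal7),
the type-2 comparators (1W6P, 1KJL, 5GAL) and the ligand-free hGal3-CRD
entry (3ZSM): average glycosidic torsions per linkage family, the psi
shift between the two families, the key Gal O4-His hydrogen bond, the
apo-vs-complex Calpha RMSD, the all-heavy-atom RMSD of the flexible
salt-bridge triad, and the clash distance between the superposed type-1
ligand's O6 and the type-2 complex's ordered water.

The deposited entries are inputs: this module only accepts a local
directory that contains them (``<ID>.pdb`` or ``<ID>.cif``, any case).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import GalkitError, MissingAtomError
from .geometry import (
    circular_mean,
    glycosidic_torsions,
    psi_shift,
    rmsd_subset,
    superpose_structures,
)
from .interactions import steric_clash_distance
from .structure_io import (
    Structure,
    correspondence_map,
    find_glycans,
    load_structure,
    select_protomer,
)

LN1_ENTRIES = {"4XBL": "hGal1", "4XBN": "hGal3", "4XBQ": "hGal7"}
LN2_ENTRIES = {"1W6P": "hGal1", "1KJL": "hGal3", "5GAL": "hGal7"}
APO_HGAL3 = "3ZSM"

# the flexible hGal1 salt-bridge triad whose conformation differs between
# the two ligand families
HGAL1_TRIAD = (54, 71, 73)


def locate_entry(pdb_dir: str | Path, entry: str) -> Path:
    pdb_dir = Path(pdb_dir)
    for suffix in (".pdb", ".cif", ".ent"):
        for name in (entry.upper(), entry.lower()):
            p = pdb_dir / f"{name}{suffix}"
            if p.exists():
                return p
    raise FileNotFoundError(
        f"entry {entry} not found in {pdb_dir} (expected {entry}.pdb or "
        f"{entry}.cif); the deposited coordinate files must be supplied "
        f"locally"
    )


def load_protomer(pdb_dir, entry: str, chain: str = "A") -> Structure:
    s = load_structure(locate_entry(pdb_dir, entry), id=entry)
    return select_protomer(s, chain)


def family_torsions(pdb_dir, entries=None, chain: str = "A") -> dict:
    """Per-entry and circular-average glycosidic torsions for one family."""
    entries = dict(entries or LN1_ENTRIES)
    per_entry = {}
    for entry in entries:
        s = load_protomer(pdb_dir, entry, chain)
        pairs = [glycosidic_torsions(g) for g in find_glycans(s)]
        per_entry[entry] = [(round(p.phi, 1), round(p.psi, 1)) for p in pairs]
    phis = [phi for pairs in per_entry.values() for phi, _ in pairs]
    psis = [psi for pairs in per_entry.values() for _, psi in pairs]
    return {
        "per_entry": per_entry,
        "phi_avg": round(circular_mean(phis), 1),
        "psi_avg": round(circular_mean(psis), 1),
    }


def gal_o4_his_distance(pdb_dir, entry: str = "4XBL", chain: str = "A") -> float:
    """The conserved Gal O4 <-> His Nepsilon2 hydrogen-bond distance."""
    s = load_protomer(pdb_dir, entry, chain)
    glycan = find_glycans(s)[0]
    cmap = correspondence_map()
    galectin = LN1_ENTRIES.get(entry) or LN2_ENTRIES[entry]
    his = getattr(cmap.lookup(galectin, 44 if galectin == "hGal1" else
                              158 if galectin == "hGal3" else 49), galectin)
    o4 = glycan.atom("GAL", "O4").xyz
    ne2 = s.get_atom(chain, his[1], "NE2").xyz
    return round(float(np.linalg.norm(o4 - ne2)), 2)


def apo_vs_complex_rmsd(pdb_dir, apo: str, holo: str, chain: str = "A") -> float:
    """Calpha RMSD between a ligand-free entry and a complex."""
    s_apo = load_protomer(pdb_dir, apo, chain)
    s_holo = load_protomer(pdb_dir, holo, chain)
    return round(superpose_structures(s_apo, s_holo, atom_mode="CA").fit_rmsd, 2)


def triad_rmsd(pdb_dir, mobile: str, reference: str, residues=HGAL1_TRIAD,
               chain: str = "A") -> float:
    """All-heavy-atom RMSD of selected residues after a Calpha fit."""
    sm = load_protomer(pdb_dir, mobile, chain)
    sr = load_protomer(pdb_dir, reference, chain)
    sup = superpose_structures(sm, sr, atom_mode="CA")
    return round(rmsd_subset(sm, sr, sup, residues, atom_mode="all-heavy"), 2)


def o6_water_clash(pdb_dir, ln1_entry: str = "4XBL", ln2_entry: str = "1W6P",
                   chain: str = "A") -> float:
    """Distance from the superposed type-1 ligand's Gal-side GlcNAc O6 to
    the nearest ordered water of the type-2 complex.

    The type-2 complexes coordinate a water through the GlcNAc N2; after
    superposition the type-1 ligand's C6-hydroxymethyl oxygen occupies
    that pocket, leaving a sub-van-der-Waals gap to the water (~2.2 A).
    """
    s1 = load_protomer(pdb_dir, ln1_entry, chain)
    s2 = load_protomer(pdb_dir, ln2_entry, chain)
    sup = superpose_structures(s1, s2, atom_mode="CA")
    glycan1 = find_glycans(s1)[0]
    try:
        o6 = glycan1.atom("GlcNAc", "O6").xyz
    except MissingAtomError:
        raise GalkitError(f"{ln1_entry} ligand lacks a GlcNAc O6 atom")
    waters = [a.xyz for a in s2.water_atoms if a.element == "O"]
    if not waters:
        raise GalkitError(f"{ln2_entry} protomer retains no ordered waters")
    return round(steric_clash_distance(sup.apply(o6), np.array(waters)), 2)


def reproduce_structural_comparison(pdb_dir: str | Path) -> dict:
    """Run the full comparison against a local directory of the deposited
    entries and return the headline numbers."""
    ln1 = family_torsions(pdb_dir, LN1_ENTRIES)
    ln2 = family_torsions(pdb_dir, LN2_ENTRIES)
    return {
        "ln1_torsions": ln1,
        "ln2_torsions": ln2,
        "psi_shift_deg": round(psi_shift(ln1["psi_avg"], ln2["psi_avg"]), 1),
        "gal_o4_his44_A": gal_o4_his_distance(pdb_dir, "4XBL"),
        "hgal3_apo_vs_ln1_rmsd_A": apo_vs_complex_rmsd(pdb_dir, APO_HGAL3, "4XBN"),
        "hgal1_triad_rmsd_A": triad_rmsd(pdb_dir, "4XBL", "1W6P"),
        "o6_water_clash_A": o6_water_clash(pdb_dir),
    }
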