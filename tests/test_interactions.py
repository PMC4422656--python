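"""Polar contacts, water bridges, stacking, clash distance and diffing."""

import numpy as np
import pytest

from galkit.errors import GalkitError, MissingAtomError, UndefinedAverageError
from galkit.interactions import (
    ContactTable,
    PolarContact,
    average_moiety_distance,
    diff_contact_tables,
    find_polar_contacts,
    find_water_bridges,
    stacking_contact,
    steric_clash_distance,
)
from galkit.structure_io import (
    AtomRecord,
    Structure,
    correspondence_map,
    find_glycan,
)
from galkit.synthetic import (
    ContactSpec,
    WaterBridgeSpec,
    make_toy_complex,
    trp_indole_template,
)


def brute_force_contacts(structure, glycan, cutoff):
    """Independent exhaustive all-pairs scan restricted to N/O atoms."""
    found = set()
    ligand = [("GAL", a) for a in glycan.gal_atoms.values() if a.is_polar]
    ligand += [("GlcNAc", a) for a in glycan.glcnac_atoms.values() if a.is_polar]
    for pa in structure.atoms:
        if pa.residue_name not in {
            "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
            "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
            "TYR", "VAL", "MSE",
        }:
            continue
        if pa.element not in ("N", "O"):
            continue
        for moiety, la in ligand:
            if np.linalg.norm(la.xyz - pa.xyz) <= cutoff:
                found.add((moiety, la.atom_name, pa.residue_seq, pa.atom_name))
    return found


def test_engineered_contact_is_reported_exactly(ln1_site):
    structure, manifest = ln1_site
    glycan = find_glycan(structure)
    table = find_polar_contacts(structure, glycan)
    spec = manifest.contacts[0]
    matching = [
        c
        for c in table.contacts
        if (c.ligand_moiety, c.ligand_atom, c.residue_seq, c.protein_atom)
        == (spec["moiety"], spec["ligand_atom"], spec["residue_seq"],
            spec["protein_atom"])
    ]
    assert len(matching) == 1
    assert matching[0].distance == pytest.approx(spec["distance"], abs=5e-3)
    # a tight cutoff excludes it entirely
    assert find_polar_contacts(structure, glycan, cutoff=2.5).contacts == []


def test_cutoff_validation(ln1_site):
    structure, _ = ln1_site
    glycan = find_glycan(structure)
    for bad in (2.0, 5.0):
        with pytest.raises(ValueError):
            find_polar_contacts(structure, glycan, cutoff=bad)


def test_contacts_match_exhaustive_scan_and_are_monotone(rng):
    for seed in range(10):
        s, _ = make_toy_complex(seed=seed)
        # surround the ligand with a random soup of protein polar atoms
        glycan = find_glycan(s)
        center = glycan.atom("GAL", "C1").xyz
        atoms = list(s.atoms)
        for i in range(25):
            name, elem = [("OD1", "O"), ("ND2", "N"), ("CB", "C")][i % 3]
            atoms.append(
                AtomRecord(
                    "A", "ASN", 400 + i, name, elem,
                    tuple(center + rng.normal(scale=4.0, size=3)),
                )
            )
        soup = Structure(id=f"soup{seed}", atoms=atoms)
        glycan = find_glycan(soup)
        tables = {}
        for cutoff in (3.0, 3.5):
            table = find_polar_contacts(soup, glycan, cutoff=cutoff)
            got = {
                (c.ligand_moiety, c.ligand_atom, c.residue_seq, c.protein_atom)
                for c in table.contacts
            }
            assert got == brute_force_contacts(soup, glycan, cutoff)
            tables[cutoff] = got
        assert tables[3.0] <= tables[3.5]  # cutoff monotonicity


def test_contact_output_invariant_to_rigid_motion():
    kwargs = dict(
        contacts=(ContactSpec("GAL", "O4", "HIS", 44, "NE2", 2.87),), seed=3
    )
    fixed, _ = make_toy_complex(apply_transform=False, **kwargs)
    moved, _ = make_toy_complex(apply_transform=True, **kwargs)
    t_fixed = find_polar_contacts(fixed, find_glycan(fixed))
    t_moved = find_polar_contacts(moved, find_glycan(moved))
    assert [
        (c.ligand_atom, c.residue_seq, c.protein_atom, c.distance)
        for c in t_fixed.contacts
    ] == [
        (c.ligand_atom, c.residue_seq, c.protein_atom, c.distance)
        for c in t_moved.contacts
    ]


def _table(distances, moiety="GAL"):
    contacts = [
        PolarContact(moiety, "O4", "HIS", 44, "NE2", d) for d in distances
    ]
    return ContactTable(complex_id="t", contacts=contacts)


def test_average_moiety_distance():
    assert average_moiety_distance(_table([2.0, 4.0]), "GAL") == pytest.approx(3.0)
    assert average_moiety_distance(_table([2.87]), "GAL") == pytest.approx(2.87)
    table = _table([2.51, 3.02, 2.88, 3.47])
    brute = round(sum([2.51, 3.02, 2.88, 3.47]) / 4, 2)
    avg = average_moiety_distance(table, "GAL")
    assert avg == pytest.approx(brute)
    assert min([2.51, 3.02, 2.88, 3.47]) <= avg <= max([2.51, 3.02, 2.88, 3.47])
    with pytest.raises(UndefinedAverageError):
        average_moiety_distance(_table([2.0]), "GlcNAc")


def test_water_bridge_detected_and_absent_without_water(ln1_site):
    structure, manifest = ln1_site
    glycan = find_glycan(structure)
    bridges = find_water_bridges(structure, glycan)
    assert len(bridges) == 1
    spec = manifest.water_bridges[0]
    b = bridges[0]
    lig = {(m, a): d for m, a, d in b.ligand_contacts}
    assert lig[(spec["moiety"], spec["ligand_atom"])] == pytest.approx(
        spec["d_ligand"], abs=5e-3
    )
    prot = {(r, s, a): d for r, s, a, d in b.protein_contacts}
    assert prot[
        (spec["residue_name"], spec["residue_seq"], spec["protein_atom"])
    ] == pytest.approx(spec["d_protein"], abs=5e-3)
    dry = Structure(
        id="dry", atoms=[a for a in structure.atoms if not a.is_water]
    )
    assert find_water_bridges(dry, find_glycan(dry)) == []


def test_steric_clash_distance(rng):
    sphere = rng.normal(size=(40, 3))
    sphere /= np.linalg.norm(sphere, axis=1, keepdims=True)
    assert steric_clash_distance([0, 0, 0], sphere) == pytest.approx(1.0)
    probe = rng.normal(size=3)
    targets = rng.normal(size=(100, 3)) * 3
    exhaustive = min(np.linalg.norm(t - probe) for t in targets)
    assert steric_clash_distance(probe, targets) == pytest.approx(exhaustive)
    with pytest.raises(GalkitError):
        steric_clash_distance(probe, np.empty((0, 3)))


def test_stacking_contact_geometry():
    indole = trp_indole_template()
    trp = {
        name: AtomRecord("A", "TRP", 68, name, name[0], tuple(map(float, xyz)))
        for name, xyz in indole.items()
    }
    ring = np.array(
        [[np.cos(np.pi / 3 * j), np.sin(np.pi / 3 * j), 4.0] for j in range(6)]
    )
    near = stacking_contact(trp, ring)
    assert near.present and near.centroid_distance == pytest.approx(4.0)
    assert near.interplanar_angle == pytest.approx(0.0, abs=1e-6)
    far = stacking_contact(trp, ring + np.array([0.0, 0.0, 4.0]))
    assert not far.present and far.centroid_distance == pytest.approx(8.0)
    with pytest.raises(MissingAtomError):
        stacking_contact({k: v for k, v in list(trp.items())[:4]}, ring)


def _named_table(rows, linkage, complex_id="x"):
    contacts = [PolarContact(*row) for row in rows]
    return ContactTable(complex_id=complex_id, contacts=contacts, linkage=linkage)


def test_diff_with_itself_is_all_zero(ln1_site):
    structure, _ = ln1_site
    glycan = find_glycan(structure)
    table = find_polar_contacts(structure, glycan)
    diff = diff_contact_tables(table, table, correspondence_map())
    assert diff.paired and all(d.delta == 0.0 for d in diff.paired)
    assert not diff.only_a and not diff.only_b


def test_diff_pairs_equivalent_atoms_across_linkages():
    # type-1 table: GlcNAc O4 contacts; type-2 table: the equivalent O3
    a = _named_table(
        [
            ("GlcNAc", "O4", "GLU", 71, "OE2", 2.65),
            ("GAL", "O4", "HIS", 44, "NE2", 2.87),
        ],
        linkage="beta1_3",
    )
    b = _named_table(
        [
            ("GlcNAc", "O3", "GLU", 184, "OE2", 2.54),
            ("GAL", "O4", "HIS", 158, "NE2", 2.87),
        ],
        linkage="beta1_4",
    )
    diff = diff_contact_tables(a, b, correspondence_map())
    assert len(diff.paired) == 2
    by_key = {d.ligand_key: d for d in diff.paired}
    assert by_key["GlcNAc:O4~O3"].delta == pytest.approx(0.11)
    assert by_key["GAL:O4"].delta == pytest.approx(0.0)
    assert not diff.only_a and not diff.only_b
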