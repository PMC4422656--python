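"""End-to-end comparison pipeline driven by a single run manifest.

The manifest (YAML or JSON) lists the complexes to analyse, the pairwise
comparisons to run and optional binding datasets:

.. code-block:: yaml

    complexes:
      - id: ln1
        path: ln1.pdb
        chain: A          # optional; protomer selection if present
        galectin: hGal1   # optional; enables the salt-bridge stage
    comparisons:
      - mobile: ln1
        reference: ln2
    binding:
      titrations:
        - id: bli1
          path: titration.csv   # columns concentration_uM,response
          mode: bli
      competitions:
        - id: comp1
          a_competitor: 0.16
          a0: 0.05
          a_max: 0.25
          kd_probe: 1.0
          p_total: 0.1
          g_total: 3.0
          c_total: 6.0
    cutoffs:
      hbond: 3.5
      saltbridge: 4.0

The report is a plain JSON document; regeneration from identical inputs
is byte-identical (keys are sorted and no timestamps are embedded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .binding import CompetitionMeasurement, TitrationData, competition_kd, fit_saturation
from .errors import ConfigError, GalkitError, PipelineError
from .geometry import (
    assign_ring_conformation,
    glycosidic_torsions,
    psi_shift,
    superpose_structures,
)
from .interactions import find_polar_contacts, find_water_bridges
from .saltbridge import extract_network
from .structure_io import correspondence_map, find_glycan, load_structure, select_protomer

logger = logging.getLogger("galkit.pipeline")


def _require(cond, msg):
    if not cond:
        raise ConfigError(msg)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    _require(path.exists(), f"config file not found: {path}")
    text = path.read_text()
    cfg = yaml.safe_load(text)
    _require(isinstance(cfg, dict), "run manifest must be a mapping")
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    _require("complexes" in cfg and isinstance(cfg["complexes"], list),
             "manifest needs a 'complexes' list")
    ids = set()
    for c in cfg["complexes"]:
        _require(isinstance(c, dict) and "id" in c and "path" in c,
                 "each complex needs 'id' and 'path'")
        _require(c["id"] not in ids, f"duplicate complex id '{c['id']}'")
        ids.add(c["id"])
    for comp in cfg.get("comparisons", []) or []:
        _require(
            comp.get("mobile") in ids and comp.get("reference") in ids,
            f"comparison references unknown complex ids: {comp}",
        )
    binding = cfg.get("binding", {}) or {}
    for t in binding.get("titrations", []) or []:
        _require("id" in t and "path" in t, "titration entries need id and path")
        _require(t.get("mode", "bli") in ("bli", "fp"),
                 f"unknown titration mode in {t}")


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute geometry -> contacts -> network -> binding and write the
    report (JSON + per-complex contact CSVs) under ``out_dir``.

    Any stage error aborts with the stage name and input id; partially
    written outputs are removed.
    """
    if not isinstance(config, dict):
        cfg = load_config(config)
        cfg_text = Path(config).read_text()
    else:
        validate_config(config)
        cfg = config
        cfg_text = json.dumps(config, sort_keys=True)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    cmap = correspondence_map()
    cutoffs = {"hbond": 3.5, "saltbridge": 4.0}
    cutoffs.update(cfg.get("cutoffs", {}) or {})

    report: dict = {
        "provenance": {
            "galkit_version": __version__,
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "inputs": {c["id"]: str(c["path"]) for c in cfg["complexes"]},
            "cutoffs": cutoffs,
            "units": {"distance": "A", "angle": "deg", "kd": "uM"},
        },
        "complexes": {},
        "comparisons": [],
        "binding": {},
    }

    try:
        structures = {}
        for c in cfg["complexes"]:
            cid = c["id"]
            try:
                s = load_structure(c["path"], id=cid)
                if c.get("chain"):
                    s = select_protomer(s, c["chain"])
                structures[cid] = (s, c)
                logger.info("loaded %s: %d atoms", cid, len(s.atoms))
            except GalkitError as exc:
                raise PipelineError("load", cid, str(exc)) from exc

        for cid, (s, c) in structures.items():
            entry: dict = {}
            try:
                glycan = find_glycan(s)
                tp = glycosidic_torsions(glycan)
                entry["geometry"] = {
                    "linkage": glycan.linkage,
                    "phi_deg": round(tp.phi, 1),
                    "psi_deg": round(tp.psi, 1),
                    "gal_pucker": assign_ring_conformation(
                        glycan.gal_ring_coords()
                    ).label,
                    "glcnac_pucker": assign_ring_conformation(
                        glycan.glcnac_ring_coords()
                    ).label,
                }
            except GalkitError as exc:
                raise PipelineError("geometry", cid, str(exc)) from exc
            try:
                table = find_polar_contacts(
                    s, glycan, cutoff=cutoffs["hbond"],
                    galectin=c.get("galectin"),
                )
                entry["contacts"] = {
                    "n": len(table.contacts),
                    "avg_gal_A": table.avg_gal,
                    "avg_glcnac_A": table.avg_glcnac,
                }
                csv_path = out_dir / f"contacts_{cid}.csv"
                table.to_dataframe().to_csv(csv_path, index=False)
                written.append(csv_path)
                bridges = find_water_bridges(s, glycan, cutoff=cutoffs["hbond"])
                entry["water_bridges"] = [
                    {
                        "water": f"{b.water_chain}:{b.water_seq}",
                        "ligand": [list(x) for x in b.ligand_contacts],
                        "protein": [list(x) for x in b.protein_contacts],
                    }
                    for b in bridges
                ]
            except GalkitError as exc:
                raise PipelineError("contacts", cid, str(exc)) from exc
            if c.get("galectin"):
                try:
                    net = extract_network(
                        s, cmap, c["galectin"], cutoff=cutoffs["saltbridge"]
                    )
                    entry["network"] = {
                        "quartet": [f"{n}{q}" for n, q in net.quartet],
                        "bridges": [
                            {
                                "basic": f"{b.basic_residue[1]}{b.basic_residue[2]}",
                                "acidic": f"{b.acidic_residue[1]}{b.acidic_residue[2]}",
                                "class": b.geometry_class,
                                "pairs": [list(p) for p in b.no_pairs],
                            }
                            for b in net.bridges
                        ],
                        "l4": {
                            "position": net.l4.position,
                            "length": net.l4.length,
                            "group": net.l4.group,
                        },
                    }
                except GalkitError as exc:
                    raise PipelineError("network", cid, str(exc)) from exc
            report["complexes"][cid] = entry

        for comp in cfg.get("comparisons", []) or []:
            mid, rid = comp["mobile"], comp["reference"]
            try:
                sup = superpose_structures(
                    structures[mid][0], structures[rid][0],
                    atom_mode=comp.get("atom_mode", "CA")
                    if comp.get("atom_mode") else "CA",
                    offset=comp.get("offset", 0),
                )
                row = {
                    "mobile": mid,
                    "reference": rid,
                    "fit_rmsd_A": round(sup.fit_rmsd, 2),
                    "n_fit_atoms": sup.n_fit_atoms,
                }
                gm = report["complexes"][mid].get("geometry")
                gr = report["complexes"][rid].get("geometry")
                if gm and gr and gm["linkage"] != gr["linkage"]:
                    ln1, ln2 = (
                        (gm, gr) if gm["linkage"] == "beta1_3" else (gr, gm)
                    )
                    row["psi_shift_deg"] = round(
                        psi_shift(ln1["psi_deg"], ln2["psi_deg"]), 1
                    )
                report["comparisons"].append(row)
            except GalkitError as exc:
                raise PipelineError("comparison", f"{mid}-{rid}", str(exc)) from exc

        binding_cfg = cfg.get("binding", {}) or {}
        for t in binding_cfg.get("titrations", []) or []:
            try:
                df = pd.read_csv(t["path"])
                data = TitrationData(
                    df["concentration_uM"].to_numpy(),
                    df["response"].to_numpy(),
                    response_type=t.get("mode", "bli"),
                )
                res = fit_saturation(data)
                report["binding"][t["id"]] = {
                    "kd_uM": res.kd,
                    "kd_stderr_uM": res.kd_stderr,
                    "amax": res.amax_fit,
                    "a0": res.a0_fit,
                    "method": res.method,
                    "flags": list(res.flags),
                }
            except (GalkitError, KeyError, OSError) as exc:
                raise PipelineError("binding-fit", t["id"], str(exc)) from exc
        for comp in binding_cfg.get("competitions", []) or []:
            cid = comp.get("id", "competition")
            try:
                m = CompetitionMeasurement(
                    a_competitor=comp["a_competitor"], a0=comp["a0"],
                    a_max=comp["a_max"], kd_probe=comp["kd_probe"],
                    p_total=comp["p_total"], g_total=comp["g_total"],
                    c_total=comp["c_total"],
                )
                res = competition_kd(m)
                report["binding"][cid] = {
                    "kd_uM": res.kd,
                    "method": res.method,
                    "species_uM": res.species,
                }
            except (GalkitError, KeyError) as exc:
                raise PipelineError("competition", cid, str(exc)) from exc

        report_path = out_dir / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(report_path)
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return report
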