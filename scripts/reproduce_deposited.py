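#!/usr/bin/env python
"""Integration tier: rerun the quaternary analyses on deposited structures.

This script is for users who have local copies of the deposited coordinate
files (e.g. the product-bound octameric UDP-glucose pyrophosphorylase and its
apo counterpart, PDB entries 4R7P and 3R2W, fetched however your site allows)
plus the chain sequence for the Matthews calculation.  Nothing is downloaded.

Example:
    python scripts/reproduce_deposited.py \
        --holo 4r7p.pdb --apo 3r2w.pdb --apo-offset 11 \
        --regions examples/hugp1_regions.yaml \
        --sequence chain.fasta --z 24 --out deposited_report.json

The displacement stage sweeps several fit-region choices because the
reported maxima depend on the (undocumented) superposition frame; all sweep
results are written so the sensitivity is visible.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from quatlock import (
    compaction_report,
    detect_interlock,
    detect_point_group,
    displacement_profile,
    matthews,
    max_displacement,
    molar_mass_from_sequence,
    read_structure,
)
from quatlock.structure_io import load_region_definitions


def _read_single_sequence(path: Path) -> str:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--holo", required=True, type=Path,
                        help="Product-bound structure file (PDB/mmCIF).")
    parser.add_argument("--apo", required=True, type=Path,
                        help="Apo structure file (PDB/mmCIF).")
    parser.add_argument("--regions", required=True, type=Path)
    parser.add_argument("--apo-offset", type=int, default=11,
                        help="Numbering offset apo -> holo scheme (short "
                             "isoform lacks 11 N-terminal residues).")
    parser.add_argument("--sequence", type=Path, default=None,
                        help="FASTA of the crystallized chain (tag included) "
                             "for the Matthews calculation.")
    parser.add_argument("--z", type=int, default=24,
                        help="Protein molecules per unit cell.")
    parser.add_argument("--out", type=Path, default=Path("deposited_report.json"))
    args = parser.parse_args()

    regions = load_region_definitions(args.regions)
    holo = read_structure(args.holo, state_label="product_bound")
    apo = read_structure(args.apo, state_label="apo")
    report: dict = {"holo": str(args.holo), "apo": str(args.apo)}

    sym = detect_point_group(holo)
    report["symmetry"] = {
        "point_group": sym.point_group,
        "n_chains": len(holo.chains),
        "fit_residual": round(sym.fit_residual, 3),
        "note": "the deposited asymmetric unit may hold only part of the "
                "biological assembly; supply pre-built oligomer coordinates "
                "for the full group",
    }

    if "SB-loop" in regions:
        interlock = detect_interlock(holo, regions["SB-loop"])
        report["interlock"] = {
            "classification": interlock.classification,
            "recurring_pairs": [list(p) for p in interlock.recurring_pairs],
            "asymmetric_chains": interlock.asymmetric_chains,
        }

    # displacement maxima with a fit-region sweep
    sweep = {}
    ref_chain = holo.chains[0]
    mov_chain = apo.chains[0]
    candidates = {
        name: regions[name]
        for name in ("catalytic-core",)
        if name in regions
    }
    # whole chain minus the report region as an additional frame
    for report_name in ("SB-loop", "SB-region"):
        if report_name not in regions:
            continue
        entry = {}
        for fit_name, fit_region in candidates.items():
            try:
                profile = displacement_profile(
                    ref_chain, mov_chain, fit_region, regions[report_name],
                    mov_offset=args.apo_offset,
                )
                ca, ca_res = max_displacement(profile, "ca")
                sc, sc_res = max_displacement(profile, "sidechain")
                entry[fit_name] = {
                    "max_ca": round(ca, 2), "max_ca_residue": ca_res,
                    "max_sidechain": round(sc, 2), "max_sidechain_residue": sc_res,
                    "fit_rmsd": round(profile.fit.rmsd, 3),
                }
            except ValueError as exc:
                entry[fit_name] = {"error": str(exc)}
        sweep[report_name] = entry
    report["displacement_sweep"] = sweep

    try:
        comp = compaction_report(apo, holo, sym)
        report["compaction"] = {
            "percent_volume_change": round(comp.percent_volume_change, 1),
            "deltas": [round(d, 1) for d in comp.deltas],
            "percent_hull_volume_change": (
                round(comp.percent_hull_volume_change, 1)
                if comp.percent_hull_volume_change is not None
                else None
            ),
        }
    except ValueError as exc:
        report["compaction"] = {"error": str(exc)}

    if args.sequence is not None and holo.unit_cell is not None:
        mass = molar_mass_from_sequence(_read_single_sequence(args.sequence))
        metrics = matthews(holo.unit_cell, args.z, mass)
        report["crystal_metrics"] = {
            "molar_mass_Da": round(mass, 1),
            "matthews_vm": round(metrics.matthews_vm, 2),
            "solvent_content_percent": (
                round(metrics.solvent_fraction, 1)
                if metrics.solvent_fraction is not None
                else None
            ),
        }

    args.out.write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
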