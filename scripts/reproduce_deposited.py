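#!/usr/bin/env python
"""Reproduce the deposited-structure analyses, given locally fetched files.

Expects coordinate files under ``data/deposited/`` (or ``--dir``):

    7ksf.cif               native PFV PR-RT (PDB 7KSF)
    7kse.cif               SeMet CSH-mutant PFV PR-RT (PDB 7KSE)
    2hb4.pdb               apo HIV-1 protease dimer (PDB 2HB4)
    pfv_pr_dimer_model.pdb in-silico PFV PR dimer model (journal appendix)

Fetch e.g. with:
    curl -o data/deposited/7ksf.cif https://files.rcsb.org/download/7KSF.cif

Computes: instability index and hotspot scan of the 751-residue construct
sequence, modeled residue count, CSH-onto-native C-alpha superposition RMSD,
the inter-domain buried-surface matrix under both area conventions, the
calcium coordination sphere, and the HIV-1 PR dimer alignment RMSD.  Writes
a JSON report; stages whose input file is absent are reported as missing.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path
import sys

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from polyprot import (  # noqa: E402
    classify_stability,
    compare_dimer_to_reference,
    default_pfv_map,
    instability_index,
    interface_table,
    kabsch_superpose,
    kabsch_superpose_trimmed,
    metal_coordination,
    pair_common_ca,
    read_structure,
    saturation_scan,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dir", type=Path, default=ROOT / "data" / "deposited")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "deposited.json")
    args = parser.parse_args()

    out: dict = {}

    def have(name: str) -> Path | None:
        p = args.dir / name
        if not p.exists():
            out[name] = {"status": "missing"}
            return None
        return p

    native_path = have("7ksf.cif")
    if native_path:
        native = read_structure(native_path)
        out["modeled_protein_residues"] = native.n_polymer_residues()

        seq = native.seqres.get(native.first_chain(), "")[:751]
        if len(seq) == 751:
            ii = instability_index(seq)
            scan = saturation_scan(seq)
            out["construct_instability_index"] = round(ii, 2)
            out["construct_classification"] = classify_stability(ii)
            out["top20_hotspot_positions"] = [int(p) for p in scan.top_hotspots(20).position]
        else:
            out["construct_instability_index"] = {"status": f"SEQRES length {len(seq)} != 751"}

        report = interface_table(native, default_pfv_map())
        out["interface_matrix_buried_total_A2"] = {
            f"{a}|{b}": round(float(report.bsa.loc[a, b]), 1)
            for i, a in enumerate(report.groups)
            for b in report.groups[i + 1:]
            if report.bsa.loc[a, b] >= report.no_contact_bsa
        }
        out["connection_row_sum_A2"] = round(report.row_sum("connection"), 1)
        out["dg_estimates_kcal_mol"] = {
            f"{a}|{b}": round(float(report.dg_estimate.loc[a, b]), 2)
            for i, a in enumerate(report.groups)
            for b in report.groups[i + 1:]
            if report.bsa.loc[a, b] >= report.no_contact_bsa
        }
        try:
            out["calcium_coordination"] = [
                {"residue": n, "name": rn, "atom": an, "distance_A": round(d, 2)}
                for n, rn, an, d in metal_coordination(native, "CA")
            ]
        except KeyError as exc:
            out["calcium_coordination"] = {"status": str(exc)}

    csh_path = have("7kse.cif")
    if native_path and csh_path:
        csh = read_structure(csh_path)
        P, Q, _ = pair_common_ca(csh, read_structure(native_path))
        out["csh_vs_native_rmsd_A"] = {
            "all_common_ca": round(kabsch_superpose(P, Q).rmsd, 3),
            "trimmed_2sigma": round(kabsch_superpose_trimmed(P, Q).rmsd, 3),
            "n_pairs": len(P),
        }

    dimer_path = have("pfv_pr_dimer_model.pdb")
    hiv_path = have("2hb4.pdb")
    if dimer_path and hiv_path:
        aln = compare_dimer_to_reference(
            read_structure(dimer_path), read_structure(hiv_path)
        )
        out["pfv_dimer_vs_hiv1_pr_rmsd_A"] = {
            "rmsd": round(aln.rmsd, 3), "n_pairs": aln.n_pairs,
        }

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
    print(json.dumps(out, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
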