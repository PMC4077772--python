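#!/usr/bin/env python
"""Annotate the synthetic precursor cDNA and excise its mature peptides.

Also computes the theoretical [M+H]+ of the three endogenous amphioxus
PQRFamide peptides (sequences are published data) — the numbers the mass
spectrometer was searched against. Writes results/peptides.tsv and
results/mine.json.
"""

import json
from pathlib import Path

from Bio import SeqIO

from rfamide import massspec as ms, precursor as pre, workflow

ROOT = Path(__file__).resolve().parent.parent / "results"
AMPHIOXUS = ["WDEAWRPQRF", "GDHTKDGWRPQRF", "GRDQGWRPQRF"]


def main() -> None:
    fasta = ROOT / "synthetic" / "precursor.fa"
    truth = json.loads((ROOT / "synthetic" / "precursor_truth.json").read_text())

    annotations = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        record = pre.NucleotideRecord(rec.id, str(rec.seq).upper())
        annotations.append(pre.annotate_precursor(record))
    ann = annotations[0]
    print(f"{ann.record_id}: ORF {ann.orf.start}..{ann.orf.end} "
          f"({len(ann.orf.protein)} aa), signal peptide ends at "
          f"residue {ann.signal_end}, {len(ann.cleavage_sites)} cleavage sites")
    for p in ann.peptides:
        print(f"  peptide {p.sequence} [{p.start + 1}-{p.end} 1-based] "
              f"amidated={p.amidated} family={p.family}")
    recovered = [p.sequence for p in ann.peptides]
    planted = [p["sequence"] for p in truth["peptides"]]
    print("round trip against planted truth:",
          "exact" if recovered == planted else "MISMATCH")

    workflow.write_peptide_table(annotations, ROOT / "peptides.tsv")

    print("\ntheoretical [M+H]+ of the endogenous amphioxus PQRFa peptides:")
    masses = {}
    for seq in AMPHIOXUS:
        mz = ms.singly_protonated_mz(ms.peptide_monoisotopic_mass(seq, True))
        masses[seq] = round(mz, 2)
        print(f"  {seq:>14s}-NH2  {mz:9.2f}")
    suffix = pre.common_c_terminal_suffix(AMPHIOXUS)
    print(f"conserved C-terminal suffix: {suffix} ({len(suffix)} aa)")

    (ROOT / "mine.json").write_text(json.dumps({
        "recovered_peptides": recovered,
        "round_trip_exact": recovered == planted,
        "theoretical_mh": masses,
        "conserved_suffix": suffix,
    }, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
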