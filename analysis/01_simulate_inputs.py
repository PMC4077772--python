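#!/usr/bin/env python
"""Generate the synthetic input bundle used by the downstream analyses.

Writes, under results/synthetic/: a precursor cDNA FASTA with a truth JSON
sidecar, a simulated MALDI peak list for one of its peptides, an alignment
evolved on a known 8-taxon tree, and paired gene tables with planted
ortholog neighbors.
"""

import dataclasses
import json
from pathlib import Path

from rfamide import simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 1
TREE = ("(((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1):0.1,"
        "((E:0.2,F:0.2):0.1,(G:0.2,H:0.2):0.1):0.1);")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    truth = simulate.generate_precursor_cdna(SEED, n_peptides=3, family="PQRFa")
    (OUT / "precursor.fa").write_text(
        f">{truth.record.id}\n{truth.record.sequence}\n")
    (OUT / "precursor_truth.json").write_text(json.dumps({
        "protein": truth.protein,
        "signal_end": truth.signal_end,
        "peptides": [dataclasses.asdict(p) for p in truth.peptides],
    }, indent=2, sort_keys=True) + "\n")
    print(f"precursor: {len(truth.record.sequence)} nt cDNA, "
          f"{len(truth.protein)} aa protein, {len(truth.peptides)} peptides: "
          + ", ".join(p.sequence for p in truth.peptides))

    target = truth.peptides[1]
    peaks, spec_truth = simulate.simulate_maldi(
        [target], sd=0.1, n_noise=20, seed=SEED)
    (OUT / "spectrum.tsv").write_text("".join(
        f"{mz:.5f}\t{inten:.3f}\n"
        for mz, inten in zip(peaks.mz, peaks.intensity)))
    (OUT / "spectrum_truth.json").write_text(
        json.dumps(dataclasses.asdict(spec_truth), indent=2, sort_keys=True) + "\n")
    print(f"spectrum: {len(peaks.mz)} peaks "
          f"({len(spec_truth.true_ions)} true ions from {target.sequence}, "
          f"{len(spec_truth.noise_mz)} noise)")

    aln = simulate.evolve_alignment(TREE, 500, seed=SEED)
    (OUT / "alignment.fa").write_text("".join(
        f">{t}\n{r}\n" for t, r in zip(aln.taxa, aln.rows)))
    (OUT / "true_tree.nwk").write_text(TREE + "\n")
    print(f"alignment: {len(aln.taxa)} taxa x {aln.n_columns} columns "
          f"evolved on the known tree")

    ta, tb, orth, fa, fb = simulate.generate_synteny_tables(
        SEED, n_genes=41, k=10, shared_fraction=0.6)
    ta.to_bed(OUT / "table_a.bed")
    tb.to_bed(OUT / "table_b.bed")
    with open(OUT / "orthology.tsv", "w") as fh:
        for a, b in sorted(orth.pairs):
            fh.write(f"{a}\t{b}\n")
    (OUT / "focal.json").write_text(json.dumps(
        {"focal_a": fa, "focal_b": fb}, indent=2) + "\n")
    print(f"synteny: 2 x 41-gene tables, {len(orth.pairs)} ortholog pairs, "
          f"focal genes {fa} / {fb}")


if __name__ == "__main__":
    main()
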