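#!/usr/bin/env python
"""Match the simulated MALDI spectrum against the mined candidate peptides.

The spectrum was simulated from one known peptide; this script asks whether
tolerance-based precursor + b/y fragment matching ranks that peptide first
among all mined candidates. Writes results/ms_match.json.
"""

import json
from pathlib import Path

import pandas as pd

from rfamide import massspec as ms, precursor as pre

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    peaks = ms.PeakList.from_tsv(ROOT / "synthetic" / "spectrum.tsv")
    spec_truth = json.loads(
        (ROOT / "synthetic" / "spectrum_truth.json").read_text())
    table = pd.read_csv(ROOT / "peptides.tsv", sep="\t")
    candidates = [
        pre.PeptidePrediction(
            sequence=row["peptide_seq"], start=int(row["start_1based"]) - 1,
            end=int(row["end_1based"]), amidated=bool(row["amidated"]),
            family=row["family"])
        for _, row in table.iterrows()
    ]
    ranked = ms.identify_peptides(peaks, candidates, tolerance=0.5)
    print(f"spectrum {peaks.source_id}: {len(peaks.mz)} peaks vs "
          f"{len(candidates)} candidates (tolerance 0.5 Da)")
    for cand, res in ranked:
        err = ("-" if res.precursor_error is None
               else f"{res.precursor_error:+.3f}")
        print(f"  {cand.sequence:>16s}  precursor_err={err:>7s} Da  "
              f"coverage={res.coverage:.2f}  matched={res.n_matched}")
    top = ranked[0][0].sequence
    source = spec_truth["peptides"][0]
    print(f"top hit {top} {'==' if top == source else '!='} "
          f"simulated source {source}")

    (ROOT / "ms_match.json").write_text(json.dumps({
        "source_peptide": source,
        "top_hit": top,
        "top_coverage": ranked[0][1].coverage,
        "ranking": [c.sequence for c, _ in ranked],
    }, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
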