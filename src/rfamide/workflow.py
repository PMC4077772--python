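"""End-to-end orchestration: mine -> mass-match -> phylo -> synteny.

A run is driven by a flat TOML config; stages whose inputs are absent are
skipped. Every stage writes its own JSON, and a combined report carries a
provenance block (config hash, package version, seeds) so a rerun with the
same config and inputs is byte-identical — no timestamps enter any output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__, massspec, phylo, precursor, synteny

__all__ = ["DEFAULTS", "load_config", "validate_config", "run_discovery",
           "write_peptide_table", "StageError"]

DEFAULTS: dict[str, Any] = {
    # inputs (absent path => stage skipped)
    "fasta": "", "peaks": "", "alignment": "",
    "table_a": "", "table_b": "", "orthology": "",
    # mine
    "min_codons": 50, "signal_window": 7, "signal_threshold": 1.6,
    # ms-match
    "tolerance": 0.5,
    # phylo
    "model": "poisson", "gap_mode": "pairwise", "n_reps": 1000,
    "bootstrap_seed": 0, "outgroup": "",
    # synteny
    "focal_a": "", "focal_b": "", "k": 10, "n_perm": 999, "synteny_seed": 0,
    "out_dir": "results",
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a flat TOML config; unknown keys are reported by validate_config."""
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    config = dict(DEFAULTS)
    config.update(user)
    return config


def validate_config(config: dict[str, Any]) -> list[str]:
    """Collect every problem at once; an empty list means the config is ok."""
    errors = []
    for key in config:
        if key not in DEFAULTS:
            errors.append(f"unknown key {key!r}")
    for key in ("fasta", "peaks", "alignment", "table_a", "table_b", "orthology"):
        path = config.get(key, "")
        if path and not Path(path).exists():
            errors.append(f"{key}: path {path!r} does not exist")
    if not any(config.get(k) for k in
               ("fasta", "peaks", "alignment", "table_a")):
        errors.append("no inputs given: at least one of fasta/peaks/alignment/table_a required")
    if config.get("tolerance", 0.5) <= 0:
        errors.append("tolerance must be > 0")
    if config.get("min_codons", 1) < 1:
        errors.append("min_codons must be >= 1")
    if config.get("n_reps", 1) < 1:
        errors.append("n_reps must be >= 1")
    if config.get("n_perm", 999) < 99:
        errors.append("n_perm must be >= 99")
    if config.get("model") not in ("p", "poisson"):
        errors.append("model must be 'p' or 'poisson'")
    if config.get("gap_mode") not in ("pairwise", "complete"):
        errors.append("gap_mode must be 'pairwise' or 'complete'")
    if config.get("k", 10) < 0:
        errors.append("k must be >= 0")
    if config.get("table_a") and not (config.get("table_b") and config.get("orthology")
                                      and config.get("focal_a") and config.get("focal_b")):
        errors.append("synteny stage needs table_a, table_b, orthology, focal_a, focal_b")
    return errors


def write_peptide_table(annotations: list[precursor.PrecursorAnnotation],
                        path: str | Path) -> pd.DataFrame:
    """Peptide TSV: 1-based inclusive coordinates, one row per mature peptide."""
    rows = []
    for ann in annotations:
        for p in ann.peptides:
            rows.append({
                "precursor_id": ann.record_id,
                "peptide_seq": p.sequence,
                "start_1based": p.start + 1,
                "end_1based": p.end,
                "amidated": p.amidated,
                "family": p.family,
                "n_flank_motif": p.n_flank_motif,
                "c_flank_motif": p.c_flank_motif,
            })
    df = pd.DataFrame(rows, columns=[
        "precursor_id", "peptide_seq", "start_1based", "end_1based",
        "amidated", "family", "n_flank_motif", "c_flank_motif"])
    df.to_csv(path, sep="\t", index=False)
    return df


def _json_dump(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _stage_mine(config, out_dir: Path) -> dict:
    from Bio import SeqIO
    annotations = []
    for rec in SeqIO.parse(config["fasta"], "fasta"):
        record = precursor.NucleotideRecord(rec.id, str(rec.seq).upper())
        annotations.append(precursor.annotate_precursor(
            record,
            min_codons=config["min_codons"],
            signal_window=config["signal_window"],
            signal_threshold=config["signal_threshold"],
        ))
    write_peptide_table(annotations, out_dir / "peptides.tsv")
    report = {
        "n_records": len(annotations),
        "precursors": [
            {
                "id": ann.record_id,
                "has_precursor": ann.has_precursor,
                "orf_start": ann.orf.start if ann.orf else None,
                "orf_end": ann.orf.end if ann.orf else None,
                "protein_length": len(ann.orf.protein) if ann.orf else 0,
                "signal_end": ann.signal_end,
                "n_cleavage_sites": len(ann.cleavage_sites),
                "peptides": [dataclasses.asdict(p) for p in ann.peptides],
            }
            for ann in annotations
        ],
    }
    _json_dump(report, out_dir / "mine.json")
    report["_annotations"] = annotations
    return report


def _stage_ms_match(config, out_dir: Path, mine_report) -> dict:
    peaks = massspec.PeakList.from_tsv(config["peaks"])
    candidates = []
    if mine_report is not None:
        for ann in mine_report["_annotations"]:
            candidates.extend(ann.peptides)
    if not candidates:
        return {"skipped": "no candidate peptides from the mine stage"}
    ranked = massspec.identify_peptides(peaks, candidates, config["tolerance"])
    report = {
        "source": peaks.source_id,
        "tolerance_da": config["tolerance"],
        "ranking": [
            {
                "peptide": cand.sequence,
                "amidated": cand.amidated,
                "family": cand.family,
                "precursor_mz": round(massspec.singly_protonated_mz(
                    massspec.peptide_monoisotopic_mass(cand.sequence, cand.amidated)), 4),
                "precursor_error": res.precursor_error,
                "coverage": res.coverage,
                "n_matched": res.n_matched,
            }
            for cand, res in ranked
        ],
    }
    _json_dump(report, out_dir / "ms_match.json")
    return report


def _stage_phylo(config, out_dir: Path) -> dict:
    aln = phylo.MultipleAlignment.from_fasta(config["alignment"])
    tree, supports = phylo.bootstrap_support(
        aln, model=config["model"], n_reps=config["n_reps"],
        seed=config["bootstrap_seed"], gap_mode=config["gap_mode"])
    if config["outgroup"]:
        tree = phylo.root_with_outgroup(tree, config["outgroup"])
        phylo.attach_supports(tree, supports)
    newick = phylo.write_newick(tree)
    (out_dir / "tree.nwk").write_text(newick + "\n")
    support_rows = pd.DataFrame(
        [{"bipartition": "|".join(sorted(s)), "support_pct": pct}
         for s, pct in sorted(supports.items(),
                              key=lambda kv: (-kv[1], "|".join(sorted(kv[0]))))])
    support_rows.to_csv(out_dir / "supports.tsv", sep="\t", index=False)
    report = {
        "n_taxa": len(aln.taxa),
        "n_columns": aln.n_columns,
        "model": config["model"],
        "n_reps": config["n_reps"],
        "seed": config["bootstrap_seed"],
        "outgroup": config["outgroup"] or None,
        "newick": newick,
    }
    _json_dump(report, out_dir / "phylo.json")
    return report


def _stage_synteny(config, out_dir: Path) -> dict:
    table_a = synteny.GeneTable.from_bed(config["table_a"])
    table_b = synteny.GeneTable.from_bed(config["table_b"])
    orthology = synteny.OrthologyMap.from_tsv(config["orthology"])
    obs, p = synteny.permutation_null(
        table_a, table_b, orthology,
        config["focal_a"], config["focal_b"], config["k"],
        n_perm=config["n_perm"], seed=config["synteny_seed"])
    report = dataclasses.asdict(obs)
    report["p_value"] = p
    report["n_perm"] = config["n_perm"]
    report["seed"] = config["synteny_seed"]
    _json_dump(report, out_dir / "synteny.json")
    return report


def run_discovery(config: dict[str, Any]) -> dict[str, Any]:
    """Run every stage whose inputs are present; write a combined report.

    Raises :class:`StageError` naming the failing stage; outputs of earlier
    stages are retained.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    canonical = json.dumps(
        {k: v for k, v in sorted(config.items())}, sort_keys=True)
    report: dict[str, Any] = {
        "provenance": {
            "config": {k: v for k, v in sorted(config.items())},
            "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
            "rfamide_version": __version__,
            "seeds": {"bootstrap": config["bootstrap_seed"],
                      "synteny": config["synteny_seed"]},
        },
        "stages": {},
    }
    mine_report = None
    stages = [
        ("mine", bool(config["fasta"]), lambda: _stage_mine(config, out_dir)),
        ("ms_match", bool(config["peaks"]),
         lambda: _stage_ms_match(config, out_dir, mine_report)),
        ("phylo", bool(config["alignment"]), lambda: _stage_phylo(config, out_dir)),
        ("synteny", bool(config["table_a"]), lambda: _stage_synteny(config, out_dir)),
    ]
    for name, enabled, runner in stages:
        if not enabled:
            report["stages"][name] = {"status": "skipped", "reason": "inputs absent"}
            continue
        try:
            stage_report = runner()
        except Exception as exc:
            _json_dump(report, out_dir / "report.json")
            raise StageError(name, exc) from exc
        if name == "mine":
            mine_report = stage_report
        stage_report = {k: v for k, v in stage_report.items()
                        if not k.startswith("_")}
        report["stages"][name] = {"status": "ok", **stage_report}
    _json_dump(report, out_dir / "report.json")
    return report
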