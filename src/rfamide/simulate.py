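"""Ground-truthed synthetic inputs for every pipeline stage.

Each generator is a pure function of (seed, parameters):

* precursor cDNAs with a hydrophobic signal leader, convertase-flanked
  amidated peptides and UTRs, reverse-translated with random synonymous
  codons — built so annotation recovers the planted truth exactly;
* MALDI peak lists: true precursor + b/y ions with Gaussian m/z error plus
  uniform noise peaks, log-normal intensities;
* alignments evolved on a known tree under a 20-state Poisson-style Markov
  model (substitution events at rate 1/site/unit branch length, new residue
  uniform over the other 19);
* paired gene tables with a controlled fraction of planted ortholog
  neighbors around a focal pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import massspec, phylo, precursor as pre

__all__ = [
    "GenerationError", "PrecursorTruth", "SpectrumTruth",
    "generate_precursor_cdna", "simulate_maldi", "evolve_alignment",
    "expected_p_differ", "generate_synteny_tables",
]

#: Residues free of cleavage/amidation/signal side effects: no basics (no
#: spurious convertase sites), no G (no spurious amide donors), no P (no
#: cleavage blocking ambiguity), no strongly hydrophobic residues (keeps the
#: signal-peptide core unique to the leader).
SAFE_RESIDUES = "ADENQSTHWY"

FAMILY_SUFFIXES = {
    "PQRFa": ("PQRF",),
    "LPXRFa": ("LPLRF", "LPQRF"),
}

_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table
        for codon, aa in standard_dna_table.forward_table.items():
            _CODONS.setdefault(aa, []).append(codon)
        for v in _CODONS.values():
            v.sort()
    return _CODONS


class GenerationError(RuntimeError):
    """Constraints could not be satisfied (self-check round trip failed)."""


@dataclass
class PrecursorTruth:
    """Planted ground truth for one synthetic precursor cDNA."""

    record: pre.NucleotideRecord
    protein: str
    signal_end: int | None
    peptides: list[pre.PeptidePrediction]


@dataclass
class SpectrumTruth:
    """Provenance of a simulated spectrum: true ions, noise, error model."""

    peptides: list[str]
    true_ions: list[tuple[str, float]]
    noise_mz: list[float]
    sd: float
    seed: int


def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _n_flank(rng: np.random.Generator, kinds: tuple[str, ...]) -> str:
    usable = [k for k in kinds if k in ("dibasic", "KXXR")]
    kind = usable[rng.integers(len(usable))] if usable else "KXXR"
    if kind == "dibasic":
        return ["KR", "RR"][rng.integers(2)]
    basic = "KR"[rng.integers(2)]
    return basic + _draw(rng, "VST", 2) + "R"


def _c_flank_basics(rng: np.random.Generator) -> str:
    return ["R", "KR", "RR"][rng.integers(3)]


def generate_precursor_cdna(
    seed: int,
    n_peptides: int = 3,
    family: str = "PQRFa",
    flank_motifs: tuple[str, ...] = ("dibasic", "KXXR", "glycine_basic"),
    record_id: str | None = None,
) -> PrecursorTruth:
    """Build a precursor cDNA whose annotation is known by construction.

    Protein layout: Met + hydrophobic leader satisfying the (-3,-1) rule,
    then per peptide a spacer, an N-flank motif (dibasic or [K/R]XXR), the
    peptide body ending in the family motif, the amide-donor Gly and a basic
    C-flank; a spacer tail pads the precursor past the default ORF minimum.
    The generator immediately re-annotates its own product and raises
    ``GenerationError`` if the round trip fails.
    """
    if n_peptides < 0:
        raise GenerationError("n_peptides must be >= 0")
    if family not in FAMILY_SUFFIXES:
        raise GenerationError(f"unknown family {family!r}")
    rng = np.random.default_rng(seed)
    for _attempt in range(20):
        truth = _build_precursor(rng, n_peptides, family, flank_motifs,
                                 record_id or f"synthetic_precursor_{seed}")
        ann = pre.annotate_precursor(truth.record)
        if (ann.has_precursor and ann.orf.protein == truth.protein
                and ann.signal_end == truth.signal_end
                and [(p.sequence, p.amidated, p.family) for p in ann.peptides]
                == [(p.sequence, p.amidated, p.family) for p in truth.peptides]):
            return truth
    raise GenerationError("could not satisfy round-trip constraints in 20 draws")


def _build_precursor(rng, n_peptides, family, flank_motifs, record_id):
    leader = "MKW" + "L" * 12 + "ASA"
    parts = [leader]
    planted: list[tuple[str, int, int]] = []  # (sequence, start, end)
    pos = len(leader)
    suffixes = FAMILY_SUFFIXES[family]
    for _ in range(n_peptides):
        spacer = _draw(rng, SAFE_RESIDUES, int(rng.integers(3, 7)))
        nflank = _n_flank(rng, flank_motifs)
        body = _draw(rng, SAFE_RESIDUES, int(rng.integers(4, 9)))
        peptide = body + suffixes[rng.integers(len(suffixes))]
        cflank = "G" + _c_flank_basics(rng)
        start = pos + len(spacer) + len(nflank)
        planted.append((peptide, start, start + len(peptide)))
        block = spacer + nflank + peptide + cflank
        parts.append(block)
        pos += len(block)
    protein = "".join(parts)
    pad = max(0, 70 - len(protein)) + int(rng.integers(5, 12))
    protein += _draw(rng, SAFE_RESIDUES, pad)

    signal_end = pre.predict_signal_peptide(protein)
    peptides = [
        pre.PeptidePrediction(
            sequence=seq, start=a, end=b, amidated=True,
            family=pre.classify_rfamide_family(seq, True))
        for seq, a, b in planted
    ]

    codons = _codon_table()
    cds = "".join(codons["M" if aa == "M" else aa][rng.integers(len(codons[aa]))]
                  for aa in protein)
    utr5 = _utr_without_atg(rng, 8)
    utr3 = _utr_without_atg(rng, 40) + "A" * 20
    cdna = utr5 + cds + "TAG" + utr3
    return PrecursorTruth(
        record=pre.NucleotideRecord(record_id, cdna),
        protein=protein,
        signal_end=signal_end,
        peptides=peptides,
    )


def _utr_without_atg(rng: np.random.Generator, n: int) -> str:
    while True:
        utr = _draw(rng, "ACGT", n)
        if "ATG" not in utr:
            return utr


def simulate_maldi(
    peptides: list[pre.PeptidePrediction],
    sd: float = 0.1,
    n_noise: int = 20,
    mz_range: tuple[float, float] = (100.0, 2000.0),
    seed: int = 0,
) -> tuple[massspec.PeakList, SpectrumTruth]:
    """Simulate a MALDI-TOF/PSD peak list for a set of peptides.

    Every precursor [M+H]+ and full singly charged b/y ladder is emitted with
    Gaussian(sd) m/z error; ``n_noise`` uniform peaks are added over
    ``mz_range``. Intensities are log-normal (noise an order dimmer).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    true_ions: list[tuple[str, float]] = []
    for p in peptides:
        ladder = massspec.fragment_ladder(p.sequence, p.amidated)
        true_ions.append((f"{p.sequence}:[M+H]+", ladder.precursor_mz))
        true_ions.extend((f"{p.sequence}:b{i}", mz) for i, mz in ladder.b_ions)
        true_ions.extend((f"{p.sequence}:y{i}", mz) for i, mz in ladder.y_ions)
    mz = [m + (rng.normal(0.0, sd) if sd > 0 else 0.0) for _, m in true_ions]
    intensity = list(rng.lognormal(mean=3.0, sigma=1.0, size=len(mz)))
    noise_mz = list(rng.uniform(*mz_range, size=n_noise))
    mz += noise_mz
    intensity += list(rng.lognormal(mean=1.0, sigma=1.0, size=n_noise))
    peaks = massspec.PeakList(mz, intensity, source_id=f"simulated_seed{seed}")
    return peaks, SpectrumTruth(
        peptides=[p.sequence for p in peptides],
        true_ions=true_ions, noise_mz=noise_mz, sd=sd, seed=seed)


def expected_p_differ(t: float) -> float:
    """P(two sequence states differ) after total path length t under the
    20-state uniform-exchange Markov model used by :func:`evolve_alignment`."""
    return (19.0 / 20.0) * (1.0 - np.exp(-20.0 * t / 19.0))


def evolve_alignment(
    tree: "dendropy.Tree | str",
    n_columns: int,
    seed: int = 0,
) -> phylo.MultipleAlignment:
    """Evolve an ungapped amino-acid alignment down a tree.

    The root sequence is uniform over the 20 residues; along a branch of
    length t each site keeps its state with probability
    1/20 + (19/20)exp(−20t/19) and otherwise becomes uniform over the other
    19 residues (the Markov transition of the Poisson-style model, so branch
    lengths are expected substitutions per site).
    """
    if isinstance(tree, str):
        tree = phylo.read_newick(tree)
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(phylo.AA20.encode(), dtype=np.uint8)
    states: dict[int, np.ndarray] = {
        id(tree.seed_node): rng.integers(0, 20, n_columns)}
    taxa, rows = [], []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            parent_states = states[id(node)]
        else:
            t = node.edge.length
            if t is None:
                raise ValueError("tree has branches without lengths")
            same = 1.0 / 20.0 + (19.0 / 20.0) * np.exp(-20.0 * t / 19.0)
            src = states[id(node.parent_node)]
            change = rng.random(n_columns) >= same
            shift = rng.integers(1, 20, n_columns)
            parent_states = np.where(change, (src + shift) % 20, src)
            states[id(node)] = parent_states
        if node.is_leaf():
            taxa.append(node.taxon.label)
            rows.append(bytes(aa[parent_states]).decode())
    return phylo.MultipleAlignment(taxa, rows)


def generate_synteny_tables(
    seed: int,
    n_genes: int = 41,
    k: int = 10,
    shared_fraction: float = 0.5,
):
    """Two single-scaffold gene tables with planted ortholog neighbors.

    ``round(shared_fraction * 2k)`` of the focal gene's 2k neighbors in table
    A receive an ortholog placed, in the same relative order, among the 2k
    neighbors of the focal gene in table B; the remaining genes are unrelated.
    Returns (table_a, table_b, orthology, focal_a, focal_b).
    """
    from .synteny import GeneTable, OrthologyMap
    import pandas as pd

    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    if n_genes < 2 * k + 1:
        raise ValueError("n_genes must be >= 2k + 1")
    rng = np.random.default_rng(seed)

    def make_table(tag: str) -> tuple[GeneTable, str, list[str]]:
        mid = n_genes // 2
        ids = [f"{tag}_g{i:03d}" for i in range(n_genes)]
        focal = f"focal_{tag}"
        ids[mid] = focal
        df = pd.DataFrame({
            "scaffold": f"scaf_{tag}",
            "start": np.arange(n_genes) * 1000,
            "end": np.arange(n_genes) * 1000 + 500,
            "gene_id": ids,
            "score": 0,
            "strand": ["+" if s else "-" for s in rng.integers(0, 2, n_genes)],
        })
        neighbors = ids[mid - k: mid] + ids[mid + 1: mid + k + 1]
        return GeneTable(df), focal, neighbors

    table_a, focal_a, nb_a = make_table("A")
    table_b, focal_b, nb_b = make_table("B")
    n_plant = round(shared_fraction * 2 * k)
    pick_a = sorted(rng.choice(2 * k, size=n_plant, replace=False))
    pick_b = sorted(rng.choice(2 * k, size=n_plant, replace=False))
    pairs = {(nb_a[i], nb_b[j]) for i, j in zip(pick_a, pick_b)}
    pairs.add((focal_a, focal_b))
    return table_a, table_b, OrthologyMap(frozenset(pairs)), focal_a, focal_b
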