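"""Neuropeptide precursor annotation.

Deduce a prepropeptide from an oriented cDNA and excise its mature peptides:
open-reading-frame scan, Kyte–Doolittle hydropathy, a (-3,-1)-rule signal
peptide heuristic, prohormone-convertase cleavage-site scan (dibasic,
[K/R]-X-X-R and Gly+monobasic amidation sites), peptide excision with
C-terminal amidation, and RFamide-family classification by C-terminal motif
(PQRFamide: ...Pro-Gln-Arg-Phe-NH2; LPXRFamide: ...Leu-Pro-[Leu/Gln]-Arg-Phe-NH2).

Coordinates are 0-based half-open internally; report writers print 1-based
inclusive positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "KYTE_DOOLITTLE",
    "NucleotideRecord",
    "OpenReadingFrame",
    "CleavageSite",
    "PeptidePrediction",
    "PrecursorAnnotation",
    "find_orfs",
    "hydropathy_profile",
    "predict_signal_peptide",
    "find_cleavage_sites",
    "extract_mature_peptides",
    "classify_rfamide_family",
    "annotate_precursor",
    "common_c_terminal_suffix",
]

#: Kyte & Doolittle hydropathy indices.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

BASIC = frozenset("KR")

#: (-3,-1)-rule residue sets: small/neutral at -1, small/aliphatic at -3.
MINUS1_RESIDUES = frozenset("AGSCTQ")
MINUS3_RESIDUES = frozenset("AVSCTGIL")

_DNA_RE = re.compile(r"^[ACGTN]+$")


class InputError(ValueError):
    """Raised for malformed sequences or inconsistent arguments."""


@dataclass(frozen=True)
class NucleotideRecord:
    """An oriented cDNA sequence (uppercase DNA over {A,C,G,T,N})."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"record {self.id!r}: empty sequence")
        if not _DNA_RE.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise InputError(f"record {self.id!r}: non-DNA characters {bad}")


@dataclass(frozen=True)
class OpenReadingFrame:
    """A forward-strand ORF; ``end`` excludes the stop codon."""

    start: int
    end: int
    frame: int
    protein: str
    complete: bool = True  # False when no in-frame stop before sequence end

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise InputError("ORF span not a multiple of 3")
        if len(self.protein) != (self.end - self.start) // 3:
            raise InputError("protein length inconsistent with ORF span")


@dataclass(frozen=True)
class CleavageSite:
    """A convertase cut; ``position`` indexes the first residue after the cut."""

    position: int
    motif: str
    kind: str  # dibasic | KXXR | glycine_basic


@dataclass(frozen=True)
class PeptidePrediction:
    """A mature peptide excised from a precursor (donor Gly excluded)."""

    sequence: str
    start: int
    end: int
    amidated: bool
    family: str  # PQRFa | LPXRFa | RFa | other
    n_flank_motif: str = ""
    c_flank_motif: str = ""


@dataclass
class PrecursorAnnotation:
    """Full annotation of one cDNA: ORF, signal boundary, cuts, peptides.

    ``orf`` is None when no ORF of the requested minimum length exists
    (a structured "no precursor" result rather than an exception).
    """

    record_id: str
    orf: OpenReadingFrame | None
    signal_end: int | None = None
    cleavage_sites: list[CleavageSite] = field(default_factory=list)
    peptides: list[PeptidePrediction] = field(default_factory=list)

    @property
    def has_precursor(self) -> bool:
        return self.orf is not None


def find_orfs(record: NucleotideRecord, min_codons: int) -> list[OpenReadingFrame]:
    """Scan the forward strand for ATG-initiated ORFs.

    Each ORF runs from an ATG to the first in-frame stop codon; ORFs reaching
    the sequence end without a stop are returned with ``complete=False``.
    Any ORF whose span contains an N is dropped (untranslatable codon).
    Sorted by protein length, longest first; ties by start position.
    """
    if min_codons < 1:
        raise InputError("min_codons must be positive")
    seq = record.sequence
    orfs: list[OpenReadingFrame] = []
    for frame in range(3):
        n_codons = (len(seq) - frame) // 3
        codons = [seq[frame + 3 * i: frame + 3 * i + 3] for i in range(n_codons)]
        stops = {i for i, c in enumerate(codons) if c in ("TAA", "TAG", "TGA")}
        for i, codon in enumerate(codons):
            if codon != "ATG":
                continue
            stop = next((j for j in sorted(stops) if j >= i), None)
            last = stop if stop is not None else n_codons
            span = seq[frame + 3 * i: frame + 3 * last]
            if "N" in span or len(span) < 3 * min_codons:
                continue
            protein = str(Seq(span).translate())
            orfs.append(OpenReadingFrame(
                start=frame + 3 * i,
                end=frame + 3 * last,
                frame=frame,
                protein=protein,
                complete=stop is not None,
            ))
    orfs.sort(key=lambda o: (-len(o.protein), o.start))
    return orfs


def hydropathy_profile(protein: str, window: int) -> list[tuple[int, float]]:
    """Sliding-window mean Kyte–Doolittle hydropathy.

    Returns one ``(center_index, mean)`` per window placement.
    """
    if window < 1 or window % 2 == 0:
        raise InputError("window must be a positive odd integer")
    if window > len(protein):
        raise InputError("window longer than protein")
    for pos, aa in enumerate(protein):
        if aa not in KYTE_DOOLITTLE:
            raise InputError(f"unknown residue {aa!r} at position {pos}")
    vals = [KYTE_DOOLITTLE[aa] for aa in protein]
    half = window // 2
    out = []
    for start in range(len(protein) - window + 1):
        out.append((start + half, sum(vals[start:start + window]) / window))
    return out


def predict_signal_peptide(
    protein: str,
    window: int = 7,
    threshold: float = 1.6,
    search_limit: int = 40,
) -> int | None:
    """Heuristic secretory signal-peptide boundary.

    Looks for a hydrophobic core (maximum ``window``-residue mean hydropathy
    >= ``threshold``) within the first ``search_limit`` residues, then applies
    the (-3,-1) rule downstream of the core: a cut at ``p`` needs a small
    neutral residue at ``p-1`` and a small/aliphatic residue at ``p-3``.
    Returns the 0-based index of the first mature residue, or None.
    """
    if len(protein) < 15:
        return None
    head = protein[: min(search_limit, len(protein))]
    if len(head) < window:
        return None
    prof = hydropathy_profile(head, window)
    best = max(v for _, v in prof)
    if best < threshold:
        return None
    # earliest window attaining the maximum; core ends after its last residue
    core_center = next(c for c, v in prof if v == best)
    core_end = core_center + window // 2 + 1
    for p in range(core_end, min(core_end + 9, len(protein) + 1)):
        if p < 3 or p >= len(protein):
            continue
        if protein[p - 1] in MINUS1_RESIDUES and protein[p - 3] in MINUS3_RESIDUES:
            return p
    return None


_DIBASIC_RE = re.compile(r"(?=([KR][KR]))")
_KXXR_RE = re.compile(r"(?=([KR][^P][^P]R))")
_GLY_BASIC_RE = re.compile(r"(?=(G[KR]))")


def find_cleavage_sites(protein: str) -> list[CleavageSite]:
    """Scan for prohormone-convertase cleavage motifs.

    Three motif classes, all cutting C-terminal to the motif:

    * dibasic pairs (KR, RR, KK, RK);
    * furin-type tetrapeptides [K/R]-X-X-R;
    * a single basic residue immediately preceded by Gly (``glycine_basic``),
      the amidation-competent monobasic site.

    Proline blocks processing: X positions of [K/R]XXR may not be Pro, and no
    cut is reported immediately before a Pro. Overlapping motifs are all
    reported; duplicates collapse on (position, kind).
    """
    sites: dict[tuple[int, str], CleavageSite] = {}

    def blocked(cut: int) -> bool:
        return cut < len(protein) and protein[cut] == "P"

    for m in _DIBASIC_RE.finditer(protein):
        cut = m.start() + 2
        if not blocked(cut):
            sites[(cut, "dibasic")] = CleavageSite(cut, m.group(1), "dibasic")
    for m in _KXXR_RE.finditer(protein):
        cut = m.start() + 4
        if not blocked(cut):
            sites[(cut, "KXXR")] = CleavageSite(cut, m.group(1), "KXXR")
    for m in _GLY_BASIC_RE.finditer(protein):
        cut = m.start() + 2
        if not blocked(cut):
            sites[(cut, "glycine_basic")] = CleavageSite(cut, m.group(1), "glycine_basic")
    return sorted(sites.values(), key=lambda s: (s.position, s.kind))


def classify_rfamide_family(sequence: str, amidated: bool) -> str:
    """Classify by the C-terminal motif; the amide is required by definition.

    Priority: LPXRFa (suffix LP[L/Q]RF) > PQRFa (suffix PQRF) > RFa (suffix RF).
    Non-amidated peptides are always ``other``.
    """
    if not amidated:
        return "other"
    tail = sequence[-5:]
    if len(tail) == 5 and tail[:2] == "LP" and tail[2] in "LQ" and tail[3:] == "RF":
        return "LPXRFa"
    if sequence.endswith("PQRF"):
        return "PQRFa"
    if sequence.endswith("RF"):
        return "RFa"
    return "other"


def extract_mature_peptides(
    protein: str,
    signal_end: int | None,
    sites: list[CleavageSite],
    min_length: int = 3,
    max_length: int = 50,
    require_amidation: bool = True,
) -> list[PeptidePrediction]:
    """Excise peptides between the union of cut points.

    Segments run between consecutive cuts (bounded by the signal-peptide end
    and the protein end). Trailing basic residues belong to the flanking motif
    and are stripped; a remaining C-terminal Gly followed by a basic residue is
    the amide donor — it is trimmed and the peptide flagged amidated. Segments
    outside [min_length, max_length] are discarded. By default only amidated
    (secretion-competent) peptides are reported; set ``require_amidation=False``
    to keep every segment.
    """
    if signal_end is not None and signal_end > len(protein):
        raise InputError("signal_end beyond protein length")
    origin = signal_end or 0
    cuts = sorted({s.position for s in sites if s.position > origin}
                  | {origin, len(protein)})
    motif_at = {}
    for s in sites:
        motif_at.setdefault(s.position, s.motif)

    peptides: list[PeptidePrediction] = []
    for a, b in zip(cuts, cuts[1:]):
        e = b
        while e > a and protein[e - 1] in BASIC:
            e -= 1
        amidated = e > a and protein[e - 1] == "G" and e < len(protein) and protein[e] in BASIC
        if amidated:
            e -= 1
        seq = protein[a:e]
        if not (min_length <= len(seq) <= max_length):
            continue
        if require_amidation and not amidated:
            continue
        peptides.append(PeptidePrediction(
            sequence=seq,
            start=a,
            end=e,
            amidated=amidated,
            family=classify_rfamide_family(seq, amidated),
            n_flank_motif=motif_at.get(a, ""),
            c_flank_motif=motif_at.get(b, ""),
        ))
    return peptides


def annotate_precursor(
    record: NucleotideRecord,
    min_codons: int = 50,
    signal_window: int = 7,
    signal_threshold: float = 1.6,
    require_amidation: bool = True,
) -> PrecursorAnnotation:
    """Full cDNA-to-peptides pipeline: longest ORF, signal, cuts, peptides."""
    orfs = find_orfs(record, min_codons)
    if not orfs:
        return PrecursorAnnotation(record_id=record.id, orf=None)
    orf = orfs[0]
    signal_end = predict_signal_peptide(
        orf.protein, window=signal_window, threshold=signal_threshold)
    sites = find_cleavage_sites(orf.protein)
    peptides = extract_mature_peptides(
        orf.protein, signal_end, sites, require_amidation=require_amidation)
    return PrecursorAnnotation(
        record_id=record.id,
        orf=orf,
        signal_end=signal_end,
        cleavage_sites=sites,
        peptides=peptides,
    )


def common_c_terminal_suffix(sequences: list[str]) -> str:
    """Longest amino-acid suffix shared by all sequences."""
    if not sequences:
        return ""
    shortest = min(len(s) for s in sequences)
    suffix = ""
    for i in range(1, shortest + 1):
        tails = {s[-i:] for s in sequences}
        if len(tails) == 1:
            suffix = tails.pop()
        else:
            break
    return suffix
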