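"""Peptide masses, b/y fragment ladders and MALDI-TOF peak assignment.

Monoisotopic residue masses are summed directly; a C-terminal amide replaces
the free-acid OH with NH2 (delta −0.984016 Da). Only singly protonated ions
are modelled, as produced by MALDI post-source decay: b_i carries the first i
residues plus a proton, y_i the last i residues plus water (amidated for the
C-terminal fragment), plus a proton.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

from .precursor import InputError, PeptidePrediction

__all__ = [
    "MONOISOTOPIC", "AVERAGE", "WATER", "PROTON", "AMIDE_DELTA",
    "PeakList", "FragmentLadder", "MatchResult",
    "peptide_monoisotopic_mass", "singly_protonated_mz",
    "fragment_ladder", "match_peaks", "identify_peptides",
]

#: Monoisotopic residue (amino-acid minus water) masses, Da.
MONOISOTOPIC = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: Average residue masses, Da (reporting option; not the default mode).
AVERAGE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER = 18.010565
PROTON = 1.007276
AMIDE_DELTA = -0.984016  # C-terminal OH -> NH2


def _residue_sum(sequence: str, table: dict[str, float]) -> float:
    total = 0.0
    for pos, aa in enumerate(sequence):
        try:
            total += table[aa]
        except KeyError:
            raise InputError(f"non-standard residue {aa!r} at position {pos}") from None
    return total


def peptide_monoisotopic_mass(sequence: str, amidated: bool, *, average: bool = False) -> float:
    """Neutral peptide mass: residue sum + water (+ amide delta if amidated)."""
    if not sequence:
        raise InputError("empty peptide")
    table = AVERAGE if average else MONOISOTOPIC
    return _residue_sum(sequence, table) + WATER + (AMIDE_DELTA if amidated else 0.0)


def singly_protonated_mz(neutral_mass: float) -> float:
    """[M+H]+ m/z of a neutral mass."""
    if neutral_mass < 0:
        raise InputError("negative neutral mass")
    return neutral_mass + PROTON


@dataclass
class PeakList:
    """An observed spectrum: (m/z, intensity) pairs, sorted ascending on m/z."""

    mz: list[float]
    intensity: list[float]
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensity):
            raise InputError("mz and intensity length mismatch")
        if any(m <= 0 for m in self.mz):
            raise InputError("non-positive m/z in peak list")
        if any(i < 0 for i in self.intensity):
            raise InputError("negative intensity in peak list")
        order = sorted(range(len(self.mz)), key=self.mz.__getitem__)
        self.mz = [self.mz[i] for i in order]
        self.intensity = [self.intensity[i] for i in order]

    @classmethod
    def from_tsv(cls, path: str | Path, source_id: str | None = None) -> "PeakList":
        """Read a 2-column (m/z, intensity) whitespace/TSV peak list."""
        mz, inten = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            mz.append(float(parts[0]))
            inten.append(float(parts[1]) if len(parts) > 1 else 1.0)
        return cls(mz, inten, source_id or Path(path).stem)

    @classmethod
    def from_mgf(cls, path: str | Path) -> list["PeakList"]:
        """Read all spectra from an MGF file (one PeakList per BEGIN IONS block)."""
        from pyteomics import mgf
        out = []
        with mgf.MGF(str(path)) as reader:
            for i, spec in enumerate(reader):
                out.append(cls(
                    list(map(float, spec["m/z array"])),
                    list(map(float, spec["intensity array"])),
                    str(spec.get("params", {}).get("title", f"spectrum_{i}")),
                ))
        return out


@dataclass(frozen=True)
class FragmentLadder:
    """Theoretical singly charged b/y series of one peptide."""

    sequence: str
    amidated: bool
    b_ions: tuple[tuple[int, float], ...]
    y_ions: tuple[tuple[int, float], ...]

    @property
    def precursor_mz(self) -> float:
        return singly_protonated_mz(
            peptide_monoisotopic_mass(self.sequence, self.amidated))


def fragment_ladder(sequence: str, amidated: bool) -> FragmentLadder:
    """Compute b_1..b_{n-1} and y_1..y_{n-1} for a peptide of length n >= 2.

    Complementarity: b_i + y_{n-i} = [M+H]+ + proton for every i.
    """
    n = len(sequence)
    if n < 2:
        raise InputError("fragment ladder needs length >= 2")
    prefix = 0.0
    b = []
    for i in range(1, n):
        prefix += MONOISOTOPIC[_check(sequence[i - 1], i - 1)]
        b.append((i, prefix + PROTON))
    cterm = WATER + (AMIDE_DELTA if amidated else 0.0)
    suffix = 0.0
    y = []
    for i in range(1, n):
        suffix += MONOISOTOPIC[_check(sequence[n - i], n - i)]
        y.append((i, suffix + cterm + PROTON))
    return FragmentLadder(sequence, amidated, tuple(b), tuple(y))


def _check(aa: str, pos: int) -> str:
    if aa not in MONOISOTOPIC:
        raise InputError(f"non-standard residue {aa!r} at position {pos}")
    return aa


@dataclass
class MatchResult:
    """Tolerance-based assignment of theoretical ions to observed peaks."""

    assignments: list[tuple[str, float, float, float]]  # (ion label, theo, obs, error)
    coverage: float
    precursor_error: float | None = None
    ambiguous: list[str] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.assignments)


def _nearest_peak(mz_sorted: list[float], target: float) -> float | None:
    if not mz_sorted:
        return None
    i = bisect.bisect_left(mz_sorted, target)
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(mz_sorted):
            if best is None or abs(mz_sorted[j] - target) < abs(best - target):
                best = mz_sorted[j]
    return best


def match_peaks(peaks: PeakList, ladder: FragmentLadder, tolerance: float = 0.5) -> MatchResult:
    """Assign each theoretical b/y ion its nearest observed peak within tolerance.

    An observed peak may serve several theoretical ions only when their
    theoretical m/z differ by less than the tolerance; such sharing is listed
    in ``ambiguous``. Coverage is the matched fraction of theoretical ions.
    """
    if tolerance <= 0:
        raise InputError("tolerance must be positive")
    theo = [(f"b{i}", mz) for i, mz in ladder.b_ions] + \
           [(f"y{i}", mz) for i, mz in ladder.y_ions]
    assignments = []
    used: dict[float, list[tuple[str, float]]] = {}
    for label, t_mz in theo:
        obs = _nearest_peak(peaks.mz, t_mz)
        if obs is None or abs(obs - t_mz) > tolerance:
            continue
        assignments.append((label, t_mz, obs, obs - t_mz))
        used.setdefault(obs, []).append((label, t_mz))
    ambiguous = []
    for obs, claimants in used.items():
        if len(claimants) > 1:
            spread = max(m for _, m in claimants) - min(m for _, m in claimants)
            if spread < tolerance:
                ambiguous.extend(lbl for lbl, _ in claimants)
            else:
                # peak cannot honestly serve well-separated ions: keep nearest only
                keep = min(claimants, key=lambda c: abs(obs - c[1]))
                assignments = [a for a in assignments
                               if a[2] != obs or a[0] == keep[0]]
    coverage = len(assignments) / len(theo) if theo else 0.0
    return MatchResult(assignments=assignments, coverage=coverage, ambiguous=sorted(ambiguous))


def identify_peptides(
    peaks: PeakList,
    candidates: list[PeptidePrediction],
    tolerance: float = 0.5,
) -> list[tuple[PeptidePrediction, MatchResult]]:
    """Rank candidate peptides against an observed spectrum.

    Order: precursor [M+H]+ matched within tolerance first, then fragment
    coverage (descending), then |precursor error| (ascending), then sequence
    as a deterministic final tie-break.
    """
    if not candidates:
        raise InputError("no candidate peptides")
    scored = []
    for cand in candidates:
        ladder = fragment_ladder(cand.sequence, cand.amidated)
        result = match_peaks(peaks, ladder, tolerance)
        obs = _nearest_peak(peaks.mz, ladder.precursor_mz)
        if obs is not None and abs(obs - ladder.precursor_mz) <= tolerance:
            result.precursor_error = obs - ladder.precursor_mz
        scored.append((cand, result))
    scored.sort(key=lambda cr: (
        cr[1].precursor_error is None,
        -cr[1].coverage,
        abs(cr[1].precursor_error) if cr[1].precursor_error is not None else float("inf"),
        cr[0].sequence,
    ))
    return scored
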