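"""Precursor annotation: ORFs, hydropathy, signal cut, cleavage, excision."""

import pytest
from hypothesis import given, strategies as st

from rfamide import precursor as pre
from _oracles import exhaustive_signal_scan


@pytest.mark.parametrize("dna,min_codons,protein,start,end", [
    ("ATGAAATAG", 2, "MK", 0, 6),       # shortest start-stop case
    ("CCATGGCTTGA", 2, "MA", 2, 8),     # offset reading frame
])
def test_find_orfs_examples(dna, min_codons, protein, start, end):
    orfs = pre.find_orfs(pre.NucleotideRecord("t", dna), min_codons)
    assert [(o.protein, o.start, o.end) for o in orfs] == [(protein, start, end)]
    assert orfs[0].complete


def test_find_orfs_sorted_longest_first_and_n_excluded():
    # two ORFs in different frames; the longer comes first
    dna = "ATGAAAAAAAAATAG" + "CATGGCTTGA"
    orfs = pre.find_orfs(pre.NucleotideRecord("t", dna), 2)
    lengths = [len(o.protein) for o in orfs]
    assert lengths == sorted(lengths, reverse=True)
    # an N anywhere in the span kills the ORF
    assert pre.find_orfs(pre.NucleotideRecord("t", "ATGANATAG"), 2) == []


def test_find_orfs_incomplete_flagged():
    orfs = pre.find_orfs(pre.NucleotideRecord("t", "ATGAAAAAA"), 2)
    assert len(orfs) == 1 and not orfs[0].complete


def test_empty_sequence_rejected():
    with pytest.raises(pre.InputError):
        pre.NucleotideRecord("t", "")


@pytest.mark.parametrize("protein,window,expected", [
    ("IIIIIIIII", 9, 4.5),     # Ile index
    ("RRRRRRRRR", 9, -4.5),    # Arg index
    ("AIAIAIAIA", 9, (1.8 * 5 + 4.5 * 4) / 9),
])
def test_hydropathy_single_window(protein, window, expected):
    prof = pre.hydropathy_profile(protein, window)
    assert len(prof) == 1
    assert prof[0] == (4, pytest.approx(expected))


def test_hydropathy_unknown_residue_names_position():
    with pytest.raises(pre.InputError, match="position 2"):
        pre.hydropathy_profile("AAZAA", 3)


def test_signal_peptide_matches_exhaustive_scan():
    cases = [
        "MKWLLLLLLLLLLLLLASAADEFHIKNQ",
        "MKW" + "L" * 12 + "ASA" + "DDEEQQNNHH",
        "MDDDDDDDDDDDDDDDDDDD",       # no hydrophobic core
        "MKWLLLLL",                    # too short
        "M" + "I" * 20 + "Q" * 20,
    ]
    for protein in cases:
        assert pre.predict_signal_peptide(protein) == exhaustive_signal_scan(protein)


def test_signal_peptide_absent_without_core():
    assert pre.predict_signal_peptide("MDDDDDDDDDDDDDDDDDDD") is None


def test_cleavage_kvsr_is_kxxr():
    sites = pre.find_cleavage_sites("AAKVSRAA")
    assert [(s.motif, s.position, s.kind) for s in sites] == [("KVSR", 6, "KXXR")]


def test_cleavage_none_without_basics():
    assert pre.find_cleavage_sites("AAAAAA") == []


def test_cleavage_gly_basic_amide_donor():
    # RFGR decomposes as amide-donor G + monobasic R; cut position 6
    sites = pre.find_cleavage_sites("PQRFGRSS")
    assert {s.position for s in sites} == {6}
    kinds = {s.kind: s.motif for s in sites}
    assert kinds["glycine_basic"] == "GR"


def test_cleavage_blocked_by_proline():
    # RPQR would otherwise cut inside every PQRFamide peptide
    assert pre.find_cleavage_sites("WDEAWRPQRF") == []
    assert all(s.kind != "dibasic" for s in pre.find_cleavage_sites("AKRPAA"))


def test_cleavage_rsgr_classified_kxxr():
    sites = pre.find_cleavage_sites("AARSGRAA")
    assert any(s.kind == "KXXR" and s.motif == "RSGR" for s in sites)


def test_extract_scaffold_yields_single_amidated_peptide():
    protein = "MKW" + "L" * 12 + "ASA" + "AKVSR" + "WDEAWRPQRF" + "GRSGR"
    signal_end = pre.predict_signal_peptide(protein)
    sites = pre.find_cleavage_sites(protein)
    peptides = pre.extract_mature_peptides(protein, signal_end, sites)
    assert [(p.sequence, p.amidated, p.family) for p in peptides] == [
        ("WDEAWRPQRF", True, "PQRFa")]
    # the amide-donor Gly sits exactly at the peptide's end coordinate
    assert protein[peptides[0].end] == "G"


def test_extract_no_sites_empty():
    assert pre.extract_mature_peptides("MAAAAAAAAAA", None, []) == []


def test_extract_signal_end_out_of_range():
    with pytest.raises(pre.InputError):
        pre.extract_mature_peptides("MAAA", 99, [])


def test_extracted_peptides_never_contain_dibasic():
    protein = ("MKW" + "L" * 12 + "ASA" + "AKVSR" + "WDEAWRPQRF" + "GKR"
               + "TTT" + "RR" + "NQDEPQRF" + "GR" + "SSSS")
    sites = pre.find_cleavage_sites(protein)
    for p in pre.extract_mature_peptides(protein, None, sites,
                                         require_amidation=False):
        assert not any(a in "KR" and b in "KR"
                       for a, b in zip(p.sequence, p.sequence[1:]))


@pytest.mark.parametrize("seq,amidated,family", [
    ("WDEAWRPQRF", True, "PQRFa"),
    ("SGTGLSATLPQRF", True, "LPXRFa"),
    ("SGTGLSATLPLRF", True, "LPXRFa"),
    ("WDEAWRPQRF", False, "other"),
    ("AAAARF", True, "RFa"),
    ("AAAAKF", True, "other"),
])
def test_classify_family(seq, amidated, family):
    assert pre.classify_rfamide_family(seq, amidated) == family


@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=30),
       st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=30))
def test_classify_depends_only_on_cterminal_five(a, b):
    """Sequences sharing their last five residues classify identically."""
    merged = b[:-5] + a[-5:]
    assert pre.classify_rfamide_family(a, True) == \
        pre.classify_rfamide_family(merged, True)


def test_annotate_trivial_orf_no_peptides():
    ann = pre.annotate_precursor(pre.NucleotideRecord("t", "ATGAAATAG"),
                                 min_codons=2)
    assert ann.has_precursor and ann.orf.protein == "MK"
    assert ann.signal_end is None and ann.peptides == []


def test_annotate_no_orf_is_structured_result():
    ann = pre.annotate_precursor(pre.NucleotideRecord("t", "CCCCCCCCC"),
                                 min_codons=2)
    assert not ann.has_precursor and ann.peptides == []


def test_common_suffix():
    assert pre.common_c_terminal_suffix(["ABCRF", "XXCRF", "CRF"]) == "CRF"
    assert pre.common_c_terminal_suffix(["AB", "CD"]) == ""
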