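"""Slippery-site scanning, pseudoknot enumeration, PRF detection, fusion."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import bruteforce_pseudoknots, pseudoknot_tuples
from totiscan.genome_model import GenomeRecord, Region
from totiscan.orf_annotation import find_orfs
from totiscan.prf_scanner import (
    build_fusion,
    detect_prf,
    find_pseudoknot,
    is_slippery,
    scan_slippery,
)

heptamer = st.text(alphabet="ACGU", min_size=7, max_size=7)


@pytest.mark.parametrize(
    "hept,strict,relaxed",
    [
        ("GGGUUUA", True, True),  # classic yeast-totivirus site
        ("UGUUUUC", False, True),  # X-triplet not identical
        ("GGAUUUU", False, True),
        ("AAAAAAA", True, True),
        ("GGGUUUG", False, False),  # Z must be A/C/U
        ("GGGUCUA", False, False),  # Y-triplet broken
    ],
)
def test_slippery_dialects(hept, strict, relaxed):
    assert is_slippery(hept, "strict") is strict
    assert is_slippery(hept, "relaxed") is relaxed


@given(hept=heptamer)
def test_strict_hits_are_subset_of_relaxed(hept):
    assert not is_slippery(hept, "strict") or is_slippery(hept, "relaxed")


def test_scan_slippery_respects_window_bounds():
    genome = GenomeRecord(id="s", sequence="CCGGGUUUACC")
    hits = scan_slippery(genome, Region(1, 11, "orf"), "strict")
    assert [(h.region.start, h.heptamer) for h in hits] == [(3, "GGGUUUA")]
    # heptamer must fit entirely inside the window
    assert scan_slippery(genome, Region(1, 8, "orf"), "strict") == []
    with pytest.warns(UserWarning, match="shorter than 7"):
        assert scan_slippery(genome, Region(1, 5, "orf"), "strict") == []


def _planted_pseudoknot_window() -> tuple[str, tuple]:
    # stem1 5nt GCGCG / loopA AA / stem2 4nt GGGG / loopB AA /
    # stem1' CGCGC / loopC AAA / stem2' CCCC  -> 25 nt, EFE -27
    s = "GCGCG" + "AA" + "GGGG" + "AA" + "CGCGC" + "AAA" + "CCCC"
    planted = ((1, 5), (14, 18), (8, 11), (22, 25))
    return s, planted


def test_find_pseudoknot_recovers_planted_stems():
    s, (s1l, s1r, s2l, s2r) = _planted_pseudoknot_window()
    genome = GenomeRecord(id="pk", sequence=s)
    top = find_pseudoknot(genome, 1, max_extent=len(s))[0]
    assert (top.stem1[0].start, top.stem1[0].end) == s1l
    assert (top.stem1[1].start, top.stem1[1].end) == s1r
    assert (top.stem2[0].start, top.stem2[0].end) == s2l
    assert (top.stem2[1].start, top.stem2[1].end) == s2r
    assert top.efe == -27.0
    assert (top.region.start, top.region.end) == (1, 25)


def test_find_pseudoknot_no_complementarity():
    genome = GenomeRecord(id="a", sequence="A" * 40)
    assert find_pseudoknot(genome, 1, max_extent=40) == []


def test_find_pseudoknot_rejects_plain_hairpin():
    # perfect hairpin, but nothing downstream to cross with
    genome = GenomeRecord(id="h", sequence="GGGGGAAAACCCCC")
    assert find_pseudoknot(genome, 1, max_extent=14) == []


def test_pseudoknot_enumeration_matches_bruteforce():
    rng = random.Random(5)
    for _ in range(25):
        n = rng.randint(25, 48)
        s = "".join(rng.choice("ACGU") for _ in range(n))
        genome = GenomeRecord(id="w", sequence=s)
        got = find_pseudoknot(genome, 1, max_extent=n)
        assert pseudoknot_tuples(got) == bruteforce_pseudoknots(s)
        keys = [(p.efe, p.region.length, p.region.start) for p in got]
        assert keys == sorted(keys)


def test_detect_prf_on_fixture(fixture_signal):
    """The planted signal is recovered with the printed geometry."""
    sig = fixture_signal
    assert sig.complete
    assert (sig.slippery.region.start, sig.slippery.region.end) == (2104, 2110)
    assert sig.slippery.heptamer == "UGUUUUC"
    assert sig.spacer.length == 19
    assert (sig.pseudoknot.region.start, sig.pseudoknot.region.end) == (2130, 2154)
    assert sig.pseudoknot.efe <= -27.0
    # geometric identity linking the three elements
    assert sig.spacer.length == sig.pseudoknot.region.start - sig.slippery.region.end - 1


def test_detect_prf_partial_signal_without_pseudoknot():
    # ORF carrying a slippery site followed by poly-A: no structure downstream
    seq = "AUG" + "GCA" * 10 + "GGGUUUA" + "A" * 62 + "UAA"
    genome = GenomeRecord(id="p", sequence=seq)
    (orf,) = find_orfs(genome, min_length_nt=30)
    sig = detect_prf(genome, orf)
    assert sig.slippery is not None and sig.pseudoknot is None and not sig.complete
    assert any("pseudoknot" in d for d in sig.diagnostics)


def test_detect_prf_prefers_site_with_valid_pseudoknot():
    # two slippery sites; only the second has a pseudoknot in spacer range
    pk, _ = _planted_pseudoknot_window()
    seq = "AUG" + "GCA" * 6 + "GGGUUUA" + "GCA" * 12 + "GGGUUUA" + "CA" + "ACCAA" + pk
    pad = (3 - (len(seq) + 3) % 3) % 3
    seq = seq + "G" * pad + "UAA"
    genome = GenomeRecord(id="two", sequence=seq)
    (orf,) = find_orfs(genome, min_length_nt=30)
    sig = detect_prf(genome, orf)
    assert sig.complete
    second_site_start = seq.index("GGGUUUA", seq.index("GGGUUUA") + 1) + 1
    assert sig.slippery.region.start == second_site_start


def test_build_fusion_hand_computed_toy():
    # 0-frame: AUG AAA GGG UUU AUU AAA UAA -> MKGFIK
    # slip at the heptamer (7-13) boundary nt 12; -1 frame: UAU UAA
    seq = "AUGAAAGGGUUUAUUAAAUAA"
    genome = GenomeRecord(id="toy", sequence=seq)
    (orf,) = find_orfs(genome, min_length_nt=21)
    (site,) = scan_slippery(genome, Region(7, 13, "orf"), "strict")
    fusion = build_fusion(genome, orf, site)
    assert fusion.protein == "MKGFY"
    assert fusion.protein_length == 5
    assert (fusion.cds_span.start, fusion.cds_span.end) == (1, 17)
    assert fusion.cds_span.length + 1 == 3 * (fusion.protein_length + 1)
    assert fusion.overlap_nt == orf.region.end - 3 + 1  # -1 frame stop-free from 3


def test_fusion_on_fixture(fixture_genome, fixture_orfs, fixture_signal):
    fusion = fixture_signal.fusion
    assert fusion.protein_length == 1518
    assert (fusion.cds_span.start, fusion.cds_span.end) == (98, 4653)
    assert fusion.cds_span.length == 4556
    assert fusion.overlap_nt == 172


def test_fusion_length_invariant_under_slip_codon_offset(
    fixture_genome, fixture_orfs, fixture_signal
):
    orf1 = fixture_orfs[0]
    site = fixture_signal.slippery
    lengths = set()
    overlaps = set()
    for offset in (-1, 0, 1):
        fusion = build_fusion(fixture_genome, orf1, site, slip_codon_offset=offset)
        lengths.add(fusion.protein_length)
        overlaps.add(fusion.overlap_nt)
    assert lengths == {1518} and overlaps == {172}


def test_build_fusion_runaway_frame_errors():
    seq = "AUG" + "AAA" + "GGGUUUA" + "CA" + "UAA" + "A" * 12
    genome = GenomeRecord(id="run", sequence=seq)
    (orf,) = find_orfs(genome, min_length_nt=18)
    (site,) = scan_slippery(genome, Region(7, 13, "orf"), "strict")
    with pytest.raises(ValueError, match="runaway"):
        build_fusion(genome, orf, site)


def test_build_fusion_stop_immediately_after_slip_errors():
    seq = "AUG" + "AAA" + "GGGUUUA" + "AA" + "UAA" + "CCC"
    genome = GenomeRecord(id="stop", sequence=seq)
    (orf,) = find_orfs(genome, min_length_nt=18)
    (site,) = scan_slippery(genome, Region(7, 13, "orf"), "strict")
    with pytest.raises(ValueError, match="immediately after slip"):
        build_fusion(genome, orf, site)


def test_build_fusion_requires_site_inside_orf(fixture_genome, fixture_orfs):
    orf2 = fixture_orfs[1]
    site = scan_slippery(fixture_genome, Region(2104, 2110, "orf"), "relaxed")[0]
    with pytest.raises(ValueError, match="inside ORF1"):
        build_fusion(fixture_genome, orf2, site)
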