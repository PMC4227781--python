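"""Calling: boundary resolution, target sites, groups, DRs, composition, TSD."""

import numpy as np
import pytest

import istronkit as ik
from istronkit.caller import (
    IStronModel,
    _longest_common_substring,
    resolve_boundaries,
)
from istronkit.grammar import BCIST1_DR, major_group, revcomp
from istronkit.records import GenomeRecord
from istronkit.screen import MobileORF, extract_upstream
from istronkit.structure import scan_intron_signature

from oracles import lcs_oracle


def _true_candidate(rec, truth, orf):
    window = extract_upstream(rec, orf)
    for cand in scan_intron_signature(window):
        if window.to_genome(cand.intron_start) == truth.istron_start:
            return cand, window
    raise AssertionError("true candidate not found by the scanner")


def _mobile_orf_b(rec, truth):
    return MobileORF(rec.id, truth.orf_b_span[0], truth.orf_b_span[1], "+", "", "test")


# ---------------------------------------------------------------------------
# resolve_boundaries
# ---------------------------------------------------------------------------

def test_homolog_method_recovers_exact_boundaries(locus_b):
    rec, truth = locus_b
    hom = ik.make_istronless_homolog(rec, truth, divergence=0.0, seed=1)
    orf = _mobile_orf_b(rec, truth)
    cand, _ = _true_candidate(rec, truth, orf)
    resolved = resolve_boundaries(cand, orf, None, [hom], genome=rec)
    assert resolved is not None
    bounds, evidence = resolved
    assert (bounds.istron_start, bounds.istron_end) == (truth.istron_start, truth.istron_end)
    assert "homolog_alignment" in evidence


def test_structural_method_group_a(locus_a):
    rec, truth = locus_a
    orf = _mobile_orf_b(rec, truth)
    cand, _ = _true_candidate(rec, truth, orf)
    resolved = resolve_boundaries(cand, orf, None, [], genome=rec)
    assert resolved is not None
    bounds, evidence = resolved
    assert (bounds.istron_start, bounds.istron_end) == (truth.istron_start, truth.istron_end)
    assert {"known_ends", "structural_enclosure"} <= evidence
    assert rec.sequence[bounds.istron_end - 4 : bounds.istron_end] == "TCAG"


def test_intron_ending_upstream_of_mobile_gene_is_not_an_istron(locus_b):
    rec, truth = locus_b
    # a mobile gene far downstream of the element: independent intron + IS
    far = MobileORF(rec.id, truth.istron_end + 300, truth.istron_end + 900, "+", "", "test")
    hom = ik.make_istronless_homolog(rec, truth, divergence=0.0, seed=1)
    orf_b = _mobile_orf_b(rec, truth)
    cand, _ = _true_candidate(rec, truth, orf_b)
    assert resolve_boundaries(cand, far, None, [hom], genome=rec) is None


def test_low_identity_homolog_abstains(locus_b):
    rec, truth = locus_b
    other = GenomeRecord("unrelated", "".join(
        np.random.default_rng(5).choice(list("ACGT"), size=1200)))
    orf = _mobile_orf_b(rec, truth)
    cand, _ = _true_candidate(rec, truth, orf)
    resolved = resolve_boundaries(cand, orf, None, [other], genome=rec)
    # the unrelated homolog abstains; structural evidence may still resolve
    if resolved is not None:
        assert "homolog_alignment" not in resolved[1]


# ---------------------------------------------------------------------------
# detect_target_site / classify_group
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "flank,expected",
    [
        ("CCCATTAT", [("ATTAT", "A")]),
        ("CCCCGAGG", [("GAGG", "B")]),
        ("CCCCC", []),
    ],
)
def test_detect_target_site(flank, expected):
    hyps = ik.detect_target_site(flank)
    for motif, group in expected:
        assert (motif, group) in hyps
    if not expected:
        assert hyps == []
    # B-variant AG matches as a suffix of GG-free AG-ending flanks
    assert ("AG", "B-variant") in ik.detect_target_site("CCTAG")


def _model(site, terminus, **kw):
    return IStronModel(
        name="m", genome_id="g", strand="+", exon5_end=100, istron_start=100,
        istron_end=600, target_site=(site, (95, 100)) if site else None,
        group="unclassified", terminus_motif=terminus, **kw,
    )


@pytest.mark.parametrize(
    "site,terminus,expected",
    [
        ("TTGAT", "TCAG", "A"),
        ("AGGG", "CGG", "B"),
        ("AG", "CAG", "B-variant"),
        ("TTGAT", "CGG", "unclassified"),
    ],
)
def test_classify_group(site, terminus, expected):
    group, flags = ik.classify_group(_model(site, terminus))
    assert group == expected
    if expected == "unclassified":
        assert "site-terminus-conflict" in flags


def test_classify_group_strand_invariant(locus_b, refs):
    rec, truth = locus_b
    hom = ik.make_istronless_homolog(rec, truth, 0.0, seed=1)
    fwd = ik.call_istrons(rec, refs, homologs=[hom])
    flipped = ik.flip_record(rec)
    rev = ik.call_istrons(flipped, refs, homologs=[hom])
    n = len(rec.sequence)
    assert len(fwd) == len(rev) == 1
    assert rev[0].group == fwd[0].group
    assert (rev[0].istron_start, rev[0].istron_end) == (
        n - fwd[0].istron_end, n - fwd[0].istron_start)


# ---------------------------------------------------------------------------
# direct repeats
# ---------------------------------------------------------------------------

def test_find_drs_bcist1_motif():
    template = ik.bcist1_like_template(seed=2)
    rec, truth = ik.simulate_locus(template, seed=31)
    region = rec.sequence[truth.istron_start : truth.istron_end]
    stem = ik.HairpinStem(
        arm5=(truth.ir5_span[0] - truth.istron_start, truth.ir5_span[1] - truth.istron_start),
        arm3=(truth.ir3_span[0] - truth.istron_start, truth.ir3_span[1] - truth.istron_start),
        loop=(0, 0), stem_length_bp=21, au_pair_fraction=0.85,
    )
    dr = ik.find_drs(region, stem, min_dr=8)
    assert dr is not None
    assert dr.dr_sequence == BCIST1_DR
    assert dr.length == 15
    # the DR is always a substring of the 5' IR arm
    arm5 = region[stem.arm5[0] : stem.arm5[1]]
    assert dr.dr_sequence in arm5
    assert dr.dr3_span[1] <= stem.arm3[0]


def test_find_drs_none_below_min():
    region = "ATCG" * 30
    stem = ik.HairpinStem(arm5=(0, 6), arm3=(100, 106), loop=(6, 100),
                          stem_length_bp=6, au_pair_fraction=0.5)
    assert ik.find_drs(region, stem, min_dr=8) is None
    with pytest.raises(ValueError):
        ik.find_drs(region, stem, min_dr=4)


def test_lcs_matches_quadratic_oracle(rng):
    for _ in range(50):
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 30))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 30))))
        length, ia, ib = _longest_common_substring(a, b)
        assert length == lcs_oracle(a, b)
        assert a[ia : ia + length] == b[ib : ib + length]


# ---------------------------------------------------------------------------
# TSD check and naming
# ---------------------------------------------------------------------------

def test_check_no_tsd_default_and_adversarial(locus_b):
    rec, truth = locus_b
    m = _model(truth.target_site_motif, truth.terminus_motif)
    m.istron_start = m.exon5_end = truth.istron_start
    m.istron_end = truth.istron_end
    m.target_site = (truth.target_site_motif, truth.target_site_span)
    assert ik.check_no_tsd(m, rec) is True
    # adversarial: duplicate the site on the 3' side
    motif = truth.target_site_motif
    dup = (rec.sequence[: truth.istron_end] + motif
           + rec.sequence[truth.istron_end + len(motif):])
    assert ik.check_no_tsd(m, GenomeRecord(rec.id, dup)) is False


def test_check_no_tsd_contig_end_truncation():
    m = _model("TTGAT", "TCAG")
    m.istron_end = 598
    genome = GenomeRecord("g", "A" * 600)
    assert ik.check_no_tsd(m, genome) is True
    assert "tsd-check-truncated" in m.flags


@pytest.mark.parametrize(
    "genus,species,index,expected",
    [
        ("Clostridium", "difficile", 1, "CdISt1"),
        ("Bacillus", "cereus", 1, "BcISt1"),
        ("Megasphaera", "sp.", 1, "MsISt1"),
    ],
)
def test_name_istron(genus, species, index, expected):
    assert ik.name_istron(genus, species, index) == expected


def test_name_istron_suffix_hook_and_validation():
    assert ik.name_istron("Megasphaera", "sp.", 1, suffix="UPII 135-E") == "MsISt1-UPII 135-E"
    with pytest.raises(ValueError):
        ik.name_istron("", "difficile", 1)
    with pytest.raises(ValueError):
        ik.name_istron("Clostridium", "difficile", 0)


def test_major_group_folds_variant_into_b():
    assert major_group("B-variant") == "B"
    assert major_group("A") == "A"


# ---------------------------------------------------------------------------
# model invariants on real calls
# ---------------------------------------------------------------------------

def test_call_models_satisfy_schema(survey_sim, survey_calls):
    gen = {g.id: g for g in survey_sim.genomes}
    n = 0
    for gid, calls in survey_calls.items():
        for m in calls:
            n += 1
            assert m.istron_start == m.exon5_end < m.istron_end
            assert m.group in ("A", "B", "B-variant", "unclassified")
            if m.orf_b is not None:
                span, _state = m.orf_b
                assert m.istron_start < span[0] and span[1] <= m.istron_end
            if m.target_site is not None:
                motif, span = m.target_site
                assert gen[gid].sequence[span[0] : span[1]] == motif
                assert span[1] == m.istron_start
            if m.group == "A":
                assert m.terminus_motif == "TCAG"
                assert m.target_site[0] in ("TTGAT", "ATTAT", "TTTAT")
            elif m.group == "B":
                assert m.terminus_motif == "CGG"
                assert m.target_site[0].endswith("GG")
            if m.dr is not None and m.ir_stem is not None:
                arm5 = m.sequence[m.ir_stem.arm5[0] : m.ir_stem.arm5[1]]
                assert m.dr.dr_sequence in arm5
    assert n >= 30
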