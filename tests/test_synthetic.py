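"""Generator correctness: template grammar, embedding, homologs, degeneration."""

import numpy as np
import pytest

import istronkit as ik
from istronkit.grammar import (
    GROUP_A_TARGET_SITES,
    GROUP_B_TARGET_SITES,
    revcomp,
)
from istronkit.synthetic import (
    ConfigurationError,
    GeneratorConfig,
    PlacementError,
    build_element_body,
    make_host_genome,
)


@pytest.mark.parametrize("group,seed", [("A", 3), ("B", 4), ("B-variant", 5)])
def test_template_obeys_group_grammar(group, seed):
    t = ik.build_istron_template(group, seed=seed)
    if group == "A":
        assert t.target_site_motif in GROUP_A_TARGET_SITES
        assert t.terminus_motif == "TCAG"
        assert 6 <= t.stem_length_bp <= 10
        assert t.stem_au_fraction == pytest.approx(0.5)
        assert t.p1_topology == "embedded-wobble"
    else:
        assert t.terminus_motif == ("CAG" if group == "B-variant" else "CGG")
        if group == "B":
            assert t.target_site_motif in GROUP_B_TARGET_SITES
            assert t.target_site_motif.endswith("GG")
        else:
            assert t.target_site_motif == "AG"
        assert 15 <= t.stem_length_bp <= 34
        assert t.stem_au_fraction >= 0.8
        assert t.dr in t.ir5 and len(t.dr) == 15
        assert t.p1_topology == "loop-adjacent-shifted"
    assert t.intron_start_motif in ("TAA", "TAG", "TGA")
    assert 4 <= t.igs_length <= 6
    assert t.ir3 == revcomp(t.ir5)


def test_template_rejects_bad_group_and_params():
    with pytest.raises(ConfigurationError):
        ik.build_istron_template("C")
    bad = GeneratorConfig(igs_range=(3, 6))
    with pytest.raises(ConfigurationError, match="igs_range"):
        ik.build_istron_template("A", bad)


def test_embedding_round_trip_and_no_tsd(locus_b):
    rec, truth = locus_b
    seq = rec.sequence
    istron = seq[truth.istron_start : truth.istron_end]
    assert istron == truth.istron_sequence
    # exact conservation: exon5 + istron + exon3 == locus
    assert seq[: truth.istron_start] + istron + seq[truth.istron_end :] == seq
    # target site present at the 5' junction, not duplicated on the 3' side
    k = len(truth.target_site_motif)
    assert seq[truth.istron_start - k : truth.istron_start] == truth.target_site_motif
    assert seq[truth.istron_end : truth.istron_end + k] != truth.target_site_motif


def test_in_frame_insertion_creates_stop_in_host_frame(locus_b):
    rec, truth = locus_b
    assert truth.context == "intragenic" and truth.in_frame
    gene = rec.genes[truth.host_gene_index]
    assert (truth.istron_start - gene.start) % 3 == 0
    assert truth.istron_sequence[:3] in ("TAA", "TAG", "TGA")


def test_intergenic_embedding_marked_intergenic():
    config = GeneratorConfig()
    genome = make_host_genome("g1", "Test organism", seed=5, config=config)
    template = ik.build_istron_template("A", config, seed=6)
    rec, truth = ik.embed_istron(genome, template, None, False, seed=7, config=config)
    assert truth.context == "intergenic"
    assert truth.in_frame is None
    for g in rec.genes:
        assert not (g.start <= truth.istron_start < g.end)


def test_embedding_rejects_short_gene():
    config = GeneratorConfig(genome_length=6000)
    genome = make_host_genome("g1", "Test organism", seed=5, config=config)
    genome.genes[0].end = genome.genes[0].start + 120  # artificially short
    template = ik.build_istron_template("A", seed=6)
    with pytest.raises(PlacementError):
        ik.embed_istron(genome, template, 0, True, seed=7)


def test_homolog_zero_divergence_is_exact_junction(locus_b):
    rec, truth = locus_b
    hom = ik.make_istronless_homolog(rec, truth, divergence=0.0, seed=1, flank_nt=500)
    f5 = rec.sequence[truth.istron_start - 500 : truth.istron_start]
    f3 = rec.sequence[truth.istron_end : truth.istron_end + 500]
    assert hom.sequence == f5 + f3
    assert truth.istron_sequence not in hom.sequence


def test_homolog_divergence_rate_matches_hamming(locus_b):
    rec, truth = locus_b
    hom = ik.make_istronless_homolog(rec, truth, divergence=0.05, seed=42, flank_nt=600)
    clean = ik.make_istronless_homolog(rec, truth, divergence=0.0, seed=42, flank_nt=600)
    hamming = sum(1 for x, y in zip(hom.sequence, clean.sequence) if x != y)
    rate = hamming / len(clean.sequence)
    assert abs(rate - 0.05) < 0.02
    with pytest.raises(ConfigurationError):
        ik.make_istronless_homolog(rec, truth, divergence=0.5)


@pytest.mark.parametrize("mode", ["delta_orfA", "phi_orfA", "orfB_only", "orfless_emetic"])
def test_degrade_modes(mode):
    template = ik.build_istron_template("B", seed=9)
    deg = ik.degrade_element(template, mode)
    exon = "ATTACCAGGG"
    body = build_element_body(template, 3)
    full, feats_full = ik.assemble_istron(template, exon, 1, body=body)
    degraded, feats = ik.assemble_istron(deg, exon, 1, body=body)
    if mode == "delta_orfA":
        # ORF A shortened below intact length, ORF B untouched
        assert feats.orf_a_span[1] - feats.orf_a_span[0] < (
            feats_full.orf_a_span[1] - feats_full.orf_a_span[0]
        )
        assert feats.orf_b_span[1] - feats.orf_b_span[0] == (
            feats_full.orf_b_span[1] - feats_full.orf_b_span[0]
        )
    elif mode == "phi_orfA":
        # nucleotide length preserved, translation disrupted by an indel pair
        a0, a1 = feats.orf_a_span
        f0, f1 = feats_full.orf_a_span
        assert a1 - a0 == f1 - f0
        assert degraded[a0:a1] != full[f0:f1]
    elif mode == "orfB_only":
        assert feats.orf_a_span is None and feats.orf_b_span is not None
    else:
        assert feats.orf_a_span is None and feats.orf_b_span is None
        assert feats.ir5_span is None
        # the retained DR + 3' IR still folds into a stem
        region = degraded[feats.dr3_span[0] : feats.ir3_span[1]]
        stem = ik.find_ir_hairpin(region, min_stem_bp=8, max_loop_nt=50)
        assert stem is not None and stem.stem_length_bp >= 15


def test_degrade_rejects_unknown_mode():
    template = ik.build_istron_template("A", seed=1)
    with pytest.raises(ConfigurationError):
        ik.degrade_element(template, "delete_everything")


def test_seed_determinism_byte_identical():
    a = ik.simulate_survey_genomes(GeneratorConfig(n_genomes=2), seed=5)
    b = ik.simulate_survey_genomes(GeneratorConfig(n_genomes=2), seed=5)
    assert [g.sequence for g in a.genomes] == [g.sequence for g in b.genomes]
    assert [h.sequence for h in a.homologs] == [h.sequence for h in b.homologs]
    assert [(t.istron_start, t.istron_end, t.element_name) for t in a.truths] == [
        (t.istron_start, t.istron_end, t.element_name) for t in b.truths
    ]


def test_generated_elements_validate_against_annotators(survey_sim):
    """Self-consistency: generator output obeys the classifier-side grammar."""
    gen = {g.id: g for g in survey_sim.genomes}
    for t in survey_sim.truths:
        g = gen[t.genome_id]
        assert g.sequence[t.istron_start : t.istron_end] == t.istron_sequence
        tail, head = ik.exon_intron_views(g, t)
        ann = ik.annotate_p1(tail, head)
        assert ann.topology == t.p1_topology
        assert ann.igs_length >= 4
        term = t.istron_sequence[-len(t.terminus_motif):]
        assert term == t.terminus_motif
        hyps = ik.detect_target_site(g.sequence[t.istron_start - 6 : t.istron_start])
        assert any(m == t.target_site_motif for m, _ in hyps)


def test_truth_outputs_round_trip(tmp_path, survey_sim):
    ik.write_fasta(survey_sim.genomes, tmp_path / "genomes.fasta")
    back = ik.read_fasta(tmp_path / "genomes.fasta")
    assert [r.sequence for r in back] == [g.sequence for g in survey_sim.genomes]
    from istronkit.synthetic import write_truth_gff3, write_truth_tsv

    write_truth_gff3(survey_sim.truths, tmp_path / "truth.gff3")
    lines = (tmp_path / "truth.gff3").read_text().splitlines()
    assert lines[0] == "##gff-version 3"
    types = {line.split("\t")[2] for line in lines[1:]}
    assert {"istron", "exon5", "exon3", "target_site", "ir3"} <= types
    write_truth_tsv(survey_sim.truths, tmp_path / "truth.tsv")
    import pandas as pd

    df = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
    assert len(df) == len(survey_sim.truths)


def test_gene_annotations_gff3_round_trip(tmp_path):
    from istronkit.records import read_genes_gff3, write_genes_gff3

    genome = make_host_genome("g1", "Test organism", seed=2)
    write_genes_gff3([genome], tmp_path / "genes.gff3")
    back = read_genes_gff3(tmp_path / "genes.gff3")
    assert [(g.start, g.end, g.strand, g.product_label) for g in back["g1"]] == [
        (g.start, g.end, g.strand, g.product_label) for g in genome.genes
    ]


def test_config_yaml_round_trip(tmp_path):
    config = GeneratorConfig(n_genomes=3, homolog_divergence=0.01)
    config.to_yaml(tmp_path / "c.yaml")
    back = GeneratorConfig.from_yaml(tmp_path / "c.yaml")
    assert back == config
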