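"""Survey aggregation: identity, clustering, contexts, splicing, reports."""

import logging

import numpy as np
import pytest

import istronkit as ik
from istronkit.caller import IStronModel
from istronkit.records import Gene

from oracles import global_identity_oracle


def _stub_call(gid, start, seq, name="m"):
    return IStronModel(
        name=name, genome_id=gid, strand="+", exon5_end=start, istron_start=start,
        istron_end=start + len(seq), target_site=("TTGAT", (start - 5, start)),
        group="A", terminus_motif="TCAG", sequence=seq,
    )


# ---------------------------------------------------------------------------
# global identity
# ---------------------------------------------------------------------------

def test_identity_trivial_cases(rng):
    s = "".join(rng.choice(list("ACGT"), size=100))
    assert ik.global_identity(s, s) == 1.0
    mutated = list(s)
    for i in rng.choice(100, size=10, replace=False):
        mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
    assert ik.global_identity(s, "".join(mutated)) == pytest.approx(0.9)
    with pytest.raises(ValueError):
        ik.global_identity("", "ACGT")


def test_identity_matches_enumeration_oracle(rng):
    for _ in range(60):
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 9))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 9))))
        assert ik.global_identity(a, b) == pytest.approx(global_identity_oracle(a, b))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _mutate(seq, n, rng):
    out = list(seq)
    for i in rng.choice(len(seq), size=n, replace=False):
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


def test_cluster_copies_threshold_behaviour(rng):
    base = "".join(rng.choice(list("ACGT"), size=400))
    near = _mutate(base, 20, rng)   # 95% identity
    far = _mutate(base, 80, rng)    # 80% identity
    calls = [_stub_call("g1", 100, base), _stub_call("g2", 100, near)]
    clusters = ik.cluster_copies(calls, threshold=0.93)
    assert len(clusters) == 1 and len(clusters[0].members) == 2
    calls2 = [_stub_call("g1", 100, base), _stub_call("g2", 100, far)]
    assert len(ik.cluster_copies(calls2, threshold=0.93)) == 2
    identical = [_stub_call(f"g{i}", 100, base) for i in range(4)]
    one = ik.cluster_copies(identical, threshold=0.93)
    assert len(one) == 1 and len(one[0].members) == 4
    with pytest.raises(ValueError):
        ik.cluster_copies(calls, threshold=0.0)


def test_cluster_order_invariance(rng):
    base = "".join(rng.choice(list("ACGT"), size=300))
    calls = [
        _stub_call("g1", 100, base),
        _stub_call("g2", 100, _mutate(base, 9, rng)),
        _stub_call("g3", 100, "".join(rng.choice(list("ACGT"), size=300))),
    ]
    order = ["g1", "g2", "g3"]
    a = ik.cluster_copies(calls, genome_order=order)
    b = ik.cluster_copies(calls[::-1], genome_order=order)
    assert [sorted(c.members) for c in a] == [sorted(c.members) for c in b]
    assert [c.name for c in a] == [c.name for c in b]


# ---------------------------------------------------------------------------
# insertion context
# ---------------------------------------------------------------------------

def test_insertion_context_in_frame_stop(locus_b):
    rec, truth = locus_b
    call = _stub_call(rec.id, truth.istron_start, truth.istron_sequence)
    ctx = ik.insertion_context(call, rec.genes)
    assert ctx.context == "intragenic"
    assert ctx.in_frame is True
    assert ctx.stop_created is True


def test_insertion_context_intergenic_undefined_frame():
    call = _stub_call("g", 500, "TAA" + "ACGT" * 50)
    ctx = ik.insertion_context(call, [Gene(1000, 2000, "+", 0, "x")])
    assert ctx.context == "intergenic"
    assert ctx.in_frame is None and ctx.stop_created is None


def test_insertion_context_minus_strand_gene():
    # element inserted in a minus-strand gene; frame origin is the gene end
    istron = ik.revcomp("TAA" + "ACGTAC" * 20)  # gene-strand first triplet TAA
    start = 1200
    gene = Gene(900, start + len(istron) + 300, "-", 0, "helicase")
    call = _stub_call("g", start, istron)
    assert (gene.end - call.istron_end) % 3 == 0
    ctx = ik.insertion_context(call, [gene])
    assert ctx.context == "intragenic"
    assert ctx.in_frame is True
    assert ctx.stop_created is True


# ---------------------------------------------------------------------------
# splicing
# ---------------------------------------------------------------------------

def test_splice_products_conservation_and_offsets(locus_b):
    rec, truth = locus_b
    call = _stub_call(rec.id, truth.istron_start, truth.istron_sequence)
    call.istron_end = truth.istron_end
    offsets = [(1, 0), (42, 0), (71, 0), (0, 1)]
    products = ik.simulate_splicing(rec.sequence, call, offsets)
    exon5 = rec.sequence[: truth.istron_start]
    exon3 = rec.sequence[truth.istron_end :]
    assert products.ligated_exons == exon5 + exon3
    w = products.junction_window
    istron = truth.istron_sequence
    assert products.full_circle_junction == istron[-w:] + istron[:w]
    for (o5, o3, junction) in products.partial_circles:
        assert len(products.full_circle_junction) - len(junction) == o5 + o3
    # reinserting the element at the junction reconstructs the locus exactly
    assert exon5 + istron + exon3 == rec.sequence


def test_splice_no_offsets_only_full_products(locus_b):
    rec, truth = locus_b
    call = _stub_call(rec.id, truth.istron_start, truth.istron_sequence)
    call.istron_end = truth.istron_end
    products = ik.simulate_splicing(rec.sequence, call, [])
    assert products.partial_circles == []
    assert products.junction_window == 30
    with pytest.raises(ValueError):
        bad = _stub_call(rec.id, truth.istron_start, truth.istron_sequence)
        bad.istron_end = len(rec.sequence) + 50
        ik.simulate_splicing(rec.sequence, bad, [])


# ---------------------------------------------------------------------------
# survey report
# ---------------------------------------------------------------------------

def test_write_survey_empty(tmp_path):
    summary = ik.write_survey([], [], [], tmp_path)
    assert summary.n_calls == 0 and summary.pct_intragenic is None
    table = (tmp_path / "elements.tsv").read_text().splitlines()
    assert len(table) == 1 and table[0].startswith("element\t")


def test_write_survey_deduplicates_with_warning(tmp_path, caplog, rng):
    seq = "".join(rng.choice(list("ACGT"), size=300))
    calls = [_stub_call("g1", 100, seq), _stub_call("g1", 100, seq)]
    clusters = ik.cluster_copies(calls[:1])
    with caplog.at_level(logging.WARNING, logger="istronkit.survey"):
        summary = ik.write_survey(calls, clusters, [], tmp_path)
    assert summary.n_calls == 1
    assert any("duplicate" in rec.message for rec in caplog.records)


def test_survey_percentages_match_truth(tmp_path, survey_sim, survey_calls):
    gen = {g.id: g for g in survey_sim.genomes}
    calls = [c for calls in survey_calls.values() for c in calls]
    contexts = [ik.insertion_context(c, gen[c.genome_id].genes) for c in calls]
    organisms = {g.id: tuple(g.organism.split()) for g in survey_sim.genomes}
    clusters = ik.cluster_copies(
        calls, organisms=organisms, genome_order=[g.id for g in survey_sim.genomes]
    )
    summary = ik.write_survey(calls, clusters, contexts, tmp_path, organisms=organisms)
    truth_intra = sum(1 for t in survey_sim.truths if t.context == "intragenic")
    assert summary.n_calls == len(survey_sim.truths)
    assert summary.pct_intragenic == pytest.approx(100 * truth_intra / len(survey_sim.truths))
    truth_inframe = sum(1 for t in survey_sim.truths if t.in_frame)
    assert summary.pct_in_frame == pytest.approx(100 * truth_inframe / truth_intra)
    # clusters obey the identity invariant and never mix species; copies with
    # large ORF-region deletions fall below the whole-length identity
    # threshold and form their own (still species-pure) clusters
    gid_to_org = {g.id: g.organism for g in survey_sim.genomes}
    for cl in clusters:
        if len(cl.members) > 1:
            # single-linkage witness: every member has a >=93% partner, and
            # chained pairs stay close to the threshold
            mat = cl.identity.values.copy()
            np.fill_diagonal(mat, 0.0)
            assert (mat.max(axis=1) >= 0.93).all()
            assert mat[mat > 0].min() >= 0.90
        assert len({gid_to_org[m.split(":")[0]] for m in cl.members}) == 1
    assert len(clusters) >= len({g.organism for g in survey_sim.genomes})
    table = (tmp_path / "elements.tsv").read_text()
    assert "IA2" in table
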