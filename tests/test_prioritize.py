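"""Annotation and composite ranking of scored interactions."""

import pytest

from mirtarsnp.intersect import InteractionTriple, Variant
from mirtarsnp.prioritize import (
    StructureImpact,
    annotate,
    load_annotation_tables,
    prioritize,
)
from mirtarsnp.rna_struct import AccessibilityResult, HybridResult
from mirtarsnp.rna_struct.distance import StructureDistanceResult
from mirtarsnp.targetome import TargetomeRecord, add_flanks


def make_scored(rsid, mirna="miR-1", p=0.05, dpu=5.0, ddg=3.0,
                location="site", pos=1010):
    rec = TargetomeRecord(
        mirna_id=mirna, gene_symbol="G1", transcript_id="TX1",
        chrom="chr1", strand="+", genomic_site=(1000, 1021),
        utr_site=(100, 121), sources=frozenset({"StarBase"}),
        evidence="predicted",
    )
    zi = add_flanks(rec, 25, utr_len=400)
    triple = InteractionTriple(
        variant=Variant(rsid, "chr1", pos, "A", "G"),
        zoned=zi, location_class=location, utr_pos=110,
    )
    impact = StructureImpact(
        distance=StructureDistanceResult(
            d_max=1.0, interval=(0, 10), p_value=p, n_null=100, seed=0,
            significant=p < 0.2, window=(0, 50)),
        access=AccessibilityResult(0.1, 0.1 + dpu / 100, dpu),
        hybrid=HybridResult(-20.0, -20.0 + ddg, ddg, False, False),
    )
    return triple, impact


def test_annotation_defaults_and_tables(tmp_path):
    eqtl = tmp_path / "eqtl.tsv"
    eqtl.write_text("rsid\tgene\ttissue\nrs1\tG1\tcolon\nrs1\tG1\tliver\n")
    cons = tmp_path / "cons.tsv"
    cons.write_text("rsid\tgerp\tsiphy\nrs1\t+\t-\nrs1\t-\t-\n")
    eq, cv = load_annotation_tables(eqtl, cons)
    records = annotate([make_scored("rs1"), make_scored("rs2")], eq, cv)
    assert records[0].is_eqtl and records[0].gerp_flag == "+"  # first row wins
    assert not records[1].is_eqtl
    assert (records[1].gerp_flag, records[1].siphy_flag) == ("-", "-")
    assert len(records) == 2  # annotation never drops records


def test_candidate_filter_uses_pcut_strictly():
    records = annotate([
        make_scored("rs1", p=0.19),
        make_scored("rs2", p=0.25),
        make_scored("rs3", p=0.05, location="flank"),
    ], set(), {})
    ranked = prioritize(records)
    assert [r.record.triple.variant.rsid for r in ranked] == ["rs1"]


def test_empty_candidate_set_gives_empty_list():
    records = annotate([make_scored("rs1", p=0.9)], set(), {})
    assert prioritize(records) == []


def test_single_candidate_gets_rank_one():
    ranked = prioritize(annotate([make_scored("rs1", p=0.01)], set(), {}))
    assert len(ranked) == 1 and ranked[0].rank == 1


def test_eqtl_bonus_breaks_otherwise_identical_records():
    records = annotate(
        [make_scored("rs1"), make_scored("rs2")], {"rs2"}, {})
    ranked = prioritize(records)
    assert ranked[0].record.triple.variant.rsid == "rs2"
    assert ranked[0].composite_score == pytest.approx(
        ranked[1].composite_score + 0.5)


def test_stronger_metrics_rank_higher():
    records = annotate([
        make_scored("rs_weak", p=0.15, dpu=0.5, ddg=0.2),
        make_scored("rs_strong", p=0.01, dpu=30.0, ddg=6.0),
    ], set(), {})
    ranked = prioritize(records)
    assert ranked[0].record.triple.variant.rsid == "rs_strong"


def test_ranking_invariant_to_input_order_and_noncandidates():
    scored = [
        make_scored("rs1", p=0.01, dpu=10, ddg=5),
        make_scored("rs2", p=0.10, dpu=2, ddg=1),
        make_scored("rs3", p=0.05, dpu=7, ddg=2, mirna="miR-9"),
    ]
    noncand = make_scored("rs4", p=0.5)
    base = prioritize(annotate(scored, set(), {}))
    shuffled = prioritize(annotate(scored[::-1] + [noncand], set(), {}))
    key = [(r.record.triple.variant.rsid, r.rank) for r in base]
    key2 = [(r.record.triple.variant.rsid, r.rank)
            for r in shuffled]
    assert key == key2
    assert [r.rank for r in base] == list(range(1, len(base) + 1))


def test_ranks_are_a_permutation_on_random_input(rng):
    scored = [
        make_scored(f"rs{i}", p=float(rng.uniform(0, 0.19)),
                    dpu=float(rng.normal(0, 10)),
                    ddg=float(rng.normal(0, 3)))
        for i in range(25)
    ]
    ranked = prioritize(annotate(scored, {"rs3", "rs7"}, {}))
    assert sorted(r.rank for r in ranked) == list(range(1, 26))
    # deterministic
    again = prioritize(annotate(scored, {"rs3", "rs7"}, {}))
    assert [(r.rank, r.record.triple.variant.rsid) for r in ranked] == \
        [(r.rank, r.record.triple.variant.rsid) for r in again]
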