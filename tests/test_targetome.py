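"""Targetome loading, merging, flank attachment and zoning."""

import pandas as pd
import pytest

from mirtarsnp.targetome import (
    TargetomeRecord,
    UnknownSourceError,
    add_flanks,
    load_targetome,
    merge_records,
)

COLS = ["db", "mirna", "gene", "transcript", "chrom", "strand",
        "genomic_start", "genomic_end", "utr_start", "utr_end", "evidence"]


def row(db="StarBase", mirna="miR-1", gs=1000, ge=1021, us=100, ue=121,
        evidence="verified", strand="+"):
    return [db, mirna, "GENE1", "TX1", "chr1", strand, gs, ge, us, ue, evidence]


def write_sources(tmp_path, *rowsets):
    paths = []
    for i, rows in enumerate(rowsets):
        p = tmp_path / f"src{i}.tsv"
        pd.DataFrame(rows, columns=COLS).to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


def rec(**kw):
    base = dict(mirna_id="miR-1", gene_symbol="GENE1", transcript_id="TX1",
                chrom="chr1", strand="+", genomic_site=(1000, 1021),
                utr_site=(100, 121), sources=frozenset({"StarBase"}),
                evidence="verified")
    base.update(kw)
    return TargetomeRecord(**base)


def test_load_and_merge_same_site_from_two_sources(tmp_path):
    paths = write_sources(
        tmp_path, [row("StarBase")], [row("microRNA.org", evidence="predicted")])
    records = load_targetome(paths)
    assert len(records) == 2
    merged = merge_records(records)
    assert len(merged) == 1
    assert merged[0].sources == {"StarBase", "microRNA.org"}
    assert merged[0].evidence == "verified"  # any verified source wins


def test_invalid_interval_rejected_with_warning(tmp_path, caplog):
    paths = write_sources(tmp_path, [row(gs=1000, ge=1000, us=100, ue=100),
                                     row()])
    assert len(load_targetome(paths)) == 1


def test_unknown_source_label_is_configuration_error(tmp_path):
    paths = write_sources(tmp_path, [row(db="miRTarBase")])
    with pytest.raises(UnknownSourceError, match="miRTarBase"):
        load_targetome(paths)


def test_overlapping_non_identical_sites_stay_separate():
    merged = merge_records([rec(), rec(genomic_site=(1005, 1026),
                                       utr_site=(105, 126))])
    assert len(merged) == 2


def test_merge_is_idempotent_and_order_invariant():
    records = [rec(), rec(sources=frozenset({"TargetScan"}),
                          evidence="predicted"),
               rec(mirna_id="miR-2")]
    once = merge_records(records)
    assert merge_records(once) == once
    assert merge_records(records[::-1]) == once


def test_add_flanks_arithmetic_and_clamping():
    zi = add_flanks(rec(utr_site=(100, 121), genomic_site=(1000, 1021)),
                    flank_len=25, utr_len=500)
    assert zi.extended_utr == (75, 146)
    zi2 = add_flanks(rec(utr_site=(10, 31), genomic_site=(910, 931)),
                     flank_len=25, utr_len=500)
    assert zi2.extended_utr == (0, 56)
    zi3 = add_flanks(rec(utr_site=(480, 501), genomic_site=(1380, 1401)),
                     flank_len=25, utr_len=501)
    assert zi3.extended_utr == (455, 501)


def test_zoning_partitions_extended_interval():
    zi = add_flanks(rec(), flank_len=25, utr_len=500)
    a, b = zi.extended_utr
    for pos in range(a, b):
        zone = zi.zone(pos)
        assert zone == ("site" if 100 <= pos < 121 else "flank")
    with pytest.raises(ValueError):
        zi.zone(b)


def test_extended_genomic_matches_utr_extension_on_both_strands():
    plus = add_flanks(rec(), flank_len=25, utr_len=500)
    assert plus.extended_genomic == (975, 1046)
    minus = add_flanks(rec(strand="-"), flank_len=25, utr_len=500)
    ga, gb = minus.extended_genomic
    assert gb - ga == plus.extended_utr[1] - plus.extended_utr[0]


def test_genomic_to_utr_mapping_is_strand_aware():
    r_plus = rec()
    assert r_plus.utr_pos_of_genomic(1000) == 100
    assert r_plus.utr_pos_of_genomic(1020) == 120
    r_minus = rec(strand="-")
    assert r_minus.utr_pos_of_genomic(1020) == 100
    assert r_minus.utr_pos_of_genomic(1000) == 120


def test_record_invariants_enforced():
    with pytest.raises(ValueError):
        rec(genomic_site=(1000, 1004), utr_site=(100, 104))  # too short
    with pytest.raises(ValueError):
        rec(utr_site=(100, 120))                             # length mismatch
    with pytest.raises(ValueError):
        rec(sources=frozenset())
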