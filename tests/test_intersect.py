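"""Variant x targetome intersection and sequence-context extraction."""

import numpy as np
import pytest

from mirtarsnp.intersect import (
    InteractionTriple,
    RefMismatchError,
    Variant,
    extract_context,
    intersect_variants,
    load_variant_table,
)
from mirtarsnp.targetome import TargetomeRecord, add_flanks


def make_record(i, chrom="chr1", strand="+", start=1000, utr_start=100,
                length=21, mirna=None, gene=None, tx=None):
    return TargetomeRecord(
        mirna_id=mirna or f"miR-{i}",
        gene_symbol=gene or f"G{i}",
        transcript_id=tx or f"TX{i}",
        chrom=chrom,
        strand=strand,
        genomic_site=(start, start + length),
        utr_site=(utr_start, utr_start + length),
        sources=frozenset({"StarBase"}),
        evidence="predicted",
    )


def brute_force_triples(variants, zoned):
    """O(n*m) containment oracle with the same site-first dedup rule."""
    out = {}
    for v in variants:
        for zi in zoned:
            if zi.record.chrom != v.chrom:
                continue
            a, b = zi.extended_genomic
            if not a <= v.pos < b:
                continue
            u = zi.record.utr_pos_of_genomic(v.pos)
            zone = zi.zone(u)
            key = (zi.record.mirna_id, zi.record.gene_symbol, v.rsid)
            if key not in out or (out[key] == "flank" and zone == "site"):
                out[key] = zone
    return out


def test_site_and_flank_classification():
    rec = make_record(1)
    zi = add_flanks(rec, 25, utr_len=400)
    inside = Variant("rs1", "chr1", 1010, "A", "G")
    in_flank = Variant("rs2", "chr1", 1030, "A", "G")   # 10 nt past site end
    outside = Variant("rs3", "chr1", 1051, "A", "G")    # 30 nt past site end
    triples = intersect_variants([inside, in_flank, outside], [zi])
    classes = {t.variant.rsid: t.location_class for t in triples}
    assert classes == {"rs1": "site", "rs2": "flank"}


def test_matches_brute_force_on_random_fixture(rng):
    zoned = []
    for i in range(60):
        chrom = "chr1" if i % 2 else "chr2"
        start = int(rng.integers(0, 5000))
        utr_start = int(rng.integers(30, 300))
        zoned.append(add_flanks(
            make_record(i, chrom=chrom, start=start, utr_start=utr_start),
            25, utr_len=800))
    variants = [
        Variant(f"rs{i}", "chr1" if rng.random() < 0.5 else "chr2",
                int(rng.integers(0, 5200)), "A", "C")
        for i in range(300)
    ]
    got = {(t.key[0], t.key[1], t.key[2]): t.location_class
           for t in intersect_variants(variants, zoned)}
    assert got == brute_force_triples(variants, zoned)


def test_triples_unique_per_mirna_gene_snp(rng):
    # two records, same miRNA/gene, overlapping intervals: one triple
    shared = dict(mirna="miR-x", gene="GX")
    zoned = [add_flanks(make_record(0, start=1000, **shared), 25, utr_len=400),
             add_flanks(make_record(1, start=1010, utr_start=110, **shared),
                        25, utr_len=400)]
    v = Variant("rs1", "chr1", 1015, "A", "G")
    triples = intersect_variants([v], zoned)
    assert len(triples) == 1
    assert triples[0].location_class == "site"


UTR = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 52 nt


def make_triple(strand="+", pos=None, ref=None, alt=None):
    rec = TargetomeRecord(
        mirna_id="miR-1", gene_symbol="G1", transcript_id="TX1",
        chrom="chr1", strand=strand,
        genomic_site=(1010, 1020) if strand == "+" else (1022, 1032),
        utr_site=(10, 20),
        sources=frozenset({"StarBase"}), evidence="predicted",
    )
    zi = add_flanks(rec, 5, utr_len=len(UTR))
    v = Variant("rs1", "chr1", pos, ref, alt)
    u = rec.utr_pos_of_genomic(pos)
    return InteractionTriple(variant=v, zoned=zi, location_class=zi.zone(u),
                             utr_pos=u)


def test_context_extraction_plus_strand():
    # genomic 1014 -> utr 14, base G; alt G>A
    t = make_triple("+", pos=1014, ref="G", alt="A")
    t2 = extract_context(t, {"TX1": UTR}, context_radius=10)
    assert t2.wt_context[t2.snp_offset] == "G"
    assert t2.alt_context[t2.snp_offset] == "A"
    diffs = [i for i, (a, b) in enumerate(zip(t2.wt_context, t2.alt_context))
             if a != b]
    assert diffs == [t2.snp_offset]
    assert "T" not in t2.wt_context  # RNA alphabet
    s, e = t2.site_in_context
    assert e - s == 10


def test_context_extraction_minus_strand_complements_alleles():
    # minus strand: genomic end-1 maps to utr_site start; genomic base is
    # the complement of the sense base.  utr pos 14 ('G') corresponds to
    # genomic pos 1027 with genomic ref C; alt C>T must appear as G>A.
    t = make_triple("-", pos=1027, ref="C", alt="T")
    assert t.utr_pos == 14
    t2 = extract_context(t, {"TX1": UTR}, context_radius=10)
    assert t2.wt_context[t2.snp_offset] == "G"
    assert t2.alt_context[t2.snp_offset] == "A"


def test_context_roundtrip_restores_wildtype():
    t = make_triple("+", pos=1014, ref="G", alt="A")
    t2 = extract_context(t, {"TX1": UTR}, context_radius=10)
    restored = (t2.alt_context[:t2.snp_offset] + "G"
                + t2.alt_context[t2.snp_offset + 1:])
    assert restored == t2.wt_context


def test_reference_mismatch_raises():
    t = make_triple("+", pos=1014, ref="C", alt="A")  # UTR has G there
    with pytest.raises(RefMismatchError, match="rs1"):
        extract_context(t, {"TX1": UTR})


def test_missing_transcript_raises_lookup_error():
    t = make_triple("+", pos=1012, ref="G", alt="A")
    with pytest.raises(KeyError, match="TX1"):
        extract_context(t, {})


def test_variant_table_skips_indels_and_multiallelics(tmp_path):
    path = tmp_path / "variants.tsv"
    path.write_text(
        "##fileformat=VCF-like\n"
        "#CHROM\tPOS\tID\tREF\tALT\n"
        "chr1\t100\trs1\tA\tG\n"
        "chr1\t200\trs2\tAT\tA\n"      # indel
        "chr1\t300\trs3\tC\tT,G\n"     # multiallelic
        "chr1\t400\trs4\tC\tC\n"       # ref == alt
    )
    variants = load_variant_table(path)
    assert [v.rsid for v in variants] == ["rs1"]
    assert variants[0].pos == 99  # 1-based file -> 0-based internal


def test_variant_invariants():
    with pytest.raises(ValueError):
        Variant("rs1", "chr1", 10, "A", "A")
    with pytest.raises(ValueError):
        Variant("rs1", "chr1", 10, "A", "AT")
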