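"""LD proxy expansion into association blocks."""

import pandas as pd
import pytest

from mirtarsnp.gwas_ingest import GwasAssociation, TraitCategory
from mirtarsnp.ld_blocks import (
    LdProxyEdge,
    LdTable,
    expand_block,
    load_ld_table,
    unique_variants,
)


def lead(rsid="rs1", pop="EUR", cat=TraitCategory.OB):
    return GwasAssociation(rsid, "Obesity", cat, 1e-8, pop)


def write_ld(tmp_path, rows):
    path = tmp_path / "ld.tsv"
    pd.DataFrame(rows, columns=["lead_rsid", "proxy_rsid", "r2", "population"]
                 ).to_csv(path, sep="\t", index=False)
    return path


def test_load_indexes_edges_and_rejects_bad_r2(tmp_path, caplog):
    path = write_ld(tmp_path, [
        ("rs1", "rs10", 0.7, "EUR"),
        ("rs1", "rs11", 0.9, "EUR"),
        ("rs2", "rs12", 0.8, "ASN"),
        ("rs2", "rs13", 1.2, "ASN"),     # invariant violation
        ("rs2", "rs14", "oops", "ASN"),  # malformed
    ])
    table = load_ld_table(path)
    assert len(table) == 3
    assert table.proxies("rs1", "EUR") == {"rs10": 0.7, "rs11": 0.9}


def test_duplicate_edges_keep_max_r2(tmp_path):
    path = write_ld(tmp_path, [
        ("rs1", "rs10", 0.65, "EUR"),
        ("rs1", "rs10", 0.92, "EUR"),
        ("rs1", "rs10", 0.70, "EUR"),
    ])
    assert load_ld_table(path).proxies("rs1", "EUR") == {"rs10": 0.92}


def test_expand_block_threshold_inclusive():
    table = LdTable([
        LdProxyEdge("rs1", "rs10", 0.7, "EUR"),
        LdProxyEdge("rs1", "rs11", 0.5, "EUR"),
        LdProxyEdge("rs1", "rs12", 0.6, "EUR"),   # boundary: retained
    ])
    block = expand_block(lead(), table)
    assert block.rsids == {"rs1", "rs10", "rs12"}
    assert ("rs1", 1.0) in block.members


def test_lead_without_edges_gives_singleton_block():
    block = expand_block(lead(), LdTable())
    assert block.rsids == {"rs1"}


def test_blocks_are_population_specific():
    table = LdTable([
        LdProxyEdge("rs1", "rs10", 0.7, "EUR"),
        LdProxyEdge("rs1", "rs10", 0.5, "ASN"),
    ])
    assert "rs10" in expand_block(lead(pop="EUR"), table).rsids
    assert "rs10" not in expand_block(lead(pop="ASN"), table).rsids


def test_lowering_threshold_never_shrinks_blocks(rng):
    edges = [
        LdProxyEdge("rs1", f"rs{100+i}", float(r), "EUR")
        for i, r in enumerate(rng.uniform(0, 1, size=50))
    ]
    table = LdTable(edges)
    prev: set = set()
    for r2_min in (0.9, 0.7, 0.5, 0.3, 0.1):
        block = expand_block(lead(), table, r2_min)
        assert prev <= block.rsids
        prev = block.rsids


def test_expansion_invariant_to_edge_order(rng):
    edges = [LdProxyEdge("rs1", f"rs{i}", 0.6 + 0.004 * i, "EUR")
             for i in range(2, 80)]
    a = expand_block(lead(), LdTable(edges)).members
    shuffled = list(edges)
    rng.shuffle(shuffled)
    b = expand_block(lead(), LdTable(shuffled)).members
    assert a == b


def test_unique_variant_accounting_matches_set_arithmetic():
    table = LdTable([
        LdProxyEdge("rs1", "rs10", 0.7, "EUR"),
        LdProxyEdge("rs1", "rs11", 0.8, "EUR"),
        LdProxyEdge("rs2", "rs10", 0.9, "EUR"),   # shared proxy
        LdProxyEdge("rs3", "rs12", 0.9, "ASN"),
    ])
    blocks = [
        expand_block(lead("rs1"), table),
        expand_block(lead("rs2"), table),
        expand_block(lead("rs3", pop="ASN", cat=TraitCategory.WHR), table),
    ]
    df = unique_variants(blocks).set_index(["category", "population"])
    ob = df.loc[("OB", "EUR")]
    assert ob["index_variants"] == 2          # rs1, rs2
    assert ob["proxy_variants"] == 2          # rs10 counted once, rs11
    assert ob["combined"] == 4
    total = df.loc[("Overall without duplicates", "All")]
    # brute force over all blocks
    leads_set = {"rs1", "rs2", "rs3"}
    proxies = ({"rs10", "rs11"} | {"rs10"} | {"rs12"}) - leads_set
    assert total["index_variants"] == len(leads_set)
    assert total["proxy_variants"] == len(proxies)
    assert total["combined"] == len(leads_set | proxies)


def test_block_members_satisfy_threshold_invariant():
    table = LdTable([LdProxyEdge("rs1", f"rs{i}", i / 100, "EUR")
                     for i in range(40, 100)])
    block = expand_block(lead(), table, r2_min=0.6)
    assert all(r2 >= 0.6 for _, r2 in block.members)


def test_bad_inputs_rejected(tmp_path):
    with pytest.raises(ValueError):
        LdProxyEdge("rs1", "rs2", 1.5, "EUR")
    with pytest.raises(ValueError):
        expand_block(lead(), LdTable(), r2_min=0.0)
    with pytest.raises(FileNotFoundError):
        load_ld_table(tmp_path / "missing.tsv")
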