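"""Synthetic bundle generation: determinism, truth bookkeeping, filters."""

import filecmp

import pandas as pd
import pytest

from mirtarsnp.gwas_ingest import filter_significant, parse_associations
from mirtarsnp.ld_blocks import expand_block, load_ld_table, unique_rsids
from mirtarsnp.synthetic_data import (
    ConfigError,
    SimConfig,
    expected_counts,
    simulate_inputs,
)

from conftest import SMALL_SIM


def test_same_seed_gives_byte_identical_bundle(tmp_path):
    cfg = SimConfig(seed=3, **SMALL_SIM)
    b1 = simulate_inputs(cfg, tmp_path / "a")
    b2 = simulate_inputs(cfg, tmp_path / "b")
    for key in ("gwas", "ld", "utr_fasta", "mirna_fasta", "variants",
                "eqtl", "conservation", "truth"):
        assert filecmp.cmp(b1.files[key], b2.files[key], shallow=False), key
    for p1, p2 in zip(b1.files["targetome"], b2.files["targetome"]):
        assert filecmp.cmp(p1, p2, shallow=False)


def test_truth_table_counts_match_config(small_bundle):
    counts = small_bundle.truth["class"].value_counts()
    cfg = small_bundle.config
    assert counts["disruptive_site"] == cfg.n_disruptive
    assert counts["benign_site"] == cfg.n_benign_site
    assert counts["hairpin_flank"] == cfg.n_hairpin_flank
    assert counts["neutral"] == cfg.n_neutral


def test_decoy_proxies_never_enter_blocks(small_bundle):
    leads = filter_significant(parse_associations(small_bundle.files["gwas"]))
    table = load_ld_table(small_bundle.files["ld"])
    members = unique_rsids([expand_block(l, table) for l in leads])
    truth = small_bundle.truth
    decoys = set(truth[truth["class"].isin(["decoy_site", "decoy_neutral"])]
                 ["rsid"])
    insig = set(truth[truth["class"] == "insig_site"]["rsid"])
    assert not members & decoys
    assert not members & insig
    # while genuinely planted proxies are reachable
    planted = set(truth[truth["class"] == "disruptive_site"]["rsid"])
    assert planted <= members


def test_planted_r2_respects_thresholds(small_bundle):
    truth = small_bundle.truth
    real = truth[truth["class"].isin(
        ["disruptive_site", "benign_site", "hairpin_flank", "neutral"])]
    assert (real["r2"] >= 0.6).all()
    decoy = truth[truth["class"] == "decoy_site"]
    assert (decoy["r2"] < 0.6).all()


def test_infeasible_config_is_rejected(tmp_path):
    with pytest.raises(ConfigError):
        simulate_inputs(SimConfig(utr_len_range=(60, 80)), tmp_path)
    with pytest.raises(ConfigError):
        simulate_inputs(
            SimConfig(n_disruptive=50, n_switch_sites=4), tmp_path)


def test_expected_counts_reflect_truth_geometry(small_bundle):
    exp = expected_counts(small_bundle)
    truth = small_bundle.truth
    # neutral variants contribute nothing; every site-planted reachable
    # variant yields at least one triple
    assert exp["n_triples"] == exp["n_site"] + exp["n_flank"]
    assert exp["eligible_candidates"] == exp["n_site"]
    zones = exp["triple_zones"]
    neutral = set(truth[truth["class"].isin(
        ["neutral", "neutral_extra", "lead_neutral"])]["rsid"])
    assert not {k.split("|")[2] for k in zones} & neutral
    disruptive = set(truth[truth["class"] == "disruptive_site"]["rsid"])
    in_zones = {k.split("|")[2] for k, z in zones.items() if z == "site"}
    assert disruptive <= in_zones


def test_planted_fractions_sum_to_one(small_bundle):
    fr = small_bundle.config.planted_fractions
    assert sum(fr.values()) == pytest.approx(1.0)


def test_mirna_fasta_covers_targetome(small_bundle):
    mirnas = set()
    with open(small_bundle.files["mirna_fasta"]) as fh:
        for line in fh:
            if line.startswith(">"):
                mirnas.add(line[1:].split()[0])
    tg = pd.concat([pd.read_csv(p, sep="\t")
                    for p in small_bundle.files["targetome"]])
    assert set(tg["mirna"]) <= mirnas
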