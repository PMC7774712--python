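"""GWAS table parsing, significance filtering, trait categorization."""

import pandas as pd
import pytest

from mirtarsnp.gwas_ingest import (
    ConfigurationError,
    GwasAssociation,
    ParseReport,
    TraitCategory,
    categorize_trait,
    filter_significant,
    normalize_population,
    parse_associations,
)


def write_gwas(tmp_path, rows, columns=("rsid", "trait", "p_value", "population")):
    path = tmp_path / "gwas.tsv"
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, sep="\t", index=False)
    return path


def test_parse_maps_fields_and_categories(tmp_path):
    path = write_gwas(tmp_path, [("rs7132908", "Obesity", "3e-9", "EUR")])
    recs = parse_associations(path)
    assert len(recs) == 1
    r = recs[0]
    assert r.lead_rsid == "rs7132908"
    assert r.category is TraitCategory.OB
    assert r.p_value == 3e-9
    assert r.population == "EUR"


def test_unparseable_rows_are_dropped_and_counted(tmp_path):
    rows = [(f"rs{i}", "Obesity", "1e-8", "EUR") for i in range(10)]
    rows += [("rs999", "Obesity", "NR", "EUR"),       # bad p
             ("chr1:123", "Obesity", "1e-8", "EUR")]  # bad rsid
    path = write_gwas(tmp_path, rows)
    report = ParseReport()
    recs = parse_associations(path, report=report)
    assert len(recs) == 10
    assert report.n_dropped == 2
    assert report.drop_reasons == {"bad_p_value": 1, "bad_rsid": 1}


def test_missing_column_raises_configuration_error(tmp_path):
    path = write_gwas(tmp_path, [("rs1", "Obesity", "1e-8")],
                      columns=("rsid", "trait", "p_value"))
    with pytest.raises(ConfigurationError, match="population"):
        parse_associations(path)


def test_empty_file_gives_empty_list(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    assert parse_associations(path) == []


def test_unknown_population_kept_verbatim_and_flagged(tmp_path):
    path = write_gwas(tmp_path, [("rs1", "Obesity", "1e-8", "Oceanian")])
    report = ParseReport()
    recs = parse_associations(path, report=report)
    assert recs[0].population == "Oceanian"
    assert not recs[0].population_known
    assert "Oceanian" in report.unknown_populations
    assert normalize_population("European") == ("EUR", True)


def _assoc(p):
    return GwasAssociation("rs1", "Obesity", TraitCategory.OB, p, "EUR")


def test_significance_boundary_is_inclusive():
    records = [_assoc(1.0e-6), _assoc(2.0e-6), _assoc(1e-9)]
    kept = filter_significant(records)
    assert [r.p_value for r in kept] == [1.0e-6, 1e-9]
    # idempotent, order preserved, never grows
    assert filter_significant(kept) == kept
    assert filter_significant([]) == []


@pytest.mark.parametrize("text,expected", [
    ("Waist circumference", TraitCategory.WHR),
    ("Body fat percentage", TraitCategory.FM),
    ("Height", TraitCategory.UNMAPPED),
    ("obesity", TraitCategory.OB),
    ("Body mass index", TraitCategory.W_B),
    ("Colorectal cancer", TraitCategory.CRC_RISK),
    ("Colorectal cancer survival", TraitCategory.CRC_SURVIVAL),
    ("Visceral fat", TraitCategory.AT),
    ("", TraitCategory.UNMAPPED),
])
def test_trait_vocabulary(text, expected):
    assert categorize_trait(text) is expected
    assert categorize_trait(text) is categorize_trait(text)  # deterministic


def test_ambiguous_trait_takes_first_table_entry_and_is_logged():
    report = ParseReport()
    # matches both the obesity and weight vocabularies; obesity comes first
    cat = categorize_trait("Obesity and birth weight", report)
    assert cat is TraitCategory.OB
    assert report.ambiguous_traits


def test_invalid_association_rejected():
    with pytest.raises(ValueError):
        GwasAssociation("rs1", "t", TraitCategory.OB, 0.0, "EUR")
    with pytest.raises(ValueError):
        GwasAssociation("snp1", "t", TraitCategory.OB, 1e-8, "EUR")
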