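"""Parsing and categorization of GWAS association tables.

Associations arrive as a TSV with (at least) rsid, trait, p-value and
population columns; rows failing basic validation (malformed rsid,
unparseable p-value) are dropped and counted in a parse report.  Free-text
traits are mapped onto a closed set of disease categories — colorectal
cancer risk/survival and five obesity-related trait groups (obesity,
weight & BMI, waist/hip measures, adipose tissue, fat mass) — via a
shipped keyword table: exact phrase match first, then word-boundary
substring fallback, first match in table order wins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

#: genome-wide significance threshold used to retain lead SNPs
P_THRESHOLD = 1e-6

SUPER_POPULATIONS = ("EUR", "ASN", "AFR", "AMR")

_POP_ALIASES = {
    "EUR": "EUR", "EUROPEAN": "EUR", "EUROPEANS": "EUR",
    "ASN": "ASN", "ASIAN": "ASN", "ASIANS": "ASN", "EAS": "ASN", "SAS": "ASN",
    "AFR": "AFR", "AFRICAN": "AFR", "AFRICANS": "AFR",
    "AMR": "AMR", "AMERICAN": "AMR", "AMERICANS": "AMR",
}

_RSID_RE = re.compile(r"^rs[0-9]+$")


class TraitCategory(str, Enum):
    """Closed trait vocabulary: CRC plus five obesity-related groups."""

    CRC_SURVIVAL = "CRC_SURVIVAL"
    CRC_RISK = "CRC_RISK"
    OB = "OB"          # obesity / adiposity / overweight
    W_B = "W_B"        # weight & BMI
    WHR = "WHR"        # waist/hip circumference (ratio)
    AT = "AT"          # adipose tissue
    FM = "FM"          # fat mass
    UNMAPPED = "UNMAPPED"


#: keyword table, scanned in order; survival before risk so that
#: "colorectal cancer survival" is not swallowed by the risk phrases
TRAIT_KEYWORDS: list[tuple[TraitCategory, tuple[str, ...]]] = [
    (TraitCategory.CRC_SURVIVAL, (
        "colorectal cancer survival", "colon cancer survival",
        "crc survival",
    )),
    (TraitCategory.CRC_RISK, (
        "colorectal cancer", "colorectal adenoma", "colon cancer",
        "rectal cancer", "crc",
    )),
    (TraitCategory.OB, (
        "adiposity", "obesity", "overweight", "extreme obesity",
        "early onset extreme obesity",
    )),
    (TraitCategory.W_B, (
        "body mass index", "bmi", "body weight", "childhood bmi",
        "weight z-score", "birth weight", "weight",
    )),
    (TraitCategory.WHR, (
        "waist circumference", "hip circumference", "waist-hip ratio",
        "waist-to-hip ratio", "waist to hip ratio",
    )),
    (TraitCategory.AT, (
        "visceral adipose tissue", "subcutaneous adipose tissue",
        "at/sat ratio", "visceral fat", "adipose tissue",
    )),
    (TraitCategory.FM, (
        "body fat mass", "trunk fat mass", "body fat percentage",
        "fat mass",
    )),
]


class ConfigurationError(ValueError):
    """A required column or source label is missing from an input file."""


@dataclass(frozen=True)
class GwasAssociation:
    lead_rsid: str
    trait_text: str
    category: TraitCategory
    p_value: float
    population: str
    study_id: str = ""
    population_known: bool = True

    def __post_init__(self):
        if self.p_value <= 0:
            raise ValueError(f"{self.lead_rsid}: p_value must be > 0")
        if not _RSID_RE.match(self.lead_rsid):
            raise ValueError(f"invalid rsid {self.lead_rsid!r}")


@dataclass
class ParseReport:
    n_rows: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)
    unknown_populations: list = field(default_factory=list)
    ambiguous_traits: list = field(default_factory=list)

    def drop(self, reason: str):
        self.n_dropped += 1
        self.drop_reasons[reason] = self.drop_reasons.get(reason, 0) + 1

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_kept": self.n_kept,
            "n_dropped": self.n_dropped,
            "drop_reasons": self.drop_reasons,
            "unknown_populations": sorted(set(self.unknown_populations)),
            "ambiguous_traits": sorted(set(self.ambiguous_traits)),
        }


DEFAULT_COLUMNS = {
    "rsid": "rsid",
    "trait": "trait",
    "p_value": "p_value",
    "population": "population",
    "study_id": "study_id",
}


def normalize_population(value: str) -> tuple[str, bool]:
    """Map free-text population labels to 1000 Genomes super-population
    codes; unknown labels are kept verbatim and flagged."""
    key = str(value).strip().upper()
    if key in _POP_ALIASES:
        return _POP_ALIASES[key], True
    return str(value).strip(), False


def categorize_trait(trait_text: str,
                     report: ParseReport | None = None) -> TraitCategory:
    """Deterministically map free trait text to a category.

    Exact (case-insensitive) phrase match over the keyword table wins
    first; otherwise a word-boundary substring scan in table order.  Text
    matching phrases of more than one category is assigned the first
    category in table order (the ambiguity is recorded in the report).
    """
    text = trait_text.strip().lower()
    if not text:
        return TraitCategory.UNMAPPED
    for cat, phrases in TRAIT_KEYWORDS:
        if text in phrases:
            return cat
    hits = []
    for cat, phrases in TRAIT_KEYWORDS:
        for ph in phrases:
            if re.search(r"\b" + re.escape(ph) + r"\b", text):
                hits.append(cat)
                break
    if not hits:
        return TraitCategory.UNMAPPED
    if len(set(hits)) > 1 and report is not None:
        report.ambiguous_traits.append(trait_text)
    return hits[0]


def parse_associations(
    path: str | Path,
    columns: dict | None = None,
    report: ParseReport | None = None,
) -> list[GwasAssociation]:
    """Read a GWAS-catalog-style TSV into validated associations.

    Rows with malformed rsid or non-numeric p-value are dropped (counted
    in the report); a missing mandatory column raises
    :class:`ConfigurationError` naming the column.
    """
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    if report is None:
        report = ParseReport()
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.empty and len(df.columns) <= 1:
        return []
    for key in ("rsid", "trait", "p_value", "population"):
        if cols[key] not in df.columns:
            raise ConfigurationError(
                f"missing mandatory column {cols[key]!r} in {path}"
            )
    out: list[GwasAssociation] = []
    for _, row in df.iterrows():
        report.n_rows += 1
        rsid = str(row[cols["rsid"]]).strip()
        if not _RSID_RE.match(rsid):
            report.drop("bad_rsid")
            continue
        try:
            p = float(row[cols["p_value"]])
        except (TypeError, ValueError):
            report.drop("bad_p_value")
            continue
        if not p > 0:
            report.drop("bad_p_value")
            continue
        pop, known = normalize_population(row[cols["population"]])
        if not known:
            report.unknown_populations.append(pop)
        trait = str(row[cols["trait"]]).strip()
        out.append(GwasAssociation(
            lead_rsid=rsid,
            trait_text=trait,
            category=categorize_trait(trait, report),
            p_value=p,
            population=pop,
            study_id=str(row[cols["study_id"]]) if cols["study_id"] in df.columns else "",
            population_known=known,
        ))
        report.n_kept += 1
    return out


def filter_significant(
    records: list[GwasAssociation],
    threshold: float = P_THRESHOLD,
) -> list[GwasAssociation]:
    """Retain genome-wide significant leads (p <= threshold, inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return [r for r in records if r.p_value <= threshold]
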