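"""Annotation and ranking of scored miRNA:mRNA:SNP interactions.

Candidates are site-located interactions whose structure-distance p-value
falls below 0.2 (the RNAsnp significance convention).  Because the source
criteria name the evidence to combine but no formula, the composite score
is defined here explicitly and recorded in the run manifest:

    composite = mean(rank01(1 - p), rank01(|dPu%|), rank01(|ddG|))
                + 0.5 if the SNP is an eQTL

where rank01 is the average-tie rank rescaled to [0, 1] over the
candidate set.  eQTL status is a bonus, not a filter.  Conservation
flags (GERP/SiPhy) are pass-through annotations.  Ties are broken by
(smaller p, larger |ddG|, rsid, miRNA) so ranking is total and
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .intersect import InteractionTriple
from .rna_struct import (
    AccessibilityResult,
    HybridResult,
    StructureDistanceResult,
)

log = logging.getLogger(__name__)

P_CUT = 0.2
EQTL_BONUS = 0.5


@dataclass(frozen=True)
class StructureImpact:
    """The three structural metrics for one interaction."""

    distance: StructureDistanceResult
    access: AccessibilityResult
    hybrid: HybridResult


@dataclass(frozen=True)
class AnnotatedRecord:
    triple: InteractionTriple
    impact: StructureImpact
    is_eqtl: bool
    gerp_flag: str    # '+' / '-'
    siphy_flag: str


@dataclass(frozen=True)
class PrioritizedRecord:
    record: AnnotatedRecord
    composite_score: float
    rank: int


def load_annotation_tables(eqtl_path: str | Path | None,
                           conservation_path: str | Path | None):
    """(eqtl rsid set, rsid -> (gerp, siphy)); duplicate rows: first wins."""
    eqtl: set = set()
    if eqtl_path is not None:
        df = pd.read_csv(eqtl_path, sep="\t", dtype=str)
        dups = df["rsid"].duplicated()
        if dups.any():
            log.warning("%d duplicate eQTL rows; first kept", int(dups.sum()))
        eqtl = set(df["rsid"].drop_duplicates())
    cons: dict = {}
    if conservation_path is not None:
        df = pd.read_csv(conservation_path, sep="\t", dtype=str)
        for _, row in df.iterrows():
            if row["rsid"] not in cons:
                cons[row["rsid"]] = (str(row["gerp"]), str(row["siphy"]))
            else:
                log.warning("duplicate conservation row for %s; first kept", row["rsid"])
    return eqtl, cons


def annotate(
    records: list[tuple],
    eqtl_rsids: set,
    conservation: dict,
) -> list[AnnotatedRecord]:
    """Attach eQTL/conservation evidence; missing rsids get (False, -, -)
    and no record is ever dropped by annotation."""
    out = []
    for triple, impact in records:
        rsid = triple.variant.rsid
        gerp, siphy = conservation.get(rsid, ("-", "-"))
        out.append(AnnotatedRecord(
            triple=triple,
            impact=impact,
            is_eqtl=rsid in eqtl_rsids,
            gerp_flag=gerp,
            siphy_flag=siphy,
        ))
    return out


def _rank01(values: np.ndarray) -> np.ndarray:
    """Average-tie ranks rescaled to [0, 1] (single element -> 1.0)."""
    n = len(values)
    if n == 1:
        return np.ones(1)
    order = pd.Series(values).rank(method="average").to_numpy()
    return (order - 1.0) / (n - 1.0)


def prioritize(records: list[AnnotatedRecord],
               p_cut: float = P_CUT) -> list[PrioritizedRecord]:
    """Rank the candidate set (site-located, d_max p < p_cut).

    An empty candidate set yields an empty list.  Ranking is invariant to
    input order and to the presence of non-candidate records.
    """
    cands = [
        r for r in records
        if r.triple.location_class == "site"
        and r.impact.distance.p_value < p_cut
    ]
    if not cands:
        return []
    cands = sorted(
        cands,
        key=lambda r: (r.triple.variant.rsid, r.triple.target.mirna_id,
                       r.triple.target.gene_symbol),
    )
    one_minus_p = np.array([1.0 - r.impact.distance.p_value for r in cands])
    abs_dpu = np.array([abs(r.impact.access.delta_pu_pct) for r in cands])
    abs_ddg = np.array([abs(r.impact.hybrid.ddg) for r in cands])
    score = (_rank01(one_minus_p) + _rank01(abs_dpu) + _rank01(abs_ddg)) / 3.0
    score = score + EQTL_BONUS * np.array([r.is_eqtl for r in cands], dtype=float)
    order = sorted(
        range(len(cands)),
        key=lambda i: (
            -score[i],
            cands[i].impact.distance.p_value,
            -abs_ddg[i],
            cands[i].triple.variant.rsid,
            cands[i].triple.target.mirna_id,
        ),
    )
    return [
        PrioritizedRecord(record=cands[i], composite_score=float(score[i]),
                          rank=pos + 1)
        for pos, i in enumerate(order)
    ]


def prioritized_table(ranked: list[PrioritizedRecord]) -> pd.DataFrame:
    """Shortlist in the report column order."""
    rows = []
    for pr in ranked:
        r = pr.record
        t = r.triple
        ev = sorted(t.variant.evidence, key=lambda e: (e.lead_rsid, e.population))
        rows.append({
            "Databases": ", ".join(sorted(t.target.sources)),
            "Categories": ", ".join(sorted(c.value for c in t.categories)),
            "SNP": f"{t.variant.rsid} {t.variant.ref_allele}>{t.variant.alt_allele}",
            "Reference-GWAS SNP": ", ".join(
                dict.fromkeys(e.lead_rsid for e in ev)) or t.variant.rsid,
            "Is SNP eQTL?": "Yes" if r.is_eqtl else "No",
            "GERP": r.gerp_flag,
            "SiPhy": r.siphy_flag,
            "d_max": round(r.impact.distance.d_max, 4),
            "p-value": round(r.impact.distance.p_value, 4),
            "dPu_pct": round(r.impact.access.delta_pu_pct, 2),
            "ddG_hybrid": round(r.impact.hybrid.ddg, 2),
            "Interaction": f"{t.target.mirna_id}:{t.target.gene_symbol}:{t.variant.rsid}",
            "composite_score": round(pr.composite_score, 4),
            "rank": pr.rank,
        })
    return pd.DataFrame(rows)
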