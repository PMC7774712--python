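"""Population-specific association blocks from a linkage-disequilibrium
proxy table.

Each GWAS lead SNP is expanded into the set of variants correlated with
it at r^2 >= 0.6 (inclusive) in the lead's super-population — one hop
from the lead, no transitive chasing (exposed as a config option).  The
lead is always a member of its own block with r^2 = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .gwas_ingest import GwasAssociation

log = logging.getLogger(__name__)

#: minimum squared correlation for proxy inclusion
R2_MIN = 0.6


@dataclass(frozen=True)
class LdProxyEdge:
    lead_rsid: str
    proxy_rsid: str
    r_squared: float
    population: str

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r^2 {self.r_squared} outside [0, 1]")


class LdTable:
    """LD edges indexed by (lead_rsid, population); duplicate
    (lead, proxy, population) rows keep the maximum r^2."""

    def __init__(self, edges: list[LdProxyEdge] | None = None):
        self._index: dict[tuple, dict[str, float]] = {}
        for e in edges or []:
            self.add(e)

    def add(self, edge: LdProxyEdge):
        key = (edge.lead_rsid, edge.population)
        bucket = self._index.setdefault(key, {})
        prev = bucket.get(edge.proxy_rsid)
        if prev is None or edge.r_squared > prev:
            bucket[edge.proxy_rsid] = edge.r_squared

    def proxies(self, lead_rsid: str, population: str) -> dict[str, float]:
        return dict(self._index.get((lead_rsid, population), {}))

    def __len__(self) -> int:
        return sum(len(b) for b in self._index.values())


def load_ld_table(path: str | Path) -> LdTable:
    """Load a (lead_rsid, proxy_rsid, r2, population) TSV.

    Rows with malformed r^2 or r^2 outside [0, 1] are skipped with a
    warning; a missing file raises the usual I/O error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    table = LdTable()
    for col in ("lead_rsid", "proxy_rsid", "r2", "population"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    for _, row in df.iterrows():
        try:
            r2 = float(row["r2"])
        except (TypeError, ValueError):
            log.warning("skipping LD row with malformed r2: %s", dict(row))
            continue
        if not 0.0 <= r2 <= 1.0:
            log.warning("skipping LD row with r2=%s outside [0,1]", r2)
            continue
        table.add(LdProxyEdge(
            lead_rsid=str(row["lead_rsid"]).strip(),
            proxy_rsid=str(row["proxy_rsid"]).strip(),
            r_squared=r2,
            population=str(row["population"]).strip(),
        ))
    return table


@dataclass(frozen=True)
class AssociationBlock:
    lead: GwasAssociation
    members: frozenset = field(default_factory=frozenset)  # (rsid, r2)
    population: str = ""

    @property
    def rsids(self) -> set:
        return {r for r, _ in self.members}

    @property
    def proxy_rsids(self) -> set:
        return self.rsids - {self.lead.lead_rsid}


def expand_block(
    lead: GwasAssociation,
    edges: LdTable,
    r2_min: float = R2_MIN,
) -> AssociationBlock:
    """Lead plus all proxies with r^2 >= r2_min (inclusive boundary) in the
    lead's population; a lead with no edges yields a singleton block."""
    if not 0.0 < r2_min <= 1.0:
        raise ValueError("r2_min must be in (0, 1]")
    members = {(lead.lead_rsid, 1.0)}
    for proxy, r2 in edges.proxies(lead.lead_rsid, lead.population).items():
        if r2 >= r2_min and proxy != lead.lead_rsid:
            members.add((proxy, r2))
    return AssociationBlock(
        lead=lead, members=frozenset(members), population=lead.population
    )


def unique_variants(blocks: list[AssociationBlock]) -> pd.DataFrame:
    """Per-(category, population) variant accounting plus overall rows.

    ``index_variants``: distinct leads; ``proxy_variants``: distinct
    proxies (leads of other blocks may appear here too — each role is
    counted where it occurs); ``combined`` = their union.  The final rows
    give the grand total with and without cross-population/-category
    duplicates.
    """
    rows = []
    groups: dict[tuple, dict] = {}
    for b in blocks:
        key = (b.lead.category.value, b.population)
        g = groups.setdefault(key, {"leads": set(), "proxies": set()})
        g["leads"].add(b.lead.lead_rsid)
        g["proxies"] |= b.proxy_rsids
    all_leads: set = set()
    all_proxies: set = set()
    sum_idx = sum_proxy = sum_comb = 0
    for (cat, pop), g in sorted(groups.items()):
        proxies = g["proxies"] - g["leads"]
        rows.append({
            "category": cat, "population": pop,
            "index_variants": len(g["leads"]),
            "proxy_variants": len(proxies),
            "combined": len(g["leads"] | proxies),
        })
        sum_idx += len(g["leads"])
        sum_proxy += len(proxies)
        sum_comb += len(g["leads"] | proxies)
        all_leads |= g["leads"]
        all_proxies |= proxies
    rows.append({
        "category": "Overall", "population": "All",
        "index_variants": sum_idx, "proxy_variants": sum_proxy,
        "combined": sum_comb,
    })
    uniq_proxies = all_proxies - all_leads
    rows.append({
        "category": "Overall without duplicates", "population": "All",
        "index_variants": len(all_leads),
        "proxy_variants": len(uniq_proxies),
        "combined": len(all_leads | uniq_proxies),
    })
    return pd.DataFrame(rows)


def unique_rsids(blocks: list[AssociationBlock]) -> set:
    out: set = set()
    for b in blocks:
        out |= b.rsids
    return out
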