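"""The unified miRNA targetome: target-site intervals from several source
databases, merged, flanked and zoned.

Every interval is carried in two coordinate systems — genomic and
transcript-relative (3'UTR, sense strand) — both 0-based half-open.  The
25 nt up- and downstream of a site are its flanking regions; the extended
interval (site plus flanks, clamped to the UTR) is what variants are
intersected against, and every position of it is zoned as either ``site``
or ``flank``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

FLANK_LEN = 25
KNOWN_SOURCES = ("StarBase", "TargetScan", "microRNA.org")
MIN_SITE_LEN = 6


class UnknownSourceError(ValueError):
    pass


@dataclass(frozen=True)
class TargetomeRecord:
    mirna_id: str
    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str                      # '+' or '-'
    genomic_site: tuple              # (start, end), 0-based half-open
    utr_site: tuple                  # transcript-relative, sense strand
    sources: frozenset
    evidence: str                    # 'verified' | 'predicted'

    def __post_init__(self):
        gs, ge = self.genomic_site
        us, ue = self.utr_site
        if ge - gs < MIN_SITE_LEN:
            raise ValueError(
                f"site shorter than {MIN_SITE_LEN} nt: {self.mirna_id}/{self.transcript_id}"
            )
        if ge - gs != ue - us:
            raise ValueError("genomic and UTR interval lengths differ")
        if not self.sources:
            raise ValueError("sources must be non-empty")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def key(self) -> tuple:
        return (self.mirna_id, self.transcript_id, self.genomic_site)

    def utr_pos_of_genomic(self, gpos: int) -> int:
        """Transcript-relative position of a genomic coordinate, using the
        site's own affine genomic<->UTR mapping (strand-aware)."""
        gs, ge = self.genomic_site
        us, _ = self.utr_site
        if self.strand == "+":
            return us + (gpos - gs)
        return us + (ge - 1 - gpos)


@dataclass(frozen=True)
class ZonedInterval:
    """A target site with flanks attached and a site/flank zoning."""

    record: TargetomeRecord
    extended_utr: tuple          # (start, end) in UTR coords, clamped
    flank_len: int = FLANK_LEN

    def zone(self, utr_pos: int) -> str:
        s, e = self.record.utr_site
        if s <= utr_pos < e:
            return "site"
        a, b = self.extended_utr
        if a <= utr_pos < b:
            return "flank"
        raise ValueError(f"position {utr_pos} outside extended interval {self.extended_utr}")

    @property
    def extended_genomic(self) -> tuple:
        """Genomic interval matching the (clamped) extended UTR interval."""
        gs, ge = self.record.genomic_site
        us, ue = self.record.utr_site
        a, b = self.extended_utr
        if self.record.strand == "+":
            return (gs - (us - a), ge + (b - ue))
        return (gs - (b - ue), ge + (us - a))


def add_flanks(record: TargetomeRecord, flank_len: int = FLANK_LEN,
               utr_len: int | None = None) -> ZonedInterval:
    """Attach up/downstream flanks, clamped to the UTR boundaries."""
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    us, ue = record.utr_site
    if utr_len is not None and utr_len < ue:
        raise ValueError("utr_len shorter than site end")
    a = max(0, us - flank_len)
    b = ue + flank_len if utr_len is None else min(utr_len, ue + flank_len)
    return ZonedInterval(record=record, extended_utr=(a, b), flank_len=flank_len)


_REQUIRED_COLS = (
    "db", "mirna", "gene", "transcript", "chrom", "strand",
    "genomic_start", "genomic_end", "utr_start", "utr_end", "evidence",
)


def load_targetome(paths: list[str | Path]) -> list[TargetomeRecord]:
    """Read one or more source TSVs into targetome records.

    Each row declares its database in the ``db`` column; unknown labels
    raise :class:`UnknownSourceError`, invalid intervals (start >= end)
    are rejected with a warning.
    """
    records: list[TargetomeRecord] = []
    for path in paths:
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.empty and len(df.columns) <= 1:
            continue
        for col in _REQUIRED_COLS:
            if col not in df.columns:
                raise ValueError(f"missing column {col!r} in {path}")
        for _, row in df.iterrows():
            db = str(row["db"]).strip()
            if db not in KNOWN_SOURCES:
                raise UnknownSourceError(
                    f"unknown source database {db!r} in {path}; "
                    f"expected one of {KNOWN_SOURCES}"
                )
            gs, ge = int(row["genomic_start"]), int(row["genomic_end"])
            us, ue = int(row["utr_start"]), int(row["utr_end"])
            if gs >= ge or us >= ue:
                log.warning("rejecting invalid interval %s:[%d,%d)", row["mirna"], gs, ge)
                continue
            records.append(TargetomeRecord(
                mirna_id=str(row["mirna"]).strip(),
                gene_symbol=str(row["gene"]).strip(),
                transcript_id=str(row["transcript"]).strip(),
                chrom=str(row["chrom"]).strip(),
                strand=str(row["strand"]).strip(),
                genomic_site=(gs, ge),
                utr_site=(us, ue),
                sources=frozenset({db}),
                evidence=str(row["evidence"]).strip(),
            ))
    return records


def merge_records(records: list[TargetomeRecord]) -> list[TargetomeRecord]:
    """Deduplicate by (miRNA, transcript, genomic interval), taking the
    union of sources; evidence is 'verified' if any source says so.
    Overlapping but non-identical intervals stay separate (logged)."""
    merged: dict[tuple, TargetomeRecord] = {}
    for rec in records:
        prev = merged.get(rec.key)
        if prev is None:
            merged[rec.key] = rec
        else:
            merged[rec.key] = TargetomeRecord(
                mirna_id=rec.mirna_id,
                gene_symbol=prev.gene_symbol,
                transcript_id=rec.transcript_id,
                chrom=prev.chrom,
                strand=prev.strand,
                genomic_site=rec.genomic_site,
                utr_site=prev.utr_site,
                sources=prev.sources | rec.sources,
                evidence="verified" if "verified" in (prev.evidence, rec.evidence)
                         else prev.evidence,
            )
    out = sorted(merged.values(), key=lambda r: (r.chrom, r.genomic_site, r.mirna_id))
    _log_near_duplicates(out)
    return out


def _log_near_duplicates(records: list[TargetomeRecord]):
    by_mt: dict[tuple, list[TargetomeRecord]] = {}
    for r in records:
        by_mt.setdefault((r.mirna_id, r.transcript_id), []).append(r)
    for (mirna, tx), recs in by_mt.items():
        if len(recs) < 2:
            continue
        recs = sorted(recs, key=lambda r: r.genomic_site)
        for a, b in zip(recs, recs[1:]):
            if a.genomic_site[1] > b.genomic_site[0]:
                log.info(
                    "near-identical sites kept separate: %s/%s %s vs %s",
                    mirna, tx, a.genomic_site, b.genomic_site,
                )


def write_targetome_bed(records: list[TargetomeRecord], path: str | Path):
    """Merged targetome as a BED-like TSV (genomic, 0-based half-open)."""
    rows = [{
        "chrom": r.chrom,
        "start": r.genomic_site[0],
        "end": r.genomic_site[1],
        "name": f"{r.mirna_id}|{r.gene_symbol}|{r.transcript_id}",
        "strand": r.strand,
        "sources": ",".join(sorted(r.sources)),
        "evidence": r.evidence,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
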