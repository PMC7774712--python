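"""Mapping disease-associated variants onto the zoned targetome.

Produces miRNA:mRNA:SNP interaction triples — the atomic result unit of
the pipeline — for every variant falling inside a target site or its
25-nt flanks, then attaches wild-type/variant RNA sequence contexts
extracted from the 3'UTR (sense strand, so minus-strand genes get their
genomic alleles complemented).

Only biallelic SNVs are processed; indels and multiallelic records are
logged and skipped upstream (structure scoring assumes equal-length
alleles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .gwas_ingest import TraitCategory
from .rna_struct.energy import dna_to_rna
from .targetome import ZonedInterval

log = logging.getLogger(__name__)

CONTEXT_RADIUS = 200

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class RefMismatchError(ValueError):
    """UTR sequence disagrees with a variant's reference allele
    (usually a sign of stale coordinates)."""

    def __init__(self, rsid: str, expected: str, observed: str):
        super().__init__(
            f"{rsid}: UTR base {observed!r} does not match reference allele "
            f"{expected!r} (after strand adjustment)"
        )
        self.rsid = rsid
        self.expected = expected
        self.observed = observed


@dataclass(frozen=True)
class VariantEvidence:
    """One (lead, population) attribution of a variant."""

    lead_rsid: str
    r_squared: float
    population: str
    category: TraitCategory
    role: str  # 'lead' | 'proxy'


@dataclass(frozen=True)
class Variant:
    rsid: str
    chrom: str
    pos: int                  # genomic, 0-based
    ref_allele: str
    alt_allele: str
    evidence: tuple = ()      # tuple of VariantEvidence

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.rsid}: ref == alt")
        for a in (self.ref_allele, self.alt_allele):
            if a not in "ACGT":
                raise ValueError(f"{self.rsid}: non-SNV allele {a!r}")


@dataclass(frozen=True)
class InteractionTriple:
    """One miRNA:mRNA:SNP unit with optional sequence contexts."""

    variant: Variant
    zoned: ZonedInterval
    location_class: str               # 'site' | 'flank'
    utr_pos: int
    wt_context: str = ""
    alt_context: str = ""
    snp_offset: int = -1
    site_in_context: tuple = ()       # site interval in context coords
    ext_in_context: tuple = ()        # site+flanks interval in context coords

    @property
    def target(self):
        return self.zoned.record

    @property
    def key(self) -> tuple:
        return (self.target.mirna_id, self.target.gene_symbol, self.variant.rsid)

    @property
    def categories(self) -> set:
        return {e.category for e in self.variant.evidence}

    @property
    def populations(self) -> set:
        return {e.population for e in self.variant.evidence}


def load_variant_table(path: str | Path) -> list[Variant]:
    """Read a VCF-like TSV (#CHROM/POS/ID/REF/ALT, 1-based positions);
    indels and multiallelic rows are logged and skipped."""
    import io

    # tolerate VCF-style '##' meta lines and a '#CHROM' header
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("##")]
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", dtype=str)
    df.columns = [c.lstrip("#").lower() for c in df.columns]
    out: list[Variant] = []
    for _, row in df.iterrows():
        ref, alt = str(row["ref"]).upper(), str(row["alt"]).upper()
        if len(ref) != 1 or len(alt) != 1 or "," in alt:
            log.warning("skipping non-SNV/multiallelic record %s", row["id"])
            continue
        if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
            log.warning("skipping malformed alleles for %s", row["id"])
            continue
        out.append(Variant(
            rsid=str(row["id"]).strip(),
            chrom=str(row["chrom"]).strip(),
            pos=int(row["pos"]) - 1,
            ref_allele=ref,
            alt_allele=alt,
        ))
    return out


def _dedup_sort_key(t: InteractionTriple) -> tuple:
    # site-class hits beat flank-class; then smaller interval, stable order
    return (
        0 if t.location_class == "site" else 1,
        t.target.genomic_site,
        t.target.transcript_id,
    )


def intersect_variants(
    variants: list[Variant],
    zoned_targetome: list[ZonedInterval],
) -> list[InteractionTriple]:
    """All (variant, extended target interval) containments, one triple
    per unique (miRNA, gene, SNP)."""
    trees: dict[str, IntervalTree] = {}
    for zi in zoned_targetome:
        a, b = zi.extended_genomic
        trees.setdefault(zi.record.chrom, IntervalTree()).addi(a, b, zi)
    hits: list[InteractionTriple] = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        for iv in tree.at(v.pos):
            zi: ZonedInterval = iv.data
            utr_pos = zi.record.utr_pos_of_genomic(v.pos)
            hits.append(InteractionTriple(
                variant=v,
                zoned=zi,
                location_class=zi.zone(utr_pos),
                utr_pos=utr_pos,
            ))
    dedup: dict[tuple, InteractionTriple] = {}
    for t in sorted(hits, key=_dedup_sort_key):
        dedup.setdefault(t.key, t)
    return sorted(
        dedup.values(),
        key=lambda t: (t.variant.chrom, t.variant.pos, t.target.mirna_id,
                       t.target.gene_symbol),
    )


def extract_context(
    triple: InteractionTriple,
    utr_seqs: dict,
    context_radius: int = CONTEXT_RADIUS,
) -> InteractionTriple:
    """Attach WT/ALT RNA contexts around the extended site interval.

    The context is the UTR (sense-strand) subsequence covering the
    extended interval plus ``context_radius`` nt on each side, truncated
    at the UTR ends and DNA->RNA converted.  For minus-strand genes the
    genomic alleles are complemented before substitution.
    """
    rec = triple.target
    try:
        utr = utr_seqs[rec.transcript_id]
    except KeyError:
        raise KeyError(f"transcript {rec.transcript_id!r} absent from UTR FASTA")
    utr = str(utr).upper().replace("U", "T")
    n = len(utr)
    if rec.strand == "+":
        ref_sense, alt_sense = triple.variant.ref_allele, triple.variant.alt_allele
    else:
        ref_sense = triple.variant.ref_allele.translate(_COMPLEMENT)
        alt_sense = triple.variant.alt_allele.translate(_COMPLEMENT)
    pos = triple.utr_pos
    if not 0 <= pos < n:
        raise RefMismatchError(triple.variant.rsid, ref_sense, "<out of range>")
    if utr[pos] != ref_sense:
        raise RefMismatchError(triple.variant.rsid, ref_sense, utr[pos])
    a0, b0 = triple.zoned.extended_utr
    a = max(0, a0 - context_radius)
    b = min(n, b0 + context_radius)
    wt = utr[a:b]
    off = pos - a
    alt = wt[:off] + alt_sense + wt[off + 1:]
    us, ue = rec.utr_site
    return replace(
        triple,
        wt_context=dna_to_rna(wt),
        alt_context=dna_to_rna(alt),
        snp_offset=off,
        site_in_context=(us - a, ue - a),
        ext_in_context=(a0 - a, b0 - a),
    )
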