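"""End-to-end pipeline: from input files to ranked result tables.

Stages: GWAS ingest -> significance filter -> LD block expansion ->
targetome merge/zoning -> variant intersection -> structure metrics
(d_max + empirical p, dPu%, ddG_hybrid) -> annotation -> prioritization.
Every stage failure aborts with the stage name and offending record
context; every threshold in force is recorded in the run manifest.

Structure metrics depend on (variant, site) only, not on the miRNA, so
they are computed once per unique (rsid, transcript, site) group and the
duplex term once per triple.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .gwas_ingest import (
    P_THRESHOLD,
    ParseReport,
    filter_significant,
    parse_associations,
)
from .intersect import (
    CONTEXT_RADIUS,
    InteractionTriple,
    Variant,
    VariantEvidence,
    extract_context,
    intersect_variants,
    load_variant_table,
)
from .ld_blocks import R2_MIN, expand_block, load_ld_table, unique_variants
from .prioritize import (
    EQTL_BONUS,
    P_CUT,
    StructureImpact,
    annotate,
    load_annotation_tables,
    prioritize,
    prioritized_table,
)
from .rna_struct import (
    EnergyModel,
    accessibility,
    ddg_hybrid,
    structure_distance,
)
from .targetome import (
    FLANK_LEN,
    add_flanks,
    load_targetome,
    merge_records,
    write_targetome_bed,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, context: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {context}: {cause}")
        self.stage = stage
        self.context = context


@dataclass
class PipelineConfig:
    """Paths and thresholds for one run (YAML-serializable)."""

    gwas: str = ""
    ld: str = ""
    targetome: list = field(default_factory=list)
    utr_fasta: str = ""
    mirna_fasta: str = ""
    variants: str = ""
    eqtl: str | None = None
    conservation: str | None = None

    p_threshold: float = P_THRESHOLD
    r2_min: float = R2_MIN
    flank_len: int = FLANK_LEN
    context_radius: int = CONTEXT_RADIUS
    p_cut: float = P_CUT
    n_null: int = 500
    window_len: int = 100
    acc_flank: int = 50
    seed: int = 0
    columns: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunManifest:
    config_hash: str
    input_checksums: dict
    seed: int
    version: str
    thresholds: dict
    scoring: dict
    timestamp: str

    def write(self, path: str | Path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _group_seed(base_seed: int, key: str) -> int:
    return (base_seed * 1_000_003 + zlib.crc32(key.encode())) % (2**31)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = ParseReport()

    # -- GWAS ingest ------------------------------------------------------
    stage = "gwas_ingest"
    try:
        assocs = parse_associations(config.gwas, config.columns or None, report)
        leads = filter_significant(assocs, config.p_threshold)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(config.gwas), e) from e
    log.info("%d associations, %d significant leads", len(assocs), len(leads))

    # -- LD blocks --------------------------------------------------------
    stage = "ld_blocks"
    try:
        ld = load_ld_table(config.ld)
        blocks = [expand_block(lead, ld, config.r2_min) for lead in leads]
        block_summary = unique_variants(blocks)
        block_summary.to_csv(outdir / "block_summary.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(config.ld), e) from e

    # -- targetome --------------------------------------------------------
    stage = "targetome"
    try:
        records = merge_records(load_targetome(config.targetome))
        utr_seqs = {
            r.id: str(r.seq) for r in SeqIO.parse(str(config.utr_fasta), "fasta")
        }
        zoned = [
            add_flanks(r, config.flank_len, utr_len=len(utr_seqs[r.transcript_id]))
            for r in records
        ]
        write_targetome_bed(records, outdir / "targetome.tsv")
        src_counts: dict = {}
        for r in records:
            for s in r.sources:
                src_counts[s] = src_counts.get(s, 0) + 1
        with open(outdir / "targetome_manifest.json", "w") as fh:
            json.dump({
                "n_sites": len(records),
                "n_mirnas": len({r.mirna_id for r in records}),
                "n_transcripts": len({r.transcript_id for r in records}),
                "records_per_source": src_counts,
                "flank_len": config.flank_len,
            }, fh, indent=2, sort_keys=True)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(config.targetome), e) from e

    # -- variants + evidence ----------------------------------------------
    stage = "variants"
    try:
        raw_variants = load_variant_table(config.variants)
        evidence: dict[str, list] = {}
        for lead, block in zip(leads, blocks):
            for rsid, r2 in block.members:
                evidence.setdefault(rsid, []).append(VariantEvidence(
                    lead_rsid=lead.lead_rsid, r_squared=r2,
                    population=lead.population, category=lead.category,
                    role="lead" if rsid == lead.lead_rsid else "proxy",
                ))
        variants = [
            Variant(v.rsid, v.chrom, v.pos, v.ref_allele, v.alt_allele,
                    evidence=tuple(sorted(
                        evidence[v.rsid],
                        key=lambda e: (e.lead_rsid, e.population))))
            for v in raw_variants if v.rsid in evidence
        ]
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(config.variants), e) from e
    log.info("%d variants in association blocks", len(variants))

    # -- intersection ------------------------------------------------------
    stage = "intersect"
    try:
        triples = intersect_variants(variants, zoned)
        triples = [
            extract_context(t, utr_seqs, config.context_radius) for t in triples
        ]
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, "variant x targetome intersection", e) from e
    log.info("%d miRNA:mRNA:SNP triples", len(triples))
    _write_interaction_tables(triples, outdir)

    # -- structure metrics -------------------------------------------------
    stage = "rna_struct"
    model = EnergyModel.turner()
    mirna_seqs = {
        r.id: str(r.seq).upper().replace("T", "U")
        for r in SeqIO.parse(str(config.mirna_fasta), "fasta")
    }
    cache: dict[tuple, tuple] = {}
    scored: list[tuple] = []
    for t in triples:
        try:
            gkey = (t.variant.rsid, t.target.transcript_id, t.target.utr_site)
            if gkey not in cache:
                dist = structure_distance(
                    t.wt_context, t.alt_context, t.snp_offset, model,
                    window_len=config.window_len, n_null=config.n_null,
                    seed=_group_seed(config.seed, "|".join(map(str, gkey))),
                    p_sig=config.p_cut,
                )
                acc = accessibility(
                    t.wt_context, t.alt_context, t.site_in_context, model,
                    acc_flank=config.acc_flank,
                )
                cache[gkey] = (dist, acc)
            dist, acc = cache[gkey]
            mirna = mirna_seqs[t.target.mirna_id]
            a, b = t.ext_in_context
            hyb = ddg_hybrid(mirna, t.wt_context[a:b], t.alt_context[a:b], model)
            scored.append((t, StructureImpact(dist, acc, hyb)))
        except Exception as e:  # noqa: BLE001
            raise StageError(
                stage,
                f"{t.target.mirna_id}:{t.target.gene_symbol}:{t.variant.rsid}",
                e,
            ) from e
    metric_df = _metric_table(scored)
    metric_df.to_csv(outdir / "metrics.tsv", sep="\t", index=False)

    # -- annotation + prioritization ---------------------------------------
    stage = "prioritize"
    try:
        eqtl, cons = load_annotation_tables(config.eqtl, config.conservation)
        annotated = annotate(scored, eqtl, cons)
        ranked = prioritize(annotated, config.p_cut)
        prioritized_table(ranked).to_csv(
            outdir / "prioritized.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, "annotation tables", e) from e

    # -- summary + manifest -------------------------------------------------
    summary = summarize_metrics(metric_df)
    summary.update({
        "n_associations": len(assocs),
        "n_significant_leads": len(leads),
        "n_block_variants": len(variants),
        "n_candidates": len(ranked),
    })
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(outdir / "parse_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)

    inputs = [config.gwas, config.ld, config.utr_fasta, config.mirna_fasta,
              config.variants, *config.targetome]
    inputs += [p for p in (config.eqtl, config.conservation) if p]
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        input_checksums={str(p): _sha256(p) for p in inputs},
        seed=config.seed,
        version=__version__,
        thresholds={
            "p_threshold": config.p_threshold,
            "r2_min": config.r2_min,
            "flank_len": config.flank_len,
            "p_cut": config.p_cut,
            "n_null": config.n_null,
            "window_len": config.window_len,
            "acc_flank": config.acc_flank,
            "context_radius": config.context_radius,
        },
        scoring={
            "composite": "mean(rank01(1-p), rank01(|dPu%|), rank01(|ddG|))",
            "eqtl_bonus": EQTL_BONUS,
            "delta_pu_sign": "100*(Pu_alt - Pu_wt); negative = reduced accessibility",
            "ddg_sign": "dG_alt - dG_wt; positive = decreased hybrid stability",
            "null": "dinucleotide-preserving shuffle + one random substitution",
        },
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(outdir / "manifest.json")
    return summary


def _metric_table(scored: list[tuple]) -> pd.DataFrame:
    rows = []
    for t, imp in scored:
        rows.append({
            "mirna": t.target.mirna_id,
            "gene": t.target.gene_symbol,
            "rsid": t.variant.rsid,
            "location_class": t.location_class,
            "d_max": imp.distance.d_max,
            "d_max_p": imp.distance.p_value,
            "significant": imp.distance.significant,
            "pu_wt": imp.access.pu_wt,
            "pu_alt": imp.access.pu_alt,
            "delta_pu_pct": imp.access.delta_pu_pct,
            "dg_wt": imp.hybrid.dg_wt,
            "dg_alt": imp.hybrid.dg_alt,
            "ddg": imp.hybrid.ddg,
        })
    cols = ["mirna", "gene", "rsid", "location_class", "d_max", "d_max_p",
            "significant", "pu_wt", "pu_alt", "delta_pu_pct", "dg_wt",
            "dg_alt", "ddg"]
    return pd.DataFrame(rows, columns=cols)


def _interaction_row(t: InteractionTriple) -> dict:
    ev = sorted(t.variant.evidence, key=lambda e: (e.lead_rsid, e.population))
    return {
        "Databases": ", ".join(sorted(t.target.sources)),
        "Targetome SNP": f"{t.variant.rsid} "
                         f"{t.variant.ref_allele}>{t.variant.alt_allele}",
        "miRNA": t.target.mirna_id,
        "Gene": t.target.gene_symbol,
        "GWAS SNP": ", ".join(dict.fromkeys(e.lead_rsid for e in ev)),
        "r2": ", ".join(str(round(e.r_squared, 3)) for e in ev),
        "Population": ", ".join(dict.fromkeys(e.population for e in ev)),
        "Categories": ", ".join(sorted({e.category.value for e in ev})),
        "location_class": t.location_class,
    }


_INTERACTION_COLS = [
    "Databases", "Targetome SNP", "miRNA", "Gene", "GWAS SNP", "r2",
    "Population", "Categories", "location_class",
]


def _write_interaction_tables(triples: list[InteractionTriple], outdir: Path):
    all_rows = [_interaction_row(t) for t in triples]
    pd.DataFrame(all_rows, columns=_INTERACTION_COLS).to_csv(
        outdir / "interactions.tsv", sep="\t", index=False)
    lead_triples = [
        t for t in triples
        if any(e.role == "lead" for e in t.variant.evidence)
    ]
    for zone in ("site", "flank"):
        rows = [_interaction_row(t) for t in lead_triples
                if t.location_class == zone]
        pd.DataFrame(rows, columns=_INTERACTION_COLS).to_csv(
            outdir / f"interactions_lead_{zone}.tsv", sep="\t", index=False)


def summarize_metrics(metric_df: pd.DataFrame) -> dict:
    """Sign tallies and extrema of the metric table.

    Unchanged (exactly zero) records form an explicit third class so that
    increased + decreased + unchanged always equals the total.
    """
    n = len(metric_df)
    if n == 0:
        zero = {"increased": 0, "decreased": 0, "unchanged": 0}
        return {
            "n_triples": 0, "n_site": 0, "n_flank": 0,
            "accessibility": dict(zero), "hybrid_stability": dict(zero),
            "significant_d_max": 0, "significant_fraction": 0.0,
            "extrema": {},
        }
    dpu = metric_df["delta_pu_pct"]
    ddg = metric_df["ddg"]
    sig = metric_df["significant"].astype(bool)
    return {
        "n_triples": int(n),
        "n_site": int((metric_df["location_class"] == "site").sum()),
        "n_flank": int((metric_df["location_class"] == "flank").sum()),
        "accessibility": {
            "increased": int((dpu > 0).sum()),
            "decreased": int((dpu < 0).sum()),
            "unchanged": int((dpu == 0).sum()),
        },
        # positive ddG = decreased hybrid stability
        "hybrid_stability": {
            "increased": int((ddg < 0).sum()),
            "decreased": int((ddg > 0).sum()),
            "unchanged": int((ddg == 0).sum()),
        },
        "significant_d_max": int(sig.sum()),
        "significant_fraction": float(sig.mean()),
        "extrema": {
            "d_max_max": float(metric_df["d_max"].max()),
            "delta_pu_pct_min": float(dpu.min()),
            "delta_pu_pct_max": float(dpu.max()),
            "ddg_min": float(ddg.min()),
            "ddg_max": float(ddg.max()),
        },
    }


def make_plots(metric_path: str | Path, outdir: str | Path):
    """Optional histograms of the three metrics (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.read_csv(metric_path, sep="\t")
    outdir = Path(outdir)
    for col, fname, xlabel in [
        ("d_max_p", "dmax_pvalues.png", "d_max p-value"),
        ("delta_pu_pct", "delta_pu.png", "dPu (percentage points)"),
        ("ddg", "ddg_hybrid.png", "ddG_hybrid (kcal/mol)"),
    ]:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.hist(df[col].dropna(), bins=30, color="#46759c")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("interactions")
        fig.tight_layout()
        fig.savefig(outdir / fname, dpi=120)
        plt.close(fig)
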