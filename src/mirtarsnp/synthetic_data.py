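"""Synthetic input bundles with known ground truth.

Emulates every file the pipeline consumes — GWAS association table, LD
proxy table, per-database targetome TSVs, 3'UTR and miRNA FASTA, variant
table, eQTL and conservation tables — with planted variant classes whose
downstream behaviour is known by construction:

``disruptive_site``
    at the centre of the seed-complement arm of a designed
    conformational-switch site (see :func:`_design_switch_site`): the
    substitution breaks a Watson-Crick pair of both the miRNA seed
    duplex and the arm:P1 stem, upon which P1 deserts the arm for a
    decoy partner — the whole site opens.  Guaranteed by construction
    and by fold validation to destabilise the hybrid (ddG > 0), open
    the site (dPu > 0) and rearrange local structure (large d_max).
``benign_site``
    inside a plain, undesigned target site; behaves like background, so
    its empirical p-values are ~uniform.
``hairpin_flank``
    in the P1 stem arm within 25 nt of a switch site (flank zone),
    perturbing structure without touching the site itself.
``neutral``
    more than 25 nt from any site; must produce no interactions.
``lead_site``
    a GWAS lead variant placed at a benign site position (exercises the
    lead-variant report tables).

Each target site carries one cognate miRNA (reverse complement of the
site plus a random 3' tail) and seed-only matchers, mirroring
multi-miRNA sites in real targetome databases.  Decoy proxies at
r^2 < 0.6 and leads above the significance threshold are planted to
verify the corresponding filters; a truth table records every planted
variant.  Same seed, same bundle, byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
RNA_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}

_CATEGORY_TRAITS = {
    "CRC_RISK": ["Colorectal cancer"],
    "CRC_SURVIVAL": ["Colorectal cancer survival"],
    "OB": ["Obesity", "Adiposity", "Overweight"],
    "W_B": ["Body mass index", "Body weight", "Birth weight"],
    "WHR": ["Waist circumference", "Hip circumference", "Waist-hip ratio"],
    "AT": ["Visceral adipose tissue", "Subcutaneous adipose tissue"],
    "FM": ["Body fat mass", "Body fat percentage"],
}
_POPS = ["EUR", "ASN", "AFR", "AMR"]
_POP_W = [0.6, 0.2, 0.1, 0.1]
_DBS = ["StarBase", "TargetScan", "microRNA.org"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic bundle."""

    seed: int = 0
    n_leads_per_category: int = 2
    n_insignificant_leads: int = 2
    extra_proxy_mean: float = 2.0       # geometric mean of decoy-neutral proxies/lead
    n_transcripts: int = 18
    utr_len_range: tuple = (205, 265)
    n_sites_per_transcript: int = 2
    n_switch_sites: int = 12            # sites with a designed structural switch
    site_len: int = 15
    stem_arm_len: int = 9               # 3' portion of the site paired in the stem
    stem_gap: int = 3                   # arm:P1 hairpin loop length
    switch_spacer: int = 3              # P1:P2 hairpin loop length
    mirnas_per_site: int = 2            # 1 cognate + seed-only matchers
    n_disruptive: int = 10
    n_benign_site: int = 160
    n_hairpin_flank: int = 8
    n_neutral: int = 12
    n_lead_site: int = 2
    n_decoy_site: int = 6               # proxies at r^2 < 0.6 planted in sites
    n_decoy_neutral: int = 6
    n_insig_site: int = 4               # site SNPs reachable only via p>1e-6 leads
    r2_true: tuple = (0.6, 1.0)
    r2_decoy: tuple = (0.2, 0.59)
    multi_pop_prob: float = 0.2
    p_eqtl_disruptive: float = 1.0      # planted regulatory SNPs are eQTLs
    p_eqtl_other: float = 0.2
    gc: float = 0.35                    # AU-rich background, like real 3'UTRs
    gc_arm: float = 0.75                # GC-rich designed stems
    design_validate: bool = True        # verify register switching by folding

    @property
    def n_planted(self) -> int:
        return (self.n_disruptive + self.n_benign_site + self.n_hairpin_flank
                + self.n_neutral)

    @property
    def planted_fractions(self) -> dict:
        n = max(1, self.n_planted)
        return {
            "disruptive_site": self.n_disruptive / n,
            "benign_site": self.n_benign_site / n,
            "hairpin_flank": self.n_hairpin_flank / n,
            "neutral": self.n_neutral / n,
        }

    def validate(self):
        for name in ("n_disruptive", "n_benign_site", "n_hairpin_flank",
                     "n_neutral", "n_transcripts", "n_sites_per_transcript"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        span = 45 + (self.n_sites_per_transcript - 1) * 110 + self.site_len \
            + 2 * (self.stem_gap + self.stem_arm_len) + self.switch_spacer + 2
        if span > self.utr_len_range[0]:
            raise ConfigError(
                f"UTRs of length {self.utr_len_range[0]} cannot hold "
                f"{self.n_sites_per_transcript} sites (need >= {span} nt)"
            )
        n_sites = self.n_transcripts * self.n_sites_per_transcript
        if self.n_switch_sites > n_sites:
            raise ConfigError("more switch sites than sites")
        if self.n_disruptive > self.n_switch_sites:
            raise ConfigError("more disruptive SNPs than switch sites")
        plain_positions = (n_sites - self.n_switch_sites) * self.site_len
        wanted = (self.n_benign_site + self.n_lead_site + self.n_decoy_site
                  + self.n_insig_site)
        if wanted > plain_positions:
            raise ConfigError("more site SNPs requested than site positions")


@dataclass
class SimBundle:
    """Paths of one generated bundle plus its truth table."""

    outdir: Path
    files: dict
    truth: pd.DataFrame
    config: SimConfig

    @property
    def truth_path(self) -> Path:
        return Path(self.files["truth"])


def _rand_seq(rng, n: int, gc: float) -> list:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=n, p=p))


def _revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def _dna2rna(seq: str) -> str:
    return seq.replace("T", "U")


def _nonpairing_substitution(base: str, rng) -> str:
    """A substitution that can pair its former partner neither WC nor GU."""
    partner = COMPLEMENT[base]  # base the original pairs with
    forbidden = {base}
    if partner == "G":
        forbidden.add("T")      # T-G wobble
    if partner == "T":
        forbidden.add("G")      # G-T wobble
    choices = [b for b in "ACGT" if b not in forbidden]
    return choices[int(rng.integers(len(choices)))]


def _switch_substitution(base: str, rng) -> str:
    """A substitution for the two-register switch: the new base must not
    pair the wild-type partner, and the wild-type base must not pair the
    new base's complement (no wobble leakage between registers)."""
    partner = COMPLEMENT[base]
    forbidden = {base}
    if partner == "G":
        forbidden.add("T")
    if partner == "T":
        forbidden.add("G")
    if base == "G":
        forbidden.add("A")      # comp(A)=T wobbles with G
    if base == "T":
        forbidden.add("C")      # comp(C)=G wobbles with T
    choices = [b for b in "ACGT" if b not in forbidden]
    return choices[int(rng.integers(len(choices)))]


def _kmers(s: str, k: int) -> set:
    return {s[i:i + k] for i in range(len(s) - k + 1)}


def _design_switch_site(seq: list, s0: int, s1: int, config: SimConfig,
                        rng) -> dict:
    """Design a conformational-switch site, in place.

    Wild type: the GC-rich 3' arm of the site pairs its perfect reverse
    complement P1 just downstream (site partially occluded).  A decoy
    partner P2 — a near-copy of the arm plus the reverse complement of
    the hairpin loop, weakened by one designed mismatch — lies further
    downstream and is out-competed.  The planted substitution breaks the
    central arm:P1 pair, upon which P1 deserts the arm for the now
    stronger P1:P2 duplex: the whole site becomes single-stranded.  The
    variant thus rearranges ~20 base pairs (large d_max) and opens the
    site (large positive dPu).

    Arm candidates are screened against self-complementarity and against
    any 5-mer complementarity with the surrounding sequence; unless
    ``design_validate`` is off, a candidate is accepted only when folding
    confirms both register occupancies.  Returns a dict with the switch
    position/substitution and the partner intervals.
    """
    from .rna_struct import EnergyModel, partition_function

    a = config.stem_arm_len           # arm length
    g = config.stem_gap               # arm:P1 hairpin loop
    c = config.switch_spacer          # P1:P2 hairpin loop
    arm0 = s1 - a
    p0 = s1 + g                       # P1 interval [p0, p0+a)
    q0 = s1 + g + a + c               # P2 interval [q0, q0+a+g)
    q1 = q0 + a + g
    sp_local = a // 2
    i_c = g + a // 2                  # P1 centre within the paired region
    model = EnergyModel.turner() if config.design_validate else None
    lo = max(0, s0 - 70)
    hi = min(len(seq), q1 + 70)
    # validate on the same local-fold scale the analysis uses (~100 nt
    # centred on the variant)
    sp = arm0 + sp_local
    w0 = max(0, sp - 50)
    w1 = min(len(seq), sp + 50)
    best = None

    def _place(cand, gap_seq, p2seq):
        seq[arm0:s1] = list(cand)
        seq[s1:s1 + g] = list(gap_seq)
        seq[p0:p0 + a] = list(_revcomp(cand))
        seq[q0:q1] = list(p2seq)

    result = {
        "arm_start": arm0, "partner_start": p0, "partner_end": p0 + a,
        "partner2_start": q0, "partner2_end": q1,
        "switch_pos": arm0 + sp_local,
    }
    for round_ in range(6):
        for _ in range(150):
            cand = "".join(_rand_seq(rng, a, config.gc_arm))
            if _kmers(cand, 4) & _kmers(_revcomp(cand), 4):
                continue
            gap_seq = "".join(_rand_seq(rng, g, config.gc))
            base = cand[sp_local]
            alt = _switch_substitution(base, rng)
            # P2 pairs the (loop + P1) stretch perfectly except one designed
            # mismatch against the centre of P1
            p2 = list(cand + _revcomp(gap_seq))
            p2[sp_local] = _nonpairing_substitution(base, rng)
            p2seq = "".join(p2)
            env = list(seq[lo:hi])
            for r0, r1 in ((arm0, s1 + g), (p0, p0 + a), (q0, q1)):
                for i in range(r0 - lo, r1 - lo):
                    env[i] = "N"
            env_rc = {_revcomp(x) for x in _kmers("".join(env), 5)
                      if "N" not in x}
            if any(_kmers(s, 5) & env_rc
                   for s in (cand, _revcomp(cand), p2seq)):
                continue
            _place(cand, gap_seq, p2seq)
            if not config.design_validate:
                result["switch_alt"] = alt
                return result
            wt = _dna2rna("".join(seq[w0:w1]))
            sp_w = arm0 + sp_local - w0
            alt_win = wt[:sp_w] + _dna2rna(alt) + wt[sp_w + 1:]
            p_wt = partition_function(wt, model).P
            p_alt = partition_function(alt_win, model).P
            # WT register: arm(i) with P1, pairs (arm0+k, p0+a-1-k)
            occ_wt = float(np.mean([
                p_wt[arm0 + k - w0, p0 + a - 1 - k - w0] for k in range(a)]))
            # ALT register: (s1+i, q1-1-i) for the loop+P1 stretch vs P2
            occ_alt = float(np.mean([
                p_alt[s1 + i - w0, q1 - 1 - i - w0]
                for i in range(a + g) if i != i_c]))
            arm_alt_tot = float(np.mean(
                p_alt[arm0 - w0:s1 - w0, :].sum(axis=1)))
            pu_alt = 0.0
            if occ_wt >= 0.7 and occ_alt >= 0.5:
                # opening probability of the whole site in the variant,
                # on the same site-centred window the accessibility
                # metric uses: the planted effect must free the site
                from .rna_struct import partition_Z

                aw0 = max(0, s0 - 50)
                aw1 = min(len(seq), s1 + 50)
                acc_seq = _dna2rna("".join(seq[aw0:aw1]))
                sp_a = arm0 + sp_local - aw0
                acc_alt = (acc_seq[:sp_a] + _dna2rna(alt)
                           + acc_seq[sp_a + 1:])
                mask = np.zeros(aw1 - aw0, dtype=bool)
                mask[s0 - aw0:s1 - aw0] = True
                pu_alt = partition_Z(acc_alt, model, unpaired_mask=mask) \
                    / partition_Z(acc_alt, model)
            if (occ_wt >= 0.88 and occ_alt >= 0.70 and arm_alt_tot <= 0.15
                    and pu_alt >= 0.02):
                result["switch_alt"] = alt
                return result
            score = min(occ_wt / 0.88, occ_alt / 0.70,
                        0.15 / max(arm_alt_tot, 1e-9), pu_alt / 0.02)
            if best is None or score > best[0]:
                best = (score, cand, gap_seq, p2seq, alt)
        if round_ < 5:
            # no acceptable arm against this background: redraw the local
            # context (still ours to choose) and try again; the fallback
            # candidate is tied to the old context, so drop it
            r0 = max(0, min(s0 - 45, w0))
            r1 = min(len(seq), max(q1 + 45, w1))
            seq[r0:r1] = _rand_seq(rng, r1 - r0, config.gc)
            best = None
    if best is None:
        raise ConfigError("could not design a switch site (arm screening)")
    _, cand, gap_seq, p2seq, alt = best
    _place(cand, gap_seq, p2seq)
    result["switch_alt"] = alt
    return result


def simulate_inputs(config: SimConfig, outdir: str | Path) -> SimBundle:
    """Generate the full input bundle under ``outdir``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- transcripts and sites ------------------------------------------
    n_sites_total = config.n_transcripts * config.n_sites_per_transcript
    switch_flags = np.zeros(n_sites_total, dtype=bool)
    switch_flags[rng.choice(n_sites_total, size=config.n_switch_sites,
                            replace=False)] = True
    transcripts = []   # dicts with seq, chrom, strand, offset, sites
    sites = []         # flat list of site dicts
    g_cursor = {"chr1": 10_000, "chr2": 10_000}
    site_counter = 0
    for t in range(config.n_transcripts):
        utr_len = int(rng.integers(*config.utr_len_range))
        seq = _rand_seq(rng, utr_len, config.gc)
        chrom = "chr1" if t % 2 == 0 else "chr2"
        strand = "+" if t % 2 == 0 else "-"
        offset = g_cursor[chrom]
        g_cursor[chrom] += utr_len + 1_000
        tx = {
            "transcript": f"TX{t:03d}", "gene": f"GENE{t:03d}",
            "chrom": chrom, "strand": strand, "offset": offset,
            "utr_len": utr_len, "seq": seq, "sites": [],
        }
        for k in range(config.n_sites_per_transcript):
            s0 = 40 + k * 110 + int(rng.integers(0, 6))
            s1 = s0 + config.site_len
            is_switch = bool(switch_flags[site_counter])
            site_counter += 1
            site = {
                "site_id": f"TX{t:03d}_S{k}",
                "tx": tx, "utr_start": s0, "utr_end": s1,
                "switch": is_switch, "mirnas": [],
            }
            if is_switch:
                design = _design_switch_site(seq, s0, s1, config, rng)
                if design["partner2_end"] + 2 > utr_len:
                    raise ConfigError("site layout exceeds UTR length")
                site.update(design)
            tx["sites"].append(site)
            sites.append(site)
        transcripts.append(tx)

    # ---- miRNAs per site -------------------------------------------------
    mir_counter = [0]

    def _new_mirna() -> str:
        mir_counter[0] += 1
        return f"miR-{mir_counter[0]:04d}"

    mirna_seqs: dict[str, str] = {}
    for site in sites:
        tx = site["tx"]
        s0, s1 = site["utr_start"], site["utr_end"]
        site_seq = "".join(tx["seq"][s0:s1])
        cognate_core = _dna2rna(_revcomp(site_seq))
        tail = _dna2rna("".join(_rand_seq(rng, 6, config.gc)))
        cognate = cognate_core + tail
        name = _new_mirna()
        mirna_seqs[name] = cognate
        site["mirnas"].append({"mirna": name, "cognate": True})
        for _ in range(config.mirnas_per_site - 1):
            m = list(_dna2rna("".join(_rand_seq(rng, 21, config.gc))))
            # seed (nt 2-8) complements the 3' portion of the site
            for kk in range(1, 8):
                m[kk] = RNA_COMP[_dna2rna(site_seq[len(site_seq) - 1 - kk])]
            name = _new_mirna()
            mirna_seqs[name] = "".join(m)
            site["mirnas"].append({"mirna": name, "cognate": False})

    # ---- targetome rows (per database) ----------------------------------
    targetome_rows: dict[str, list] = {db: [] for db in _DBS}
    for site in sites:
        tx = site["tx"]
        s0, s1 = site["utr_start"], site["utr_end"]
        if tx["strand"] == "+":
            g0, g1 = tx["offset"] + s0, tx["offset"] + s1
        else:
            g0 = tx["offset"] + tx["utr_len"] - s1
            g1 = tx["offset"] + tx["utr_len"] - s0
        site["genomic"] = (g0, g1)
        for m in site["mirnas"]:
            n_db = 1 + int(rng.integers(0, len(_DBS)))
            dbs = [_DBS[i] for i in sorted(
                rng.choice(len(_DBS), size=n_db, replace=False))]
            for db in dbs:
                targetome_rows[db].append({
                    "db": db, "mirna": m["mirna"], "gene": tx["gene"],
                    "transcript": tx["transcript"], "chrom": tx["chrom"],
                    "strand": tx["strand"],
                    "genomic_start": g0, "genomic_end": g1,
                    "utr_start": s0, "utr_end": s1,
                    "evidence": "verified" if db == "StarBase" else "predicted",
                })

    # ---- GWAS leads ------------------------------------------------------
    rs_counter = [100_000]

    def _new_rsid() -> str:
        rs_counter[0] += int(rng.integers(1, 50))
        return f"rs{rs_counter[0]}"

    leads = []
    for cat, traits in _CATEGORY_TRAITS.items():
        for _ in range(config.n_leads_per_category):
            pops = [str(rng.choice(_POPS, p=_POP_W))]
            if rng.random() < config.multi_pop_prob:
                extra = str(rng.choice([p for p in _POPS if p != pops[0]]))
                pops.append(extra)
            leads.append({
                "rsid": _new_rsid(), "category": cat,
                "trait": traits[int(rng.integers(len(traits)))],
                "p": 10.0 ** -float(rng.uniform(6.2, 14)),
                "pops": pops, "significant": True,
            })
    for _ in range(config.n_insignificant_leads):
        cat = str(rng.choice(list(_CATEGORY_TRAITS)))
        leads.append({
            "rsid": _new_rsid(), "category": cat,
            "trait": _CATEGORY_TRAITS[cat][0],
            "p": 10.0 ** -float(rng.uniform(3.0, 5.5)),
            "pops": [str(rng.choice(_POPS, p=_POP_W))],
            "significant": False,
        })
    sig_leads = [l for l in leads if l["significant"]]
    insig_leads = [l for l in leads if not l["significant"]]

    # ---- position pools --------------------------------------------------
    arm_pool = []      # designed switch positions (disruptive)
    plain_pool = []    # positions in plain (undesigned) sites
    partner_pool = []  # stem partner P1 positions (hairpin_flank)
    for site in sites:
        s0 = site["utr_start"]
        if site["switch"]:
            arm_pool.append((site, site["switch_pos"]))
            for p in range(site["partner_start"] + 2,
                           site["partner_end"] - 2):
                partner_pool.append((site, p))
        else:
            for p in range(s0, s0 + config.site_len):
                plain_pool.append((site, p))
    for pool in (arm_pool, plain_pool, partner_pool):
        rng.shuffle(pool)  # type: ignore[arg-type]

    # used site keys so at most one disruptive SNP lands per site
    def _draw(pool, n, one_per_site=False):
        out, seen_sites, seen_pos = [], set(), set()
        for site, p in pool:
            if len(out) == n:
                break
            key = (site["tx"]["transcript"], p)
            if key in seen_pos:
                continue
            if one_per_site and site["site_id"] in seen_sites:
                continue
            out.append((site, p))
            seen_sites.add(site["site_id"])
            seen_pos.add(key)
        if len(out) < n:
            raise ConfigError("not enough positions to place planted SNPs")
        # remove drawn entries from the pool
        drawn = {(s["site_id"], p) for s, p in out}
        pool[:] = [(s, p) for s, p in pool if (s["site_id"], p) not in drawn]
        return out

    placements = []  # (class, site_or_tx, utr_pos, role)
    for site, p in _draw(arm_pool, config.n_disruptive, one_per_site=True):
        placements.append(("disruptive_site", site, p, "proxy"))
    for site, p in _draw(plain_pool, config.n_benign_site):
        placements.append(("benign_site", site, p, "proxy"))
    for site, p in _draw(partner_pool, config.n_hairpin_flank):
        placements.append(("hairpin_flank", site, p, "proxy"))
    for site, p in _draw(plain_pool, config.n_lead_site):
        placements.append(("lead_site", site, p, "lead"))
    for site, p in _draw(plain_pool, config.n_decoy_site):
        placements.append(("decoy_site", site, p, "decoy"))
    for site, p in _draw(plain_pool, config.n_insig_site):
        placements.append(("insig_site", site, p, "insig"))

    # neutral positions: outside every extended interval
    neutral_placements = []
    for tx in transcripts:
        blocked = np.zeros(tx["utr_len"], dtype=bool)
        for site in tx["sites"]:
            a = max(0, site["utr_start"] - 25)
            b = min(tx["utr_len"], site["utr_end"] + 25)
            if site["switch"]:
                b = max(b, min(tx["utr_len"], site["partner2_end"] + 2))
            blocked[a:b] = True
        open_pos = np.flatnonzero(~blocked)
        for p in open_pos:
            neutral_placements.append((tx, int(p)))
    rng.shuffle(neutral_placements)  # type: ignore[arg-type]
    need_neutral = config.n_neutral + config.n_decoy_neutral
    extra_per_lead = [int(min(rng.geometric(1.0 / (1.0 + config.extra_proxy_mean)),
                              6)) for _ in sig_leads]
    need_neutral += sum(extra_per_lead) + len(leads)
    if len(neutral_placements) < need_neutral:
        raise ConfigError("not enough neutral UTR positions")

    # ---- assemble variants ----------------------------------------------
    variants = []   # dicts: rsid, tx, utr_pos, ref/alt (sense), class, site
    truth_rows = []

    def _add_variant(klass, tx, utr_pos, site, role, alt_sense=None):
        rsid = _new_rsid()
        ref = tx["seq"][utr_pos]
        if alt_sense is None:
            alts = [b for b in "ACGT" if b != ref]
            alt_sense = alts[int(rng.integers(3))]
        variants.append({
            "rsid": rsid, "tx": tx, "utr_pos": utr_pos,
            "ref": ref, "alt": alt_sense, "class": klass,
            "site": site, "role": role,
        })
        return rsid

    neutral_iter = iter(neutral_placements)
    for klass, site, p, role in placements:
        tx = site["tx"]
        if klass == "disruptive_site":
            alt = site["switch_alt"]       # the register-switch substitution
        elif klass == "hairpin_flank":
            alt = _nonpairing_substitution(tx["seq"][p], rng)
        else:
            alt = None
        _add_variant(klass, tx, p, site, role, alt)
    for _ in range(config.n_neutral):
        tx, p = next(neutral_iter)
        _add_variant("neutral", tx, p, None, "proxy")
    for _ in range(config.n_decoy_neutral):
        tx, p = next(neutral_iter)
        _add_variant("decoy_neutral", tx, p, None, "decoy")
    # leads that are not site-placed live at neutral positions
    lead_site_variants = [v for v in variants if v["class"] == "lead_site"]
    for i, lead in enumerate(leads):
        if i < len(lead_site_variants):
            lead_site_variants[i]["rsid"] = lead["rsid"]
            lead_site_variants[i]["role"] = "lead"
            lead["placed"] = "site"
        else:
            tx, p = next(neutral_iter)
            ref = tx["seq"][p]
            alts = [b for b in "ACGT" if b != ref]
            variants.append({
                "rsid": lead["rsid"], "tx": tx, "utr_pos": p, "ref": ref,
                "alt": alts[int(rng.integers(3))],
                "class": "lead_neutral", "site": None, "role": "lead",
            })
            lead["placed"] = "neutral"
    # geometric tail of extra neutral proxies per significant lead
    for lead, n_extra in zip(sig_leads, extra_per_lead):
        for _ in range(n_extra):
            tx, p = next(neutral_iter)
            rsid = _add_variant("neutral_extra", tx, p, None, "proxy")
            variants[-1]["lead_fixed"] = lead

    # ---- LD table --------------------------------------------------------
    ld_rows = []

    def _link(lead, rsid, r2_range):
        r2 = round(float(rng.uniform(*r2_range)), 3)
        for pop in lead["pops"]:
            ld_rows.append({
                "lead_rsid": lead["rsid"], "proxy_rsid": rsid,
                "r2": r2, "population": pop,
            })
        return r2

    for v in variants:
        if v["role"] == "proxy":
            lead = v.get("lead_fixed") or sig_leads[int(rng.integers(len(sig_leads)))]
            v["lead"] = lead
            v["r2"] = _link(lead, v["rsid"], config.r2_true)
        elif v["role"] == "decoy":
            lead = sig_leads[int(rng.integers(len(sig_leads)))]
            v["lead"] = lead
            v["r2"] = _link(lead, v["rsid"], config.r2_decoy)
        elif v["role"] == "insig":
            lead = insig_leads[int(rng.integers(len(insig_leads)))]
            v["lead"] = lead
            v["r2"] = _link(lead, v["rsid"], config.r2_true)
        else:  # lead variant
            v["lead"] = None
            v["r2"] = 1.0

    # ---- annotation tables ----------------------------------------------
    eqtl_rows, cons_rows = [], []
    for v in variants:
        p_eq = (config.p_eqtl_disruptive if v["class"] == "disruptive_site"
                else config.p_eqtl_other)
        v["eqtl"] = bool(rng.random() < p_eq)
        if v["eqtl"]:
            eqtl_rows.append({
                "rsid": v["rsid"], "gene": v["tx"]["gene"], "tissue": "colon",
            })
        if rng.random() < 0.8:
            cons_rows.append({
                "rsid": v["rsid"],
                "gerp": "+" if rng.random() < 0.5 else "-",
                "siphy": "+" if rng.random() < 0.5 else "-",
            })

    # ---- write files -----------------------------------------------------
    files = {}

    gwas_rows = []
    for i, lead in enumerate(leads):
        for pop in lead["pops"]:
            gwas_rows.append({
                "rsid": lead["rsid"], "trait": lead["trait"],
                "p_value": f"{lead['p']:.3e}", "population": pop,
                "study_id": f"GCST{i:05d}",
            })
    files["gwas"] = outdir / "gwas.tsv"
    pd.DataFrame(gwas_rows).to_csv(files["gwas"], sep="\t", index=False)

    files["ld"] = outdir / "ld.tsv"
    pd.DataFrame(ld_rows).to_csv(files["ld"], sep="\t", index=False)

    files["targetome"] = []
    for db in _DBS:
        path = outdir / f"targetome_{db.lower().replace('.', '_')}.tsv"
        pd.DataFrame(targetome_rows[db]).to_csv(path, sep="\t", index=False)
        files["targetome"].append(path)

    files["utr_fasta"] = outdir / "utr.fasta"
    with open(files["utr_fasta"], "w") as fh:
        for tx in transcripts:
            fh.write(f">{tx['transcript']} gene={tx['gene']}\n")
            s = "".join(tx["seq"])
            for i in range(0, len(s), 70):
                fh.write(s[i:i + 70] + "\n")

    files["mirna_fasta"] = outdir / "mirna.fasta"
    with open(files["mirna_fasta"], "w") as fh:
        for name in sorted(mirna_seqs):
            fh.write(f">{name}\n{mirna_seqs[name]}\n")

    files["variants"] = outdir / "variants.tsv"
    var_rows = []
    for v in variants:
        tx = v["tx"]
        if tx["strand"] == "+":
            gpos = tx["offset"] + v["utr_pos"]
            ref_g, alt_g = v["ref"], v["alt"]
        else:
            gpos = tx["offset"] + tx["utr_len"] - 1 - v["utr_pos"]
            ref_g, alt_g = COMPLEMENT[v["ref"]], COMPLEMENT[v["alt"]]
        v["gpos"] = gpos
        v["chrom"] = tx["chrom"]
        var_rows.append({
            "#CHROM": tx["chrom"], "POS": gpos + 1, "ID": v["rsid"],
            "REF": ref_g, "ALT": alt_g,
        })
    var_df = pd.DataFrame(var_rows).sort_values(["#CHROM", "POS"])
    with open(files["variants"], "w") as fh:
        fh.write("##fileformat=VCF-like TSV (SNVs only)\n")
        var_df.to_csv(fh, sep="\t", index=False)

    files["eqtl"] = outdir / "eqtl.tsv"
    pd.DataFrame(eqtl_rows or [{"rsid": "rs0", "gene": "-", "tissue": "-"}]
                 ).to_csv(files["eqtl"], sep="\t", index=False)
    files["conservation"] = outdir / "conservation.tsv"
    pd.DataFrame(cons_rows or [{"rsid": "rs0", "gerp": "-", "siphy": "-"}]
                 ).to_csv(files["conservation"], sep="\t", index=False)

    for v in variants:
        site = v["site"]
        truth_rows.append({
            "rsid": v["rsid"], "class": v["class"], "role": v["role"],
            "chrom": v["chrom"], "pos_1based": v["gpos"] + 1,
            "transcript": v["tx"]["transcript"], "gene": v["tx"]["gene"],
            "utr_pos": v["utr_pos"],
            "site_id": site["site_id"] if site else "-",
            "cognate_mirna": site["mirnas"][0]["mirna"] if site else "-",
            "lead_rsid": v["lead"]["rsid"] if v.get("lead") else v["rsid"],
            "r2": v["r2"],
            "is_eqtl": v["eqtl"],
        })
    files["truth"] = outdir / "truth.tsv"
    truth_df = pd.DataFrame(truth_rows)
    truth_df.to_csv(files["truth"], sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "planted_fractions": config.planted_fractions,
        "files": {k: ([str(p) for p in v] if isinstance(v, list) else str(v))
                  for k, v in files.items()},
    }
    files["manifest"] = outdir / "bundle_manifest.json"
    with open(files["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return SimBundle(outdir=outdir, files=files, truth=truth_df, config=config)


# ---------------------------------------------------------------------------
# expected tallies by brute force


def expected_counts(bundle: SimBundle) -> dict:
    """Predict the pipeline's structural tallies by brute force.

    Re-derives, from the emitted files only (no interval trees, no
    pipeline code): which variants are reachable through significant
    leads and r^2 >= 0.6 proxies, then an all-pairs containment scan
    against the merged targetome intervals, deduplicated per
    (miRNA, gene, rsid) with site-class priority — exactly the counts the
    pipeline must report on this bundle.
    """
    gwas = pd.read_csv(bundle.files["gwas"], sep="\t", dtype=str)
    sig = {r["rsid"] for _, r in gwas.iterrows() if float(r["p_value"]) <= 1e-6}
    sig_pops = {}
    for _, r in gwas.iterrows():
        if r["rsid"] in sig:
            sig_pops.setdefault(r["rsid"], set()).add(r["population"])
    ld = pd.read_csv(bundle.files["ld"], sep="\t")
    reachable = set(sig)
    for _, r in ld.iterrows():
        if (str(r["lead_rsid"]) in sig and float(r["r2"]) >= 0.6
                and str(r["population"]) in sig_pops[str(r["lead_rsid"])]):
            reachable.add(str(r["proxy_rsid"]))

    frames = [pd.read_csv(p, sep="\t") for p in bundle.files["targetome"]]
    tg = pd.concat(frames, ignore_index=True)
    tg = tg.drop_duplicates(
        subset=["mirna", "transcript", "genomic_start", "genomic_end"])

    with open(bundle.files["variants"]) as fh:
        lines = [ln for ln in fh if not ln.startswith("##")]
    import io
    var = pd.read_csv(io.StringIO("".join(lines)), sep="\t")
    var.columns = [c.lstrip("#") for c in var.columns]

    utr_lens = {}
    name = None
    with open(bundle.files["utr_fasta"]) as fh:
        for ln in fh:
            if ln.startswith(">"):
                name = ln[1:].split()[0]
                utr_lens[name] = 0
            else:
                utr_lens[name] += len(ln.strip())

    triples = {}
    for _, v in var.iterrows():
        if str(v["ID"]) not in reachable:
            continue
        pos = int(v["POS"]) - 1
        for _, s in tg.iterrows():
            if str(s["chrom"]) != str(v["CHROM"]):
                continue
            g0, g1 = int(s["genomic_start"]), int(s["genomic_end"])
            us, ue = int(s["utr_start"]), int(s["utr_end"])
            utr_len = utr_lens[str(s["transcript"])]
            if str(s["strand"]) == "+":
                u = us + (pos - g0)
            else:
                u = us + (g1 - 1 - pos)
            a = max(0, us - 25)
            b = min(utr_len, ue + 25)
            if not (a <= u < b):
                continue
            zone = "site" if us <= u < ue else "flank"
            key = (str(s["mirna"]), str(s["gene"]), str(v["ID"]))
            prev = triples.get(key)
            if prev is None or (prev == "flank" and zone == "site"):
                triples[key] = zone
    n_site = sum(1 for z in triples.values() if z == "site")
    n_flank = len(triples) - n_site
    truth = bundle.truth
    site_class = truth[truth["class"].isin(
        ["disruptive_site", "benign_site", "lead_site"])]
    return {
        "n_triples": len(triples),
        "n_site": n_site,
        "n_flank": n_flank,
        "eligible_candidates": n_site,
        "n_reachable_variants": len(reachable & set(var["ID"].astype(str))),
        "planted_site_snps": len(site_class),
        "triple_zones": {"|".join(k): z for k, z in sorted(triples.items())},
    }
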